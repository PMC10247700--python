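import numpy as np
import pandas as pd
import pytest

from voxenc.cortex import responses_from_signals
from voxenc.evaluation import (audit_split_purity, explained_variance_fraction,
                               model_output_correlation, noise_ceiling,
                               permutation_threshold, prediction_accuracy,
                               win_percentage)
from voxenc.stimuli import generate_experiment_stimuli


class TestPredictionAccuracy:
    def test_identical_series_give_unit_correlation(self, rng):
        y = rng.normal(size=(50, 4))
        acc = prediction_accuracy(y, y)
        np.testing.assert_allclose(acc["rho"], 1.0, atol=1e-12)

    def test_negated_series_give_minus_one(self, rng):
        y = rng.normal(size=(50, 4))
        np.testing.assert_allclose(prediction_accuracy(-y, y)["rho"], -1.0,
                                   atol=1e-12)

    def test_invariant_under_positive_affine_transform(self, rng):
        y = rng.normal(size=(50, 4))
        preds = rng.normal(size=(50, 4))
        a = prediction_accuracy(preds, y)["rho"]
        b = prediction_accuracy(3.0 * preds + 2.0, y)["rho"]
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_degenerate_series_flagged_as_zero(self, rng):
        y = rng.normal(size=(20, 2))
        preds = rng.normal(size=(20, 2))
        preds[:, 0] = 5.0
        acc = prediction_accuracy(preds, y)
        assert acc.loc[0, "rho"] == 0.0 and acc.loc[0, "degenerate"]

    def test_bootstrap_se_shrinks_with_trial_count(self, rng):
        ses = []
        for n in (100, 400):
            y = rng.normal(size=(n, 30))
            preds = 0.5 * y + rng.normal(size=(n, 30))
            acc = prediction_accuracy(preds, y, n_bootstrap=200, seed=1)
            ses.append(acc["rho_se"].mean())
        assert 1.5 < ses[0] / ses[1] < 2.7  # ~ sqrt(4) = 2


class TestPermutationThreshold:
    def test_threshold_decreases_with_trial_count(self):
        t_small = permutation_threshold(500, p=0.01, n_perm=300, seed=0)
        t_large = permutation_threshold(3000, p=0.01, n_perm=300, seed=0)
        assert t_large < t_small

    def test_matches_gaussian_null_approximation(self):
        n = 3000
        thr = permutation_threshold(n, p=0.01, n_perm=500, seed=1)
        assert thr == pytest.approx(2.326 / np.sqrt(n), rel=0.10)

    def test_median_of_null_is_near_zero(self):
        thr = permutation_threshold(3000, p=0.5, n_perm=200, seed=2)
        assert abs(thr) < 0.02

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ValueError):
            permutation_threshold(100, p=1.5)
        with pytest.raises(ValueError):
            permutation_threshold(100, p=0.001, n_perm=10)


class TestNoiseCeiling:
    @staticmethod
    def _dataset(noise, signal_sd=1.0, n_images=200, n_repeats=3, seed=0,
                 n_sessions=2):
        stim = generate_experiment_stimuli(n_train=10, n_shared=n_images,
                                           resolution=16, seed=seed)
        rng = np.random.default_rng(seed + 1)
        n_total = stim.n_images
        signals = rng.normal(0, signal_sd, size=(n_total, 40))
        return responses_from_signals(signals, stim,
                                      noise_sd=np.full(40, noise),
                                      n_repeats=n_repeats,
                                      n_sessions=n_sessions, seed=seed + 2)

    def test_zero_noise_gives_full_ceiling(self):
        # exact within one session; session-wise z-scoring perturbs repeats
        # split across sessions only at the ~0.5-point level
        nc = noise_ceiling(self._dataset(0.0, n_sessions=1))
        np.testing.assert_allclose(nc["noise_ceiling"], 100.0, atol=1e-6)
        nc2 = noise_ceiling(self._dataset(0.0, n_sessions=2))
        assert nc2["noise_ceiling"].min() > 98.0

    def test_matched_signal_and_noise_give_half_ceiling(self):
        nc = noise_ceiling(self._dataset(1.0))
        assert nc["noise_ceiling"].mean() == pytest.approx(50.0, abs=5.0)

    def test_pure_noise_voxel_has_near_zero_ceiling(self):
        nc = noise_ceiling(self._dataset(1.0, signal_sd=1e-6))
        assert nc["noise_ceiling"].mean() < 5.0

    def test_requires_repeats(self, dataset_small):
        solo = dataset_small.trials.drop_duplicates("image_id")
        import copy
        ds = copy.copy(dataset_small)
        ds.trials = solo
        ds.betas = dataset_small.betas[solo["trial"].to_numpy()]
        with pytest.raises(ValueError):
            noise_ceiling(ds)


class TestWinPercentage:
    @staticmethod
    def _acc(rhos, areas=None):
        t = pd.DataFrame({"voxel": np.arange(len(rhos)), "rho": rhos})
        if areas is not None:
            t["area"] = areas
        return t

    def test_equal_models_never_win(self):
        a = self._acc([0.3, 0.2])
        assert win_percentage(a, a.copy()) == 0.0

    def test_split_outcome(self):
        assert win_percentage(self._acc([0.2, 0.1]),
                              self._acc([0.1, 0.2])) == 50.0

    def test_uniform_advantage_wins_everywhere(self):
        base = np.linspace(-0.2, 0.6, 7)
        assert win_percentage(self._acc(base + 0.01), self._acc(base)) == 100.0

    def test_mismatched_voxels_rejected(self):
        a = self._acc([0.1])
        b = self._acc([0.1, 0.2])
        with pytest.raises(ValueError):
            win_percentage(a, b)

    def test_per_area_breakdown(self):
        a = self._acc([0.2, 0.2, 0.0], areas=[1, 1, 2])
        b = self._acc([0.1, 0.1, 0.1], areas=[1, 1, 2])
        overall, per_area = win_percentage(a, b, by_area=True)
        assert overall == pytest.approx(100 * 2 / 3)
        assert per_area[1] == 100.0 and per_area[2] == 0.0


class TestExplainedVarianceFraction:
    def test_zero_accuracy_explains_nothing(self):
        acc = pd.DataFrame({"voxel": [0], "rho": [0.0]})
        nc = pd.DataFrame({"voxel": [0], "noise_ceiling": [50.0]})
        out = explained_variance_fraction(acc, nc)
        assert out["fraction"].iloc[0] == 0.0

    def test_voxels_below_floor_are_excluded(self):
        acc = pd.DataFrame({"voxel": [0, 1], "rho": [0.5, 0.5]})
        nc = pd.DataFrame({"voxel": [0, 1], "noise_ceiling": [50.0, 2.0]})
        out = explained_variance_fraction(acc, nc, min_nc=5.0)
        assert out["n_voxels"].iloc[0] == 1
        assert out.attrs["n_excluded"] == 1

    def test_perfect_model_explains_all_explainable_variance(self, rng):
        stim = generate_experiment_stimuli(n_train=10, n_shared=200,
                                           resolution=16, seed=4)
        signals = rng.normal(size=(stim.n_images, 40))
        ds = responses_from_signals(signals, stim, noise_sd=np.ones(40),
                                    n_repeats=3, n_sessions=1, seed=5)
        preds = ds.signal  # the noiseless ground-truth signal per trial
        acc = prediction_accuracy(preds, ds.betas)
        nc = noise_ceiling(ds)
        out = explained_variance_fraction(acc, nc)
        assert out["fraction"].iloc[0] == pytest.approx(100.0, abs=5.0)

    def test_nonpositive_floor_rejected(self):
        acc = pd.DataFrame({"voxel": [0], "rho": [0.1]})
        nc = pd.DataFrame({"voxel": [0], "noise_ceiling": [50.0]})
        with pytest.raises(ValueError):
            explained_variance_fraction(acc, nc, min_nc=0.0)


class TestModelOutputCorrelation:
    def test_self_correlation_is_one(self, rng):
        a = rng.normal(size=(100, 5))
        out = model_output_correlation(a, a)
        np.testing.assert_allclose(out["rho"], 1.0, atol=1e-12)

    def test_symmetric_in_model_order(self, rng):
        a = rng.normal(size=(100, 5))
        b = rng.normal(size=(100, 5))
        np.testing.assert_allclose(model_output_correlation(a, b)["rho"],
                                   model_output_correlation(b, a)["rho"],
                                   atol=1e-12)

    def test_independent_models_decorrelate(self, rng):
        a = rng.normal(size=(300, 200))
        b = rng.normal(size=(300, 200))
        out = model_output_correlation(a, b)
        assert abs(out["rho"].mean()) < 0.1


class TestSplitPurity:
    def test_clean_dataset_passes(self, stimuli_small, dataset_small):
        audit_split_purity(stimuli_small, dataset_small)

    def test_leaked_image_detected(self, stimuli_small, dataset_small):
        leaky = stimuli_small.table.copy()
        shared_id = leaky.loc[leaky["split"] == "shared-validation",
                              "image_id"].iloc[0]
        extra = leaky[leaky["image_id"] == shared_id].assign(split="train")
        leaky = pd.concat([leaky, extra], ignore_index=True)
        import copy
        stim = copy.copy(stimuli_small)
        stim.table = leaky
        with pytest.raises(AssertionError):
            audit_split_purity(stim, dataset_small)
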