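import numpy as np
import pytest

from voxenc.cortex import (AreaSpec, CortexConfig, build_synthetic_cortex,
                           responses_from_signals, simulate_responses,
                           zscore_by_session)
from voxenc.stats import pearson_columns
from voxenc.stimuli import generate_experiment_stimuli

from conftest import RES, small_area_specs


def tiny_config(regime="hierarchical", seed=0, **kw):
    areas = kw.pop("areas", None) or [
        AreaSpec(n_voxels=4, rf_slope=0.1, rf_intercept=3.0),
        AreaSpec(n_voxels=4, rf_slope=0.2, rf_intercept=5.0),
    ]
    return CortexConfig(regime=regime, areas=areas, resolution=RES,
                        seed=seed, **kw)


class TestBuildCortex:
    def test_intercepts_without_jitter_are_exact_at_zero_slope(self):
        areas = [AreaSpec(n_voxels=5, rf_slope=0.0, rf_intercept=ic)
                 for ic in (2.0, 3.0, 4.0, 5.0)]
        cortex = build_synthetic_cortex(tiny_config(areas=areas))
        for ic, area in zip((2.0, 3.0, 4.0, 5.0), (1, 2, 3, 4)):
            sizes = [v.size for v in cortex.voxels if v.area == area]
            assert sizes == [ic] * 5

    def test_parallel_regime_has_exactly_one_stage_per_area(self):
        cortex = build_synthetic_cortex(tiny_config("parallel"))
        assert all(cortex.stage_count(a) == 1 for a in (1, 2))

    def test_hierarchical_stage_count_equals_area_index(self):
        cortex = build_synthetic_cortex(tiny_config("hierarchical"))
        assert [cortex.stage_count(a) for a in (1, 2)] == [1, 2]

    def test_fixed_seed_is_bit_identical(self, stimuli_small):
        a = build_synthetic_cortex(tiny_config(seed=9))
        b = build_synthetic_cortex(tiny_config(seed=9))
        assert [(v.center, v.size) for v in a.voxels] \
            == [(v.center, v.size) for v in b.voxels]
        imgs = stimuli_small.images[:5]
        np.testing.assert_array_equal(a.voxel_signals(imgs),
                                      b.voxel_signals(imgs))

    def test_rejects_bad_configs(self):
        with pytest.raises(ValueError):
            build_synthetic_cortex(tiny_config("serial"))
        with pytest.raises(ValueError):
            build_synthetic_cortex(CortexConfig(
                areas=[AreaSpec(n_voxels=3)], resolution=RES))
        decreasing = [AreaSpec(n_voxels=3, rf_slope=0.3, rf_intercept=5.0),
                      AreaSpec(n_voxels=3, rf_slope=0.1, rf_intercept=2.0)]
        with pytest.raises(ValueError):
            build_synthetic_cortex(tiny_config(areas=decreasing))

    def test_parallel_windows_non_decreasing(self):
        cortex = build_synthetic_cortex(tiny_config("parallel"))
        assert cortex.parallel_windows == sorted(cortex.parallel_windows)


class TestZScoring:
    def test_session_moments(self, dataset_small):
        sessions = dataset_small.trials["session"].to_numpy()
        for s in np.unique(sessions):
            block = dataset_small.betas[sessions == s]
            np.testing.assert_allclose(block.mean(axis=0), 0.0, atol=1e-8)
            np.testing.assert_allclose(block.std(axis=0), 1.0, atol=1e-8)

    def test_idempotence(self, dataset_small):
        sessions = dataset_small.trials["session"].to_numpy()
        twice = zscore_by_session(dataset_small.betas, sessions)
        assert np.abs(twice - dataset_small.betas).max() < 1e-12


class TestSimulateResponses:
    def test_zero_noise_makes_repeats_identical(self, signals_small,
                                                stimuli_small):
        ds = responses_from_signals(signals_small, stimuli_small,
                                    noise_sd=np.zeros(signals_small.shape[1]),
                                    n_repeats=3, n_sessions=1, seed=0)
        by_image = ds.trials.groupby("image_id").groups
        for img, rows in by_image.items():
            if len(rows) > 1:
                block = ds.betas[np.asarray(rows)]
                assert np.abs(block - block[0]).max() < 1e-10

    def test_fixed_seed_reproduces_beta_matrix(self, cortex_hier,
                                               stimuli_small):
        a = simulate_responses(cortex_hier, stimuli_small, seed=3)
        b = simulate_responses(cortex_hier, stimuli_small, seed=3)
        np.testing.assert_array_equal(a.betas, b.betas)

    def test_single_repeat_records_noise_ceiling_warning(self, signals_small,
                                                         stimuli_small):
        ds = responses_from_signals(signals_small, stimuli_small,
                                    noise_sd=np.ones(signals_small.shape[1]),
                                    n_repeats=1, seed=0)
        assert any("noise-ceiling" in w for w in ds.metadata["warnings"])

    def test_shared_images_receive_requested_repeats(self, dataset_small,
                                                     stimuli_small):
        shared = stimuli_small.table.loc[
            stimuli_small.table["split"] == "shared-validation", "image_id"]
        counts = dataset_small.trials["image_id"].value_counts()
        assert all(counts[i] == 3 for i in shared)

    def test_repeat_correlation_monotone_in_noise(self, signals_small,
                                                  stimuli_small):
        """Cross-repeat correlation grows as configured noise shrinks."""
        n_vox = signals_small.shape[1]
        cors = []
        for noise in (2.0, 1.0, 0.3):
            ds = responses_from_signals(
                signals_small, stimuli_small,
                noise_sd=np.full(n_vox, noise), n_repeats=2, n_sessions=1,
                seed=42)
            t = ds.trials.sort_values(["image_id", "repeat"])
            rep = t[t["image_id"].duplicated(keep=False)]
            r0 = rep[rep["repeat"] == 0]["trial"].to_numpy()
            r1 = rep[rep["repeat"] == 1]["trial"].to_numpy()
            cors.append(pearson_columns(ds.betas[r0], ds.betas[r1]).mean())
        assert cors[0] < cors[1] < cors[2]


class TestRegimeSeparability:
    def test_stage1_readout_separates_hierarchy_levels(self):
        """A linear read-out of stage-1 features recovers area-1 signals
        nearly perfectly but area-4 (deep composition) signals strictly
        worse, on noiseless data (overdetermined least-squares oracle)."""
        cortex = build_synthetic_cortex(CortexConfig(
            regime="hierarchical", resolution=RES, seed=21,
            areas=small_area_specs(), gabor_frequencies=(4.0, 8.0)))
        stim = generate_experiment_stimuli(n_train=1400, n_shared=100,
                                           resolution=RES, seed=77)
        signals = cortex.voxel_signals(stim.images)
        areas = np.array([v.area for v in cortex.voxels])
        feats = cortex.stage1_features(stim.images)
        x = feats.reshape(feats.shape[0], -1)
        x = np.column_stack([x, np.ones(len(x))])
        fit, ev = slice(0, 1300), slice(1300, 1500)
        coef, *_ = np.linalg.lstsq(x[fit], signals[fit], rcond=None)
        rho = pearson_columns(signals[ev], x[ev] @ coef)
        rho1 = rho[areas == 1].mean()
        rho4 = rho[areas == 4].mean()
        assert rho1 > 0.99
        assert rho4 < rho1
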