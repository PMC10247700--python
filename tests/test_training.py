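import numpy as np
import pytest

from voxenc.extractors import (GaborBank, GaborBankSpec,
                               default_extractor_spec)
from voxenc.readout import build_gpf_grid
from voxenc.stats import pearson_columns
from voxenc.training import (RidgeConfig, TrainingConfig,
                             batch_correlation_weights, candidate_features,
                             fit_readout_grid_ridge, fine_tune, ridge_solve,
                             train_roiwise, train_single_branch,
                             training_data_from_dataset, weighted_loss)

from conftest import RES


class TestWeightedLoss:
    def test_uniform_weights_reduce_to_mse(self, rng):
        y = rng.normal(size=(16, 10))
        yhat = rng.normal(size=(16, 10))
        loss = weighted_loss(y, yhat, weights=np.ones(10))
        assert loss == pytest.approx(((y - yhat) ** 2).mean(), rel=1e-12)

    def test_hand_computed_two_voxel_case(self):
        y = np.array([[0.0, 0.0]])
        yhat = np.array([[1.0, 2.0]])  # squared errors (1, 4)
        assert weighted_loss(y, yhat, weights=np.array([0.25, 0.75])) \
            == pytest.approx(3.25)

    def test_duplicating_a_voxel_leaves_loss_unchanged(self, rng):
        y = rng.normal(size=(8, 3))
        yhat = rng.normal(size=(8, 3))
        w = np.array([0.3, 0.5, 0.2])
        base = weighted_loss(y, yhat, weights=w)
        y2 = np.column_stack([y, y[:, 0]])
        yhat2 = np.column_stack([yhat, yhat[:, 0]])
        w2 = np.array([0.3, 0.5, 0.2, 0.3])
        # duplicated voxel replaces half the original weight on each copy
        w2[0] /= 2
        w2[3] /= 2
        assert weighted_loss(y2, yhat2, weights=w2) == pytest.approx(base)

    def test_all_zero_weights_rejected(self, rng):
        y = rng.normal(size=(8, 3))
        with pytest.raises(ValueError):
            weighted_loss(y, y + 1, weights=np.zeros(3))

    def test_floor_applies_to_squared_correlation(self, rng):
        y = rng.normal(size=(16, 4))
        w = batch_correlation_weights(y, rng.normal(size=(16, 4)), floor=0.1)
        assert (w >= 0.1).all()
        w_perfect = batch_correlation_weights(y, 2 * y + 1, floor=0.1)
        np.testing.assert_allclose(w_perfect, 1.0, atol=1e-12)

    def test_gradient_matches_finite_difference(self, rng):
        y = rng.normal(size=(8, 3))
        yhat = rng.normal(size=(8, 3))
        w = np.array([0.2, 0.5, 0.9])
        _, grad = weighted_loss(y, yhat, weights=w, return_grad=True)
        eps = 1e-7
        for (i, j) in [(0, 0), (3, 1), (7, 2)]:
            yp = yhat.copy(); yp[i, j] += eps
            ym = yhat.copy(); ym[i, j] -= eps
            num = (weighted_loss(y, yp, weights=w)
                   - weighted_loss(y, ym, weights=w)) / (2 * eps)
            assert grad[i, j] == pytest.approx(num, rel=1e-5, abs=1e-9)


class TestRidge:
    def test_matches_normal_equations_oracle(self, rng):
        x = rng.normal(size=(20, 5))
        y = rng.normal(size=(20, 3))
        for lam in (1e-3, 1.0, 100.0):
            w = ridge_solve(x, y, lam)
            oracle = np.linalg.inv(x.T @ x + lam * np.eye(5)) @ x.T @ y
            np.testing.assert_allclose(w, oracle, atol=1e-8)

    def test_training_residual_monotone_in_penalty(self, rng):
        x = rng.normal(size=(30, 6))
        y = rng.normal(size=(30, 2))
        resid = [np.linalg.norm(y - x @ ridge_solve(x, y, lam))
                 for lam in (0.0, 0.1, 1.0, 10.0, 100.0)]
        assert all(a <= b + 1e-12 for a, b in zip(resid, resid[1:]))

    def test_zero_penalty_recovers_ols_on_noiseless_system(self, rng):
        x = rng.normal(size=(40, 5))
        w_true = rng.normal(size=(5, 2))
        y = x @ w_true
        np.testing.assert_allclose(ridge_solve(x, y, 0.0), w_true, atol=1e-6)


@pytest.fixture(scope="module")
def gabor_features():
    from voxenc.stimuli import generate_stimuli
    stim = generate_stimuli(40, RES, ("composite",), seed=3)
    bank = GaborBank(GaborBankSpec((3.0, 6.0), (0.0, np.pi / 2)), RES)
    maps = bank.forward(stim.images)
    candidates = build_gpf_grid(3, 8.0, 30.0)
    feats = candidate_features(maps, candidates, f_in="log1p_abs")
    return feats, candidates


class TestGridRidgeFit:
    def test_recovers_planted_on_grid_field(self, gabor_features, rng):
        feats, candidates = gabor_features
        true_c = 7
        w_true = rng.normal(size=(feats.shape[2], 3))
        y = feats[true_c] @ w_true
        fit = fit_readout_grid_ridge(feats, y, candidates, seed=0)
        spacing = 1.75 * candidates[true_c].size
        for v in range(3):
            chosen = fit.pooling_field(v)
            dist = np.hypot(chosen.center[0] - candidates[true_c].center[0],
                            chosen.center[1] - candidates[true_c].center[1])
            assert dist <= spacing / 2
            ratio = chosen.size / candidates[true_c].size
            step = (30.0 / 8.0) ** (1 / 2)
            assert 1 / step - 1e-9 <= ratio <= step + 1e-9

    def test_degenerate_voxel_flagged_and_zeroed(self, gabor_features):
        feats, candidates = gabor_features
        y = np.zeros((feats.shape[1], 2))
        y[:, 1] = feats[0] @ np.ones(feats.shape[2])
        fit = fit_readout_grid_ridge(feats, y, candidates, seed=0)
        assert fit.degenerate[0] and not fit.degenerate[1]
        np.testing.assert_array_equal(fit.w[0], 0.0)

    def test_needs_at_least_two_candidates(self, gabor_features):
        feats, candidates = gabor_features
        with pytest.raises(ValueError):
            fit_readout_grid_ridge(feats[:1], np.zeros((feats.shape[1], 1)),
                                   candidates[:1])


@pytest.fixture(scope="module")
def joint_setup(dataset_small_module, stimuli_small_module):
    data = training_data_from_dataset(stimuli_small_module,
                                      dataset_small_module)
    cfg = TrainingConfig(max_epochs=3, patience=3, batch_size=25, seed=5,
                         lr=3e-3, head_lr=1e-2)
    spec = default_extractor_spec(RES, dropout=0.1)
    model, log = train_single_branch(spec, data, cfg)
    return data, cfg, spec, model, log


# module-scoped clones of the session fixtures (cheap indirection)
@pytest.fixture(scope="module")
def stimuli_small_module():
    from voxenc.stimuli import generate_experiment_stimuli
    return generate_experiment_stimuli(n_train=120, n_shared=60,
                                       resolution=RES, seed=11)


@pytest.fixture(scope="module")
def dataset_small_module(stimuli_small_module):
    from conftest import small_area_specs
    from voxenc.cortex import (CortexConfig, build_synthetic_cortex,
                               simulate_responses)
    cortex = build_synthetic_cortex(
        CortexConfig(regime="hierarchical", resolution=RES, seed=21,
                     areas=small_area_specs()))
    return simulate_responses(cortex, stimuli_small_module, n_repeats=3,
                              n_sessions=4, seed=31)


class TestTrainJoint:
    def test_every_sample_seen_exactly_once_per_epoch(self, joint_setup):
        data, cfg, spec, model, log = joint_setup
        per_epoch = log.loc[log["epoch"] > 0, "samples_seen"]
        assert (per_epoch == len(data.train_idx)).all()

    def test_alternation_counts_match_schedule(self, joint_setup):
        data, cfg, spec, model, log = joint_setup
        n_batches = int(np.ceil(len(data.train_idx) / cfg.batch_size))
        body = log[log["epoch"] > 0]
        assert (body["extractor_steps"] == n_batches * cfg.schedule[0]).all()
        assert (body["head_steps"] == n_batches * cfg.schedule[1]).all()

    def test_best_epoch_dominates_log(self, joint_setup):
        _, _, _, _, log = joint_setup
        best = log.attrs["best_holdout_rho"]
        assert (log["holdout_rho"] <= best + 1e-12).all()

    def test_fixed_seed_reproduces_parameters(self, joint_setup):
        data, cfg, spec, model, _ = joint_setup
        again, _ = train_single_branch(spec, data, cfg)
        for pa, pb in zip(model.extractor.params() + model.heads.params(),
                          again.extractor.params() + again.heads.params()):
            np.testing.assert_array_equal(pa.v, pb.v)

    def test_batch_size_floor_enforced(self):
        with pytest.raises(ValueError):
            TrainingConfig(batch_size=4)

    def test_non_finite_targets_abort(self, joint_setup):
        data, cfg, spec, _, _ = joint_setup
        bad = data.select_voxels(np.arange(4))
        bad.y_train = bad.y_train.copy()
        bad.y_train[0, 0] = np.nan
        with pytest.raises(FloatingPointError):
            train_single_branch(spec, bad, cfg)


class TestFineTune:
    def test_phase2_freezes_heads_and_phase3_freezes_extractor(self,
                                                               joint_setup):
        data, cfg, spec, model, _ = joint_setup
        short = TrainingConfig(**{**cfg.__dict__, "max_epochs": 2})
        heads_before = {k: v.copy() for k, v in model.heads.state().items()
                        if k in ("w", "b")}
        log2 = fine_tune(model, data, phase=2, cfg=short)
        np.testing.assert_array_equal(model.heads.w.v, heads_before["w"])
        np.testing.assert_array_equal(model.heads.b.v, heads_before["b"])
        ext_before = [p.v.copy() for p in model.extractor.params()]
        log3 = fine_tune(model, data, phase=3, cfg=short)
        for p, before in zip(model.extractor.params(), ext_before):
            np.testing.assert_array_equal(p.v, before)
        # clamping: each phase's best never undercuts its starting point
        assert log2.attrs["best_holdout_rho"] >= log2["holdout_rho"].iloc[0] - 1e-12
        assert log3.attrs["best_holdout_rho"] >= log3["holdout_rho"].iloc[0] - 1e-12

    def test_invalid_phase_rejected(self, joint_setup):
        data, cfg, _, model, _ = joint_setup
        with pytest.raises(ValueError):
            fine_tune(model, data, phase=1, cfg=cfg)


class TestRoiwise:
    def test_branches_depend_only_on_their_area(self, joint_setup):
        data, cfg, spec, _, _ = joint_setup
        short = TrainingConfig(**{**cfg.__dict__, "max_epochs": 2})
        specs = {a: spec for a in (1, 2)}
        sub = data.select_voxels(np.flatnonzero(np.isin(data.areas, [1, 2])))
        models_a, _ = train_roiwise(specs, sub, short)
        # corrupt area 2's responses; area 1's branch must be bit-identical
        sub2 = data.select_voxels(np.flatnonzero(np.isin(data.areas, [1, 2])))
        sub2.y_train = sub2.y_train.copy()
        sub2.y_train[:, sub2.areas == 2] = \
            -sub2.y_train[:, sub2.areas == 2]
        models_b, _ = train_roiwise(specs, sub2, short)
        for pa, pb in zip(models_a[1].extractor.params(),
                          models_b[1].extractor.params()):
            np.testing.assert_array_equal(pa.v, pb.v)
        np.testing.assert_array_equal(models_a[1].heads.w.v,
                                      models_b[1].heads.w.v)

    def test_branch_models_cover_only_their_voxels(self, joint_setup):
        data, cfg, spec, _, _ = joint_setup
        short = TrainingConfig(**{**cfg.__dict__, "max_epochs": 1})
        models, _ = train_roiwise({1: spec}, data, short)
        assert models[1].heads.n_voxels == int((data.areas == 1).sum())
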