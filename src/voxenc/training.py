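"""Model fitting: correlation-weighted loss, grid-search + ridge read-outs,
joint gradient training with subject interleaving and alternating updates,
ROI-wise branch training, fine-tuning phases, and distillation of a teacher
model's outputs into per-area reference models.

The gradient path minimizes the correlation-weighted squared error

    L = Σ_v ⌊ρ_v²⌋ (r_v − r̄_v)² / Σ_v ⌊ρ_v²⌋,

where ⌊ρ_v²⌋ = max(ρ_v², floor) and ρ_v is the within-minibatch Pearson
correlation between predictions and targets for voxel v, treated as a
constant (no gradient) within the step.  With equal weights the loss reduces
exactly to the mean squared error over voxels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

from .extractors import ConvExtractor, ExtractorSpec, FeatureMaps, default_extractor_spec
from .nn import Adam
from .readout import FlexibleHeadBank, GaussianPoolingField, get_nonlinearity
from .stats import pearson_columns


# ---------------------------------------------------------------------------
# Configs

@dataclass
class TrainingConfig:
    lr: float = 1e-3
    head_lr: float | None = None   # defaults to ``lr``
    beta1: float = 0.9
    beta2: float = 0.999
    batch_size: int = 32
    max_epochs: int = 50
    patience: int = 10
    holdout_fraction: float = 0.10
    loss_floor: float = 0.1
    schedule: tuple[int, int] = (1, 1)  # (extractor steps, head steps) per minibatch
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.holdout_fraction < 1:
            raise ValueError("holdout fraction must be in (0, 1)")
        if not 0 <= self.loss_floor <= 1:
            raise ValueError("loss floor must be in [0, 1]")
        if self.batch_size < 8:
            raise ValueError("batch size must be >= 8 so the batchwise "
                             "correlation weights are well defined")


@dataclass
class RidgeConfig:
    penalties: tuple[float, ...] = tuple(np.geomspace(1e-3, 1e3, 9))
    holdout_fraction: float = 0.10

    def __post_init__(self):
        pens = np.asarray(self.penalties, dtype=float)
        if pens.size == 0 or (pens < 0).any():
            raise ValueError("penalty grid must be nonempty and >= 0")
        self.penalties = tuple(pens)


# ---------------------------------------------------------------------------
# Loss

def batch_correlation_weights(targets: np.ndarray, predictions: np.ndarray,
                              floor: float = 0.1) -> np.ndarray:
    """⌊ρ_v²⌋: squared batchwise Pearson correlation, floored."""
    rho = pearson_columns(targets, predictions)
    return np.maximum(rho * rho, floor)


def weighted_loss(targets: np.ndarray, predictions: np.ndarray,
                  weights: np.ndarray | None = None, floor: float = 0.1,
                  return_grad: bool = False):
    """Correlation-weighted squared-error loss (optionally with gradient).

    ``weights`` defaults to the batchwise ⌊ρ_v²⌋ computed from the inputs.
    The returned gradient is with respect to the predictions, with the
    weights treated as constants.
    """
    targets = np.atleast_2d(np.asarray(targets, dtype=np.float64))
    predictions = np.atleast_2d(np.asarray(predictions, dtype=np.float64))
    if targets.shape != predictions.shape:
        raise ValueError("targets and predictions must have the same shape")
    if weights is None:
        weights = batch_correlation_weights(targets, predictions, floor)
    weights = np.asarray(weights, dtype=np.float64)
    wsum = weights.sum()
    if wsum <= 0:
        raise ValueError("all-zero weights with floor 0 leave the loss "
                         "undefined; use a positive floor")
    se = (targets - predictions) ** 2
    loss = float((weights * se.mean(axis=0)).sum() / wsum)
    if not return_grad:
        return loss
    grad = 2.0 * weights[None, :] * (predictions - targets) / (se.shape[0] * wsum)
    return loss, grad


# ---------------------------------------------------------------------------
# Data plumbing

@dataclass
class TrainingData:
    """Per-subject arrays the trainers consume.

    ``images`` is the full stimulus stack; the three ``*_idx`` arrays map
    trials of each split to rows of ``images`` (repeats appear as separate
    trials).  ``voxel_index`` records which columns of the source dataset the
    targets correspond to; ``areas`` carries per-voxel area labels.
    """

    images: np.ndarray
    train_idx: np.ndarray
    y_train: np.ndarray
    holdout_idx: np.ndarray
    y_holdout: np.ndarray
    val_idx: np.ndarray
    y_val: np.ndarray
    areas: np.ndarray | None = None
    voxel_index: np.ndarray | None = None

    @property
    def n_voxels(self) -> int:
        return self.y_train.shape[1]

    def select_voxels(self, cols: np.ndarray) -> "TrainingData":
        return TrainingData(self.images, self.train_idx, self.y_train[:, cols],
                            self.holdout_idx, self.y_holdout[:, cols],
                            self.val_idx, self.y_val[:, cols],
                            None if self.areas is None else self.areas[cols],
                            np.asarray(cols))


def training_data_from_dataset(stimuli, dataset,
                               voxel_cols: np.ndarray | None = None) -> TrainingData:
    """Split a ResponseDataset's trials by the stimulus split labels."""
    id_to_row = {int(i): r for r, i in enumerate(stimuli.table["image_id"])}
    image_row = np.array([id_to_row[int(i)] for i in dataset.trials["image_id"]])
    split_of_row = stimuli.table["split"].to_numpy()
    trial_split = split_of_row[image_row]
    betas = dataset.betas
    areas = dataset.voxels["area"].to_numpy()
    if voxel_cols is not None:
        betas = betas[:, voxel_cols]
        areas = areas[voxel_cols]
    parts = {}
    for name in ("train", "holdout", "shared-validation"):
        t = np.flatnonzero(trial_split == name)
        parts[name] = (image_row[t], betas[t])
    return TrainingData(stimuli.images,
                        *parts["train"], *parts["holdout"],
                        *parts["shared-validation"],
                        areas=areas, voxel_index=voxel_cols)


def training_data_from_outputs(stimuli, outputs_by_image: np.ndarray,
                               areas: np.ndarray | None = None) -> TrainingData:
    """Treat a model's noiseless per-image outputs as synthetic brain data."""
    parts = {}
    for name in ("train", "holdout", "shared-validation"):
        idx = stimuli.indices(name)
        parts[name] = (idx, outputs_by_image[idx])
    return TrainingData(stimuli.images,
                        *parts["train"], *parts["holdout"],
                        *parts["shared-validation"], areas=areas)


# ---------------------------------------------------------------------------
# Encoding model container

@dataclass
class EncodingModel:
    """A feature extractor plus a bank of per-voxel read-out heads."""

    extractor: ConvExtractor
    heads: FlexibleHeadBank
    areas: np.ndarray | None = None

    def predict(self, images: np.ndarray, batch_size: int = 64,
                weight_mask: np.ndarray | None = None) -> np.ndarray:
        images = np.asarray(images, dtype=np.float64)
        out = []
        for s in range(0, len(images), batch_size):
            maps = self.extractor.forward(images[s:s + batch_size], train=False)
            out.append(self.heads.forward(maps, weight_mask=weight_mask))
        return np.concatenate(out, axis=0)

    def state(self) -> dict:
        return {"extractor": self.extractor.state(), "heads": self.heads.state()}

    def load_state(self, state: dict) -> None:
        self.extractor.load_state(state["extractor"])
        self.heads.load_state(state["heads"])


# ---------------------------------------------------------------------------
# Gradient training

def _holdout_rho(extractor, heads_and_data: list, batch_size: int = 64) -> float:
    rhos = []
    for heads, data in heads_and_data:
        if len(data.holdout_idx) == 0:
            raise ValueError("training data has no holdout trials")
        preds = []
        imgs = data.images[data.holdout_idx]
        for s in range(0, len(imgs), batch_size):
            maps = extractor.forward(imgs[s:s + batch_size], train=False)
            preds.append(heads.forward(maps))
        rhos.append(pearson_columns(data.y_holdout, np.concatenate(preds)))
    return float(np.mean(np.concatenate(rhos)))


def train_joint(extractor: ConvExtractor,
                heads_by_subject: dict[str, FlexibleHeadBank],
                data_by_subject: dict[str, "TrainingData"],
                cfg: TrainingConfig) -> pd.DataFrame:
    """Jointly train a shared extractor and per-subject read-out heads.

    Subject-interleaved minibatches: per epoch every training sample of every
    subject is consumed exactly once, in a seeded shuffled order of
    (subject, minibatch) pairs.  Extractor and head updates alternate per the
    configured schedule.  After each epoch the holdout accuracy is evaluated;
    at termination (early stopping with patience) parameters are clamped to
    the best-holdout state.  Returns the per-epoch training log.
    """
    if set(heads_by_subject) != set(data_by_subject):
        raise ValueError("subjects of heads and data must match")
    for s, d in data_by_subject.items():
        if len(d.train_idx) == 0:
            raise ValueError(f"subject {s}: empty training set")

    rng = np.random.default_rng(cfg.seed)
    extractor.set_train_rng(np.random.default_rng(rng.integers(2 ** 31)))
    head_lr = cfg.head_lr if cfg.head_lr is not None else cfg.lr
    opt_ext = Adam(extractor.params(), cfg.lr, cfg.beta1, cfg.beta2)
    opt_heads = {s: Adam(h.params(), head_lr, cfg.beta1, cfg.beta2)
                 for s, h in heads_by_subject.items()}
    pairs = [(heads_by_subject[s], data_by_subject[s])
             for s in sorted(data_by_subject)]

    def snapshot():
        return {"ext": extractor.state(),
                "heads": {s: h.state() for s, h in heads_by_subject.items()}}

    def restore(state):
        extractor.load_state(state["ext"])
        for s, h in heads_by_subject.items():
            h.load_state(state["heads"][s])

    best_rho = _holdout_rho(extractor, pairs)
    best_state = snapshot()
    best_epoch = 0
    wait = 0
    log_rows = [{"epoch": 0, "train_loss": np.nan, "holdout_rho": best_rho,
                 "extractor_steps": 0, "head_steps": 0, "samples_seen": 0}]

    for epoch in range(1, cfg.max_epochs + 1):
        batches = []
        for s in sorted(data_by_subject):
            d = data_by_subject[s]
            perm = rng.permutation(len(d.train_idx))
            n_chunks = max(1, int(np.ceil(len(perm) / cfg.batch_size)))
            for chunk in np.array_split(perm, n_chunks):
                batches.append((s, chunk))
        order = rng.permutation(len(batches))
        ext_steps = head_steps = samples = 0
        losses = []
        for bi in order:
            s, idx = batches[bi]
            d = data_by_subject[s]
            heads = heads_by_subject[s]
            x = d.images[d.train_idx[idx]]
            y = d.y_train[idx]
            samples += len(idx)
            for _ in range(cfg.schedule[0]):
                loss = _grad_pass(extractor, heads, x, y, cfg,
                                  opt_ext=opt_ext, opt_heads=None)
                ext_steps += 1
            for _ in range(cfg.schedule[1]):
                loss = _grad_pass(extractor, heads, x, y, cfg,
                                  opt_ext=None, opt_heads=opt_heads[s])
                head_steps += 1
            losses.append(loss)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}; aborting")
        # pooling-field constraints hold by construction; assert each epoch
        for heads, _ in pairs:
            for g in heads.effective_grids().values():
                assert (g >= 0).all()
                assert np.allclose(g.sum(axis=(1, 2)), 1.0, atol=1e-9)
        rho = _holdout_rho(extractor, pairs)
        log_rows.append({"epoch": epoch, "train_loss": float(np.mean(losses)),
                         "holdout_rho": rho, "extractor_steps": ext_steps,
                         "head_steps": head_steps, "samples_seen": samples})
        if rho > best_rho:
            best_rho, best_state, best_epoch, wait = rho, snapshot(), epoch, 0
        else:
            wait += 1
            if wait >= cfg.patience:
                break
    restore(best_state)
    log = pd.DataFrame(log_rows)
    log.attrs["best_epoch"] = best_epoch
    log.attrs["best_holdout_rho"] = best_rho
    return log


def _grad_pass(extractor, heads, x, y, cfg, opt_ext=None, opt_heads=None) -> float:
    """One forward/backward pass updating either the extractor or the heads."""
    for p in extractor.params():
        p.zero_grad()
    for p in heads.params():
        p.zero_grad()
    maps = extractor.forward(x, train=True)
    rbar = heads.forward(maps)
    loss, grad = weighted_loss(y, rbar, floor=cfg.loss_floor, return_grad=True)
    d_maps = heads.backward(grad, need_map_grads=opt_ext is not None)
    if opt_ext is not None:
        extractor.backward(d_maps)
        opt_ext.step()
    if opt_heads is not None:
        opt_heads.step()
    return loss


def train_single_branch(spec: ExtractorSpec | None, data: TrainingData,
                        cfg: TrainingConfig, f_in: str = "tanh_log",
                        f_out: str = "tanh_log",
                        subject: str = "S1") -> tuple[EncodingModel, pd.DataFrame]:
    """Convenience wrapper: one subject, one branch, fresh heads."""
    if spec is None:
        spec = default_extractor_spec(data.images.shape[-1])
    extractor = ConvExtractor(spec, seed=cfg.seed)
    heads = FlexibleHeadBank(extractor.layer_shapes(), data.n_voxels,
                             f_in=f_in, f_out=f_out, seed=cfg.seed + 1)
    log = train_joint(extractor, {subject: heads}, {subject: data}, cfg)
    return EncodingModel(extractor, heads, areas=data.areas), log


def train_roiwise(branch_specs: dict[int, ExtractorSpec | None],
                  data: TrainingData, cfg: TrainingConfig,
                  f_in: str = "tanh_log", f_out: str = "tanh_log"
                  ) -> tuple[dict[int, EncodingModel], dict[int, pd.DataFrame]]:
    """Train one independent branch per area on that area's voxels only."""
    if data.areas is None:
        raise ValueError("ROI-wise training needs per-voxel area labels")
    models, logs = {}, {}
    for area in sorted(branch_specs):
        cols = np.flatnonzero(data.areas == area)
        if cols.size == 0:
            raise ValueError(f"no voxels in area {area}")
        sub = data.select_voxels(cols)
        branch_cfg = TrainingConfig(**{**cfg.__dict__,
                                       "seed": cfg.seed + 101 * area})
        models[area], logs[area] = train_single_branch(
            branch_specs[area], sub, branch_cfg, f_in=f_in, f_out=f_out)
    return models, logs


# ---------------------------------------------------------------------------
# Head-only training on a frozen extractor (cached feature maps)

def train_heads_frozen(extractor: ConvExtractor, data: TrainingData,
                       cfg: TrainingConfig, f_in: str = "tanh_log",
                       f_out: str = "tanh_log",
                       heads: FlexibleHeadBank | None = None
                       ) -> tuple[FlexibleHeadBank, pd.DataFrame]:
    """Train fresh read-out heads on a frozen extractor.

    Feature maps for all needed images are computed once in evaluation mode
    and cached, so head updates are cheap.
    """
    extractor.freeze(True)
    used = np.unique(np.concatenate([data.train_idx, data.holdout_idx]))
    pos = {int(i): k for k, i in enumerate(used)}
    cache: dict[str, np.ndarray] = {}
    for s in range(0, len(used), 64):
        maps = extractor.forward(data.images[used[s:s + 64]], train=False)
        for lid, v in maps.layers.items():
            cache.setdefault(lid, []).append(v)
    cache = {lid: np.concatenate(vs) for lid, vs in cache.items()}
    if heads is None:
        heads = FlexibleHeadBank(extractor.layer_shapes(), data.n_voxels,
                                 f_in=f_in, f_out=f_out, seed=cfg.seed + 1)

    rng = np.random.default_rng(cfg.seed)
    head_lr = cfg.head_lr if cfg.head_lr is not None else cfg.lr
    opt = Adam(heads.params(), head_lr, cfg.beta1, cfg.beta2)
    tr_rows = np.array([pos[int(i)] for i in data.train_idx])
    ho_rows = np.array([pos[int(i)] for i in data.holdout_idx])

    def holdout_rho():
        preds = heads.forward({lid: v[ho_rows] for lid, v in cache.items()})
        return float(pearson_columns(data.y_holdout, preds).mean())

    best_rho = holdout_rho()
    best_state = heads.state()
    best_epoch, wait = 0, 0
    rows = [{"epoch": 0, "train_loss": np.nan, "holdout_rho": best_rho}]
    for epoch in range(1, cfg.max_epochs + 1):
        perm = rng.permutation(len(tr_rows))
        n_chunks = max(1, int(np.ceil(len(perm) / cfg.batch_size)))
        losses = []
        for chunk in np.array_split(perm, n_chunks):
            sub = {lid: v[tr_rows[chunk]] for lid, v in cache.items()}
            y = data.y_train[chunk]
            for p in heads.params():
                p.zero_grad()
            rbar = heads.forward(sub)
            loss, grad = weighted_loss(y, rbar, floor=cfg.loss_floor,
                                       return_grad=True)
            heads.backward(grad, need_map_grads=False)
            opt.step()
            losses.append(loss)
        rho = holdout_rho()
        rows.append({"epoch": epoch, "train_loss": float(np.mean(losses)),
                     "holdout_rho": rho})
        if rho > best_rho:
            best_rho, best_state, best_epoch, wait = rho, heads.state(), epoch, 0
        else:
            wait += 1
            if wait >= cfg.patience:
                break
    heads.load_state(best_state)
    log = pd.DataFrame(rows)
    log.attrs["best_epoch"] = best_epoch
    log.attrs["best_holdout_rho"] = best_rho
    return heads, log


# ---------------------------------------------------------------------------
# Fine-tuning phases

def fine_tune(model: EncodingModel, data: TrainingData, phase: int,
              cfg: TrainingConfig, subject: str = "S1") -> pd.DataFrame:
    """Phase 2 freezes all head parameters and trains the extractor
    (including the prefilter); phase 3 freezes the extractor and trains the
    heads.  Each phase restarts from the current (previous phase's best)
    weights and clamps to its own best-holdout state, so the best holdout
    accuracy never decreases across phases.
    """
    if phase not in (2, 3):
        raise ValueError("fine-tuning phase must be 2 or 3")
    if phase == 2:
        model.heads.freeze(True)
        model.extractor.freeze(False)
        schedule = (1, 0)
    else:
        model.extractor.freeze(True)
        model.heads.freeze(False)
        schedule = (0, 1)
    phase_cfg = TrainingConfig(**{**cfg.__dict__, "schedule": schedule})
    log = train_joint(model.extractor, {subject: model.heads},
                      {subject: data}, phase_cfg)
    model.heads.freeze(False)
    model.extractor.freeze(False)
    return log


# ---------------------------------------------------------------------------
# Distillation into per-area reference models

def distill_reference(teacher_outputs: dict[int, np.ndarray], stimuli,
                      cfg: TrainingConfig,
                      branch_specs: dict[int, ExtractorSpec | None] | None = None,
                      f_in: str = "tanh_log", f_out: str = "tanh_log"
                      ) -> dict[int, dict]:
    """Copy a teacher's per-area outputs into independent one-branch models.

    ``teacher_outputs[area]`` is the teacher's noiseless per-image output
    matrix (n_images, n_area_voxels).  For each area an independent branch is
    trained against those outputs; the held-out output correlation ρ_ref of
    every voxel is recorded from the shared-validation images.
    """
    results = {}
    for area in sorted(teacher_outputs):
        outputs = teacher_outputs[area]
        data = training_data_from_outputs(stimuli, outputs)
        spec = None if branch_specs is None else branch_specs.get(area)
        area_cfg = TrainingConfig(**{**cfg.__dict__, "seed": cfg.seed + 17 * area})
        model, log = train_single_branch(spec, data, area_cfg,
                                         f_in=f_in, f_out=f_out)
        preds_val = model.predict(data.images[data.val_idx])
        rho_ref = pearson_columns(data.y_val, preds_val)
        results[area] = {"model": model, "rho_ref": rho_ref, "log": log,
                         "data": data}
    return results


# ---------------------------------------------------------------------------
# Grid-search + ridge fitting for Gaussian-pooling-field heads

def ridge_solve(x: np.ndarray, y: np.ndarray, penalty: float) -> np.ndarray:
    """Multi-target ridge weights via the Gram system (X'X + λI) W = X'Y."""
    k = x.shape[1]
    gram = x.T @ x + penalty * np.eye(k)
    try:
        c = cho_factor(gram)
        return cho_solve(c, x.T @ y)
    except np.linalg.LinAlgError:
        return np.linalg.lstsq(gram, x.T @ y, rcond=None)[0]


def candidate_features(maps: FeatureMaps | dict,
                       candidates: list[GaussianPoolingField],
                       f_in: str = "identity") -> np.ndarray:
    """Pooled features for every candidate pooling field: (P, N, K)."""
    fin, _ = get_nonlinearity(f_in)
    layers = maps.layers if hasattr(maps, "layers") else maps
    parts = []
    for vals in layers.values():
        res = vals.shape[-1]
        grids = np.stack([c.raster(res) for c in candidates])
        parts.append(np.einsum("bchw,phw->pbc", fin(vals), grids,
                               optimize=True))
    return np.concatenate(parts, axis=2)


@dataclass
class GridRidgeFit:
    """Per-voxel grid-search + ridge solution."""

    w: np.ndarray                 # (V, K) on standardized features
    b: np.ndarray                 # (V,)
    candidate_index: np.ndarray   # (V,)
    penalty: np.ndarray           # (V,)
    selection_rho: np.ndarray     # (V,) holdout accuracy of the chosen pair
    degenerate: np.ndarray        # (V,) zero-variance targets flagged
    candidates: list[GaussianPoolingField]
    feature_mean: np.ndarray      # (V, K) standardization of the chosen candidate
    feature_sd: np.ndarray        # (V, K)

    def pooling_field(self, voxel: int) -> GaussianPoolingField:
        return self.candidates[int(self.candidate_index[voxel])]

    def predict(self, features: np.ndarray) -> np.ndarray:
        """features: (P, N, K) candidate features for new images -> (N, V)."""
        n = features.shape[1]
        out = np.empty((n, len(self.b)))
        for v in range(len(self.b)):
            x = (features[self.candidate_index[v]] - self.feature_mean[v]) \
                / self.feature_sd[v]
            out[:, v] = x @ self.w[v] + self.b[v]
        return out


def fit_readout_grid_ridge(features: np.ndarray, responses: np.ndarray,
                           candidates: list[GaussianPoolingField],
                           ridge: RidgeConfig | None = None,
                           seed: int = 0) -> GridRidgeFit:
    """Grid search over candidate pooling fields with ridge tuning weights.

    For each voxel the (candidate, penalty) pair maximizing Pearson accuracy
    on a held-out fraction of the training images is selected (ties broken by
    smaller pooling-field size, then larger penalty), and the weights are
    refit on the full training split at the chosen penalty.  Features are
    standardized per candidate using training-split moments.
    """
    ridge = ridge or RidgeConfig()
    p, n, k = features.shape
    if p != len(candidates):
        raise ValueError("features first axis must match candidate list")
    if p < 2:
        raise ValueError("need at least 2 candidate pooling fields")
    v = responses.shape[1]
    rng = np.random.default_rng(seed)
    n_sel = max(1, int(round(ridge.holdout_fraction * n)))
    if n - n_sel < k + 1 and n - n_sel < 2:
        raise ValueError("training set too small to split for selection")
    sel = np.zeros(n, dtype=bool)
    sel[rng.choice(n, size=n_sel, replace=False)] = True
    fit_rows, sel_rows = ~sel, sel

    y = np.asarray(responses, dtype=np.float64)
    degenerate = y.var(axis=0) <= 1e-300

    best_rho = np.full(v, -np.inf)
    best_cand = np.zeros(v, dtype=int)
    best_pen = np.zeros(v)

    # candidates in size-ascending (stable) order; penalties descending, so a
    # strict improvement rule implements the tie-break (smaller size, then
    # larger penalty wins ties).
    order = np.argsort([c.size for c in candidates], kind="stable")
    penalties = sorted(ridge.penalties, reverse=True)
    yf = y[fit_rows]
    ymean = yf.mean(axis=0)
    yc = yf - ymean
    ysel = y[sel_rows]
    for ci in order:
        x = features[ci]
        mu = x[fit_rows].mean(axis=0)
        sd = x[fit_rows].std(axis=0)
        sd = np.where(sd < 1e-12, 1.0, sd)
        xs = (x - mu) / sd
        xf, xv = xs[fit_rows], xs[sel_rows]
        xty = xf.T @ yc
        gram = xf.T @ xf
        for pen in penalties:
            try:
                w = cho_solve(cho_factor(gram + pen * np.eye(k)), xty)
            except np.linalg.LinAlgError:
                w = np.linalg.lstsq(gram + pen * np.eye(k), xty, rcond=None)[0]
            preds = xv @ w + ymean
            rho = pearson_columns(ysel, preds)
            better = rho > best_rho
            best_cand[better] = ci
            best_pen[better] = pen
            best_rho[better] = rho[better]

    # refit on the full training split at the chosen (candidate, penalty)
    w_out = np.zeros((v, k))
    b_out = np.zeros(v)
    mu_out = np.zeros((v, k))
    sd_out = np.ones((v, k))
    ymean_all = y.mean(axis=0)
    for ci, pen in {(int(c), float(pe)) for c, pe in zip(best_cand, best_pen)}:
        cols = np.flatnonzero((best_cand == ci) & (best_pen == pen)
                              & ~degenerate)
        if cols.size == 0:
            continue
        x = features[ci]
        mu = x.mean(axis=0)
        sd = x.std(axis=0)
        sd = np.where(sd < 1e-12, 1.0, sd)
        xs = (x - mu) / sd
        w = ridge_solve(xs, y[:, cols] - ymean_all[cols], pen)
        w_out[cols] = w.T
        b_out[cols] = ymean_all[cols]
        mu_out[cols] = mu
        sd_out[cols] = sd
    best_rho[degenerate] = 0.0
    return GridRidgeFit(w_out, b_out, best_cand, best_pen, best_rho,
                        degenerate, list(candidates), mu_out, sd_out)
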