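"""Synthetic multi-area visual cortex with a controllable hierarchy regime.

The generator produces per-voxel ground truth (pooling field, tuning weights,
noise) on top of per-area feature banks built in one of two regimes:

* ``hierarchical``: area m's bank is a composition of exactly m nonlinear
  stages.  Stage 1 is a Gabor-energy stage (oriented bandpass amplitude
  followed by local 2x average pooling); each later stage applies rectified
  linear mixtures of the previous stage's maps followed by local 2x average
  pooling, so both feature complexity and integration windows grow with area.
* ``parallel``: every area's bank applies exactly one nonlinear stage
  (rectified area-specific mixtures of Gabor energy) and areas differ only in
  the extent of a subsequent *linear* smoothing window and in feature mixing,
  never in stage count.  Integration windows still grow from area 1 to A, so
  both regimes express an integration hierarchy, but only the hierarchical
  regime composes nonlinear stages.

Voxel responses are simulated as
``beta = z-score_by_session(signal + Gaussian noise)``, with per-voxel signal
standardized over the stimulus ensemble so that configured signal/noise
standard deviations translate directly into repeat-based noise ceilings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter

from .filters import FilterBank
from .readout import GaussianPoolingField
from .stimuli import StimulusSet

REGIMES = ("hierarchical", "parallel")


# ---------------------------------------------------------------------------
# Ground-truth types

@dataclass
class VoxelGroundTruth:
    area: int                      # 1-based area index
    center: tuple[float, float]    # (x, y) % of span, center-origin
    size: float                    # pooling-field std, % of span
    weights: np.ndarray            # tuning over the area's feature bank
    noise_sd: float                # response units

    def __post_init__(self):
        if self.size <= 0:
            raise ValueError("ground-truth pooling-field size must be > 0")
        if max(abs(self.center[0]), abs(self.center[1])) > 50:
            raise ValueError("ground-truth center must lie within the frame")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")
        self.weights = np.asarray(self.weights, dtype=np.float64)


@dataclass
class AreaSpec:
    n_voxels: int = 100
    rf_slope: float = 0.15        # size = slope*ecc + intercept + jitter (% span)
    rf_intercept: float = 3.0
    rf_jitter_sd: float = 0.0
    noise_sd: float = 1.0
    ecc_max: float = 35.0


@dataclass
class CortexConfig:
    regime: str = "hierarchical"
    areas: list[AreaSpec] = field(default_factory=lambda: [
        AreaSpec(rf_slope=0.10, rf_intercept=2.0),
        AreaSpec(rf_slope=0.15, rf_intercept=3.5),
        AreaSpec(rf_slope=0.22, rf_intercept=5.5),
        AreaSpec(rf_slope=0.30, rf_intercept=8.0),
    ])
    resolution: int = 64
    n_gabor_orientations: int = 4
    gabor_frequencies: tuple[float, ...] = (3.0, 6.0, 12.0)
    signal_sd: float = 1.0
    #: weight of the random component in stage mixing matrices; the
    #: remainder is the identity, so composed stages drift gradually away
    #: from the Gabor-energy substrate instead of scrambling it outright
    mix_beta: float = 0.5
    #: feature-bank maps are not downsampled below this resolution; further
    #: stages use resolution-preserving local average pooling instead
    min_bank_resolution: int = 6
    seed: int = 0


class _GaborEnergyStage:
    """Fixed oriented-energy first stage shared by both regimes."""

    def __init__(self, resolution: int, orientations: int,
                 frequencies: tuple[float, ...]):
        from skimage.filters import gabor_kernel
        self.resolution = resolution
        kernels = [np.asarray(gabor_kernel(frequency=f / resolution, theta=t))
                   for f in frequencies
                   for t in (np.arange(orientations) * np.pi / orientations)]
        self._bank = FilterBank(kernels, resolution)

    @property
    def n_channels(self):
        return self._bank.n_channels

    def apply(self, images: np.ndarray) -> np.ndarray:
        out = self._bank.energy(np.asarray(images, dtype=np.float64))
        return _avgpool2(out)


def _rectified_mix(feats: np.ndarray, mix: np.ndarray) -> np.ndarray:
    """Rectified linear combination of feature maps.

    The combination includes subtraction of the per-image spatial mean, so
    roughly half of each map is rectified away and the stage is genuinely
    nonlinear (a plain ReLU of nonnegative energy maps would be nearly
    linear, making composed stages trivially readable from shallow ones).
    """
    h = np.einsum("dc,nchw->ndhw", mix, feats, optimize=True)
    h -= h.mean(axis=(2, 3), keepdims=True)
    return np.maximum(h, 0.0)


def _avgpool2(x: np.ndarray) -> np.ndarray:
    b, c, h, w = x.shape
    if h % 2 or w % 2:  # edge-pad odd dims so deep stages work at any size
        x = np.pad(x, ((0, 0), (0, 0), (0, h % 2), (0, w % 2)), mode="edge")
        b, c, h, w = x.shape
    return x.reshape(b, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5))


@dataclass
class SyntheticCortex:
    """Per-area feature banks plus per-voxel ground truth."""

    config: CortexConfig
    voxels: list[VoxelGroundTruth]
    mix_matrices: list[np.ndarray]     # per area (hierarchical: per stage)
    parallel_windows: list[int] | None  # smoothing extents, parallel regime

    def __post_init__(self):
        self._stage1 = _GaborEnergyStage(self.config.resolution,
                                         self.config.n_gabor_orientations,
                                         self.config.gabor_frequencies)

    @property
    def n_areas(self) -> int:
        return len(self.config.areas)

    @property
    def regime(self) -> str:
        return self.config.regime

    def stage_count(self, area: int) -> int:
        """Number of nonlinear stages composed by area ``area`` (1-based)."""
        return area if self.regime == "hierarchical" else 1

    def area_line(self, area: int) -> tuple[float, float]:
        spec = self.config.areas[area - 1]
        return spec.rf_slope, spec.rf_intercept

    # -- feature banks ------------------------------------------------------
    def stage1_features(self, images: np.ndarray) -> np.ndarray:
        return self._stage1.apply(np.asarray(images, dtype=np.float64))

    def area_features(self, images: np.ndarray, area: int) -> np.ndarray:
        """Ground-truth feature maps of one area's bank, (N, C, H, W)."""
        feats = self.stage1_features(images)
        min_res = self.config.min_bank_resolution
        if self.regime == "hierarchical":
            for stage in range(2, area + 1):
                feats = _rectified_mix(feats, self.mix_matrices[stage - 2])
                if feats.shape[-1] // 2 >= min_res:
                    feats = _avgpool2(feats)
                else:  # resolution floor: local pooling without downsampling
                    feats = uniform_filter(feats, size=(1, 1, 2, 2),
                                           mode="nearest")
        else:
            feats = _rectified_mix(feats, self.mix_matrices[area - 1])
            win = self.parallel_windows[area - 1]
            if win > 1:
                feats = uniform_filter(feats, size=(1, 1, win, win),
                                       mode="nearest")
        return feats

    # -- ground-truth signals ------------------------------------------------
    def voxel_signals(self, images: np.ndarray) -> np.ndarray:
        """Noiseless, standardized per-voxel signals, (N, V).

        signal_v = tuning_v · (pooled area features), standardized over the
        image ensemble and scaled to the configured signal sd.
        """
        images = np.asarray(images, dtype=np.float64)
        n = images.shape[0]
        out = np.empty((n, len(self.voxels)))
        by_area: dict[int, list[int]] = {}
        for vi, v in enumerate(self.voxels):
            by_area.setdefault(v.area, []).append(vi)
        for area, vids in sorted(by_area.items()):
            feats = self.area_features(images, area)
            res = feats.shape[-1]
            grids = np.stack([GaussianPoolingField(self.voxels[vi].center,
                                                   self.voxels[vi].size).raster(res)
                              for vi in vids])
            pooled = np.einsum("nchw,vhw->nvc", feats, grids, optimize=True)
            w = np.stack([self.voxels[vi].weights for vi in vids])
            sig = np.einsum("nvc,vc->nv", pooled, w, optimize=True)
            out[:, vids] = sig
        mu = out.mean(axis=0)
        sd = out.std(axis=0)
        sd[sd < 1e-12] = 1.0
        return (out - mu) / sd * self.config.signal_sd

    def voxel_table(self) -> pd.DataFrame:
        rows = []
        for vi, v in enumerate(self.voxels):
            rows.append({"voxel": vi, "area": v.area, "x": v.center[0],
                         "y": v.center[1], "size": v.size,
                         "noise_sd": v.noise_sd})
        return pd.DataFrame(rows)


def build_synthetic_cortex(config: CortexConfig) -> SyntheticCortex:
    """Construct the ground-truth cortex for the configured regime."""
    if config.regime not in REGIMES:
        raise ValueError(f"unknown regime {config.regime!r}; "
                         f"choose from {REGIMES}")
    if len(config.areas) < 2:
        raise ValueError("need at least 2 areas")
    if any(a.n_voxels < 1 for a in config.areas):
        raise ValueError("every area needs at least 1 voxel")
    for lo, hi in zip(config.areas[:-1], config.areas[1:]):
        if hi.rf_slope < lo.rf_slope or hi.rf_intercept < lo.rf_intercept:
            raise ValueError("per-area RF size lines must have non-decreasing "
                             "slope and intercept from area 1 upward")
    for ai, a in enumerate(config.areas, start=1):
        if a.rf_slope * 0 + a.rf_intercept <= 0 and a.rf_slope <= 0:
            raise ValueError(f"area {ai} RF line is non-positive in-field")

    rng = np.random.default_rng(config.seed)
    stage1 = _GaborEnergyStage(config.resolution, config.n_gabor_orientations,
                               config.gabor_frequencies)
    c = stage1.n_channels
    n_areas = len(config.areas)
    beta = config.mix_beta

    def draw_mix():
        g = rng.normal(0, 1.0 / np.sqrt(c), size=(c, c))
        return (1.0 - beta) * np.eye(c) + beta * g

    if config.regime == "hierarchical":
        # one mixing matrix per composed stage (stage 2..A)
        mixes = [draw_mix() for _ in range(n_areas - 1)]
        windows = None
    else:
        mixes = [draw_mix() for _ in range(n_areas)]
        # modest odd smoothing windows, non-decreasing with area index; every
        # area gets some smoothing so single-stage targets are comparably
        # learnable across areas
        windows = [3 + 2 * ((m - 1) // 2) for m in range(1, n_areas + 1)]

    voxels: list[VoxelGroundTruth] = []
    for ai, spec in enumerate(config.areas, start=1):
        if config.regime == "hierarchical":
            n_ch = c  # channel count preserved by square mixes
        else:
            n_ch = c
        for _ in range(spec.n_voxels):
            for _attempt in range(100):
                ecc = spec.ecc_max * np.sqrt(rng.random())
                theta = rng.uniform(0, 2 * np.pi)
                center = (float(ecc * np.cos(theta)), float(ecc * np.sin(theta)))
                size = spec.rf_slope * ecc + spec.rf_intercept
                if spec.rf_jitter_sd > 0:
                    size += rng.normal(0, spec.rf_jitter_sd)
                if size > 0:
                    break
            else:
                raise ValueError(
                    f"area {ai}: could not draw a positive RF size; the "
                    "configured line is non-positive over the field")
            weights = rng.normal(0, 1, size=n_ch)
            voxels.append(VoxelGroundTruth(ai, center, float(size), weights,
                                           float(spec.noise_sd)))
    return SyntheticCortex(config, voxels, mixes, windows)


# ---------------------------------------------------------------------------
# Response simulation

@dataclass
class ResponseDataset:
    """Trials x voxels betas with trial/voxel metadata and optional ground truth."""

    betas: np.ndarray
    trials: pd.DataFrame        # trial -> image_id, subject, session, repeat
    voxels: pd.DataFrame        # voxel -> area, subject (+ ground-truth cols)
    subject: str = "S1"
    signal: np.ndarray | None = None    # noiseless per-trial signals (pre z-score)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.betas.shape[0] != len(self.trials):
            raise ValueError("betas rows must match trial table")
        if self.betas.shape[1] != len(self.voxels):
            raise ValueError("betas columns must match voxel table")

    @property
    def n_voxels(self) -> int:
        return self.betas.shape[1]

    def trial_indices(self, split: str, stimuli: StimulusSet) -> np.ndarray:
        ids = set(stimuli.table.loc[stimuli.table["split"] == split, "image_id"])
        mask = self.trials["image_id"].isin(ids).to_numpy()
        return np.flatnonzero(mask)


def zscore_by_session(betas: np.ndarray, sessions: np.ndarray) -> np.ndarray:
    """Z-score each voxel within each session (population sd)."""
    out = np.array(betas, dtype=np.float64, copy=True)
    for s in np.unique(sessions):
        rows = sessions == s
        block = out[rows]
        mu = block.mean(axis=0)
        sd = block.std(axis=0)
        sd[sd < 1e-12] = 1.0
        out[rows] = (block - mu) / sd
    return out


def simulate_responses(cortex: SyntheticCortex, stimuli: StimulusSet,
                       n_repeats: int = 3, n_sessions: int = 4,
                       seed: int = 0, subject: str = "S1",
                       keep_ground_truth: bool = True) -> ResponseDataset:
    """Simulate a single synthetic subject's session-z-scored betas.

    Train and holdout images are presented once; shared-validation images are
    presented ``n_repeats`` times with independent noise draws.  Trials are
    shuffled, partitioned contiguously into sessions, and z-scored per voxel
    per session.
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    signals_by_image = cortex.voxel_signals(stimuli.images)
    return responses_from_signals(
        signals_by_image, stimuli,
        noise_sd=np.array([v.noise_sd for v in cortex.voxels]),
        n_repeats=n_repeats, n_sessions=n_sessions, seed=seed,
        subject=subject,
        voxel_table=cortex.voxel_table() if keep_ground_truth else None)


def responses_from_signals(signals_by_image: np.ndarray, stimuli: StimulusSet,
                           noise_sd: np.ndarray, n_repeats: int = 3,
                           n_sessions: int = 4, seed: int = 0,
                           subject: str = "S1",
                           voxel_table: pd.DataFrame | None = None
                           ) -> ResponseDataset:
    """Build a ResponseDataset from precomputed noiseless per-image signals."""
    rng = np.random.default_rng(seed)
    table = stimuli.table
    image_ids = table["image_id"].to_numpy()
    split = table["split"].to_numpy()
    rows = []
    for idx in range(len(table)):
        reps = n_repeats if split[idx] == "shared-validation" else 1
        for rep in range(reps):
            rows.append((int(image_ids[idx]), idx, rep))
    rows = [rows[i] for i in rng.permutation(len(rows))]
    n_trials = len(rows)
    session = np.repeat(np.arange(n_sessions),
                        int(np.ceil(n_trials / n_sessions)))[:n_trials]

    metadata = {"seed": seed, "n_repeats": n_repeats}
    shared_count = int((split == "shared-validation").sum())
    if shared_count and n_repeats < 2:
        metadata["warnings"] = [
            "shared-validation images have < 2 repeats; repeat-based "
            "noise-ceiling estimation will not be possible"]

    image_idx = np.array([r[1] for r in rows])
    signal = signals_by_image[image_idx]
    noise = rng.normal(0.0, 1.0, size=signal.shape) * noise_sd[None, :]
    betas = zscore_by_session(signal + noise, session)

    trials = pd.DataFrame({
        "trial": np.arange(n_trials),
        "image_id": [r[0] for r in rows],
        "subject": subject,
        "session": session,
        "repeat": [r[2] for r in rows],
    })
    if voxel_table is None:
        voxel_table = pd.DataFrame({"voxel": np.arange(signal.shape[1]),
                                    "area": 0})
    voxel_table = voxel_table.copy()
    voxel_table["subject"] = subject
    return ResponseDataset(betas, trials, voxel_table, subject=subject,
                           signal=signal, metadata=metadata)
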