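"""Stimulus sets: grayscale image stacks with ids, class labels and splits.

Stimulus classes mirror the artificial-stimulus families used to probe
out-of-sample generalization of encoding models (noise images, gratings,
contrast-modulated scenes) plus a "composite" class of scene-like images
(pink-noise background with localized oriented structure) that serves as the
naturalistic training material for synthetic experiments.

Contrast-series frames are the same base scene linearly rescaled about its
mean luminance by the factors 1.0, 0.5, 0.1, 0.06 and 0.04 (100% down to 4%
contrast), so the pixel standard deviation scales exactly with the factor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coords import DEFAULT_SPAN_DEGREES

STIMULUS_CLASSES = ("pink-noise", "white-noise", "grating", "contrast-series",
                    "composite")
CONTRAST_LEVELS = (1.0, 0.5, 0.1, 0.06, 0.04)
SPLITS = ("train", "holdout", "shared-validation")


@dataclass
class StimulusSet:
    """Grayscale frames plus a per-frame table (image_id, class, split, ...).

    Frames are square, with pixel values in [0, 1].  ``table`` has one row
    per frame and at least the columns ``image_id``, ``stimulus_class`` and
    ``split``; generator-specific parameters (contrast, orientation,
    cycles/stimulus) appear as extra columns where applicable.
    """

    images: np.ndarray
    table: pd.DataFrame
    span_degrees: float = DEFAULT_SPAN_DEGREES

    def __post_init__(self):
        self.images = np.asarray(self.images, dtype=np.float64)
        if self.images.ndim != 3 or self.images.shape[1] != self.images.shape[2]:
            raise ValueError("images must be a stack of square frames (N, R, R)")
        if len(self.table) != len(self.images):
            raise ValueError("table must have one row per frame")
        lo, hi = self.images.min(initial=0.0), self.images.max(initial=1.0)
        if lo < -1e-9 or hi > 1.0 + 1e-9:
            raise ValueError(f"pixel values must lie in [0, 1], got [{lo}, {hi}]")
        bad = set(self.table["split"]) - set(SPLITS)
        if bad:
            raise ValueError(f"unknown split labels: {sorted(bad)}")

    @property
    def resolution(self) -> int:
        return self.images.shape[1]

    @property
    def n_images(self) -> int:
        return self.images.shape[0]

    def indices(self, split: str) -> np.ndarray:
        return np.flatnonzero((self.table["split"] == split).to_numpy())

    def subset(self, idx: np.ndarray) -> "StimulusSet":
        return StimulusSet(self.images[idx],
                           self.table.iloc[idx].reset_index(drop=True),
                           self.span_degrees)


def _normalize01(frame: np.ndarray) -> np.ndarray:
    lo, hi = frame.min(), frame.max()
    if hi - lo < 1e-12:
        return np.full_like(frame, 0.5)
    return (frame - lo) / (hi - lo)


def pink_noise_frame(resolution: int, rng: np.random.Generator) -> np.ndarray:
    """1/f-amplitude noise, the classic natural-image power spectrum."""
    fx = np.fft.fftfreq(resolution)[None, :]
    fy = np.fft.fftfreq(resolution)[:, None]
    f = np.hypot(fx, fy)
    f[0, 0] = 1.0
    phases = rng.uniform(0, 2 * np.pi, size=(resolution, resolution))
    spectrum = (1.0 / f) * np.exp(1j * phases)
    spectrum[0, 0] = 0.0
    frame = np.fft.ifft2(spectrum).real
    return _normalize01(frame)


def white_noise_frame(resolution: int, rng: np.random.Generator) -> np.ndarray:
    return rng.random((resolution, resolution))


def grating_frame(resolution: int, cycles_per_stimulus: float,
                  orientation: float, phase: float = 0.0,
                  contrast: float = 1.0) -> np.ndarray:
    """Full-field sinusoidal grating.

    ``cycles_per_stimulus`` is the spatial frequency across the full frame;
    ``orientation`` (radians) is the direction of modulation.
    """
    u = (np.arange(resolution) + 0.5) / resolution
    xx, yy = np.meshgrid(u, u)
    t = xx * np.cos(orientation) + yy * np.sin(orientation)
    return 0.5 + 0.5 * contrast * np.sin(2 * np.pi * cycles_per_stimulus * t + phase)


def composite_frame(resolution: int, rng: np.random.Generator,
                    n_patches: int = 4) -> np.ndarray:
    """Scene-like frame: pink-noise background plus localized oriented patches."""
    frame = pink_noise_frame(resolution, rng) - 0.5
    u = (np.arange(resolution) + 0.5) / resolution
    xx, yy = np.meshgrid(u, u)
    for _ in range(n_patches):
        cx, cy = rng.uniform(0.15, 0.85, size=2)
        sigma = rng.uniform(0.05, 0.15)
        theta = rng.uniform(0, np.pi)
        freq = rng.uniform(4, 12)
        env = np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * sigma ** 2))
        carrier = np.sin(2 * np.pi * freq * (xx * np.cos(theta) + yy * np.sin(theta)))
        frame = frame + rng.uniform(0.3, 0.8) * env * carrier
    return _normalize01(frame)


def contrast_series(base: np.ndarray,
                    levels: tuple[float, ...] = CONTRAST_LEVELS) -> np.ndarray:
    """Rescale a base scene about its mean luminance by each contrast level."""
    mean = base.mean()
    return np.stack([mean + c * (base - mean) for c in levels])


def generate_stimuli(n_per_class: int, resolution: int,
                     classes: tuple[str, ...] | list[str],
                     seed: int = 0,
                     split: str = "train") -> StimulusSet:
    """Generate ``n_per_class`` frames for each requested stimulus class.

    Contrast-series frames cycle through the five contrast levels applied to
    successive base scenes; gratings sweep orientation and spatial frequency.
    """
    if resolution < 16:
        raise ValueError("resolution must be >= 16")
    if not classes:
        raise ValueError("classes must be nonempty")
    unknown = set(classes) - set(STIMULUS_CLASSES)
    if unknown:
        raise ValueError(
            f"unknown stimulus class(es) {sorted(unknown)}; "
            f"valid classes are {list(STIMULUS_CLASSES)}")
    rng = np.random.default_rng(seed)
    frames, rows = [], []

    for cls in classes:
        if cls == "pink-noise":
            for i in range(n_per_class):
                frames.append(pink_noise_frame(resolution, rng))
                rows.append({"stimulus_class": cls})
        elif cls == "white-noise":
            for i in range(n_per_class):
                frames.append(white_noise_frame(resolution, rng))
                rows.append({"stimulus_class": cls})
        elif cls == "grating":
            n_ori = max(1, int(np.ceil(np.sqrt(n_per_class))))
            oris = np.arange(n_ori) * np.pi / n_ori
            freqs = np.geomspace(2, max(3, resolution // 4),
                                 max(1, int(np.ceil(n_per_class / n_ori))))
            combos = [(o, f) for f in freqs for o in oris][:n_per_class]
            for ori, f in combos:
                frames.append(grating_frame(resolution, f, ori))
                rows.append({"stimulus_class": cls, "orientation": ori,
                             "cycles_per_stimulus": f})
        elif cls == "contrast-series":
            made = 0
            while made < n_per_class:
                base = composite_frame(resolution, rng)
                series = contrast_series(base)
                for lvl, frame in zip(CONTRAST_LEVELS, series):
                    if made >= n_per_class:
                        break
                    frames.append(frame)
                    rows.append({"stimulus_class": cls, "contrast": lvl})
                    made += 1
        elif cls == "composite":
            for i in range(n_per_class):
                frames.append(composite_frame(resolution, rng))
                rows.append({"stimulus_class": cls})

    table = pd.DataFrame(rows)
    table.insert(0, "image_id", np.arange(len(frames)))
    table["split"] = split
    return StimulusSet(np.stack(frames), table)


def generate_experiment_stimuli(n_train: int = 1500, n_shared: int = 200,
                                resolution: int = 64, seed: int = 0,
                                holdout_fraction: float = 0.10,
                                stimulus_class: str = "composite") -> StimulusSet:
    """Scene-like stimulus set with train / holdout / shared-validation splits.

    Emulates the structure of a natural-scenes experiment: a large set of
    distinct training images (a seeded ``holdout_fraction`` of which is
    labeled ``holdout`` for model selection / early stopping) plus a separate
    shared-validation set used only for final cross-validated evaluation.
    """
    total = n_train + n_shared
    stim = generate_stimuli(total, resolution, (stimulus_class,), seed=seed)
    rng = np.random.default_rng(seed + 1)
    split = np.array(["train"] * total, dtype=object)
    split[n_train:] = "shared-validation"
    n_hold = int(round(holdout_fraction * n_train))
    hold_idx = rng.choice(n_train, size=n_hold, replace=False)
    split[hold_idx] = "holdout"
    table = stim.table.copy()
    table["split"] = split
    return StimulusSet(stim.images, table, stim.span_degrees)
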