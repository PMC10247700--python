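"""Model scoring: single-trial prediction accuracy, permutation significance
thresholds, repeat-based noise ceilings, win percentages, explainable-variance
fractions, and between-model output correlations.

Prediction accuracy is the Pearson correlation between predicted and measured
activity on a single-trial basis over the shared-validation split (repeats
kept as separate trials).  The noise ceiling of a voxel is the percentage of
its single-trial response variance attributable to the stimulus, estimated
from repeated presentations: noise variance is the mean within-image variance
across repeats, signal variance the (clipped) remainder of total variance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import pearson_columns


def prediction_accuracy(predictions: np.ndarray, measured: np.ndarray,
                        voxel_table: pd.DataFrame | None = None,
                        model_id: str = "model",
                        n_bootstrap: int = 0, seed: int = 0) -> pd.DataFrame:
    """Per-voxel single-trial Pearson accuracy table.

    ``predictions`` and ``measured`` are (trials, voxels).  Degenerate series
    are recorded with ρ = 0 and flagged.  With ``n_bootstrap`` > 0, a
    standard error is estimated by resampling trials with replacement of the
    predicted and actual activities.
    """
    predictions = np.asarray(predictions, dtype=np.float64)
    measured = np.asarray(measured, dtype=np.float64)
    rho, degenerate = pearson_columns(measured, predictions,
                                      return_degenerate=True)
    table = pd.DataFrame({"voxel": np.arange(len(rho)), "model_id": model_id,
                          "rho": rho, "degenerate": degenerate})
    if voxel_table is not None:
        for col in ("area", "subject"):
            if col in voxel_table.columns:
                table[col] = voxel_table[col].to_numpy()
    if n_bootstrap > 0:
        rng = np.random.default_rng(seed)
        n = measured.shape[0]
        boots = np.empty((n_bootstrap, len(rho)))
        for i in range(n_bootstrap):
            rows = rng.integers(0, n, size=n)
            boots[i] = pearson_columns(measured[rows], predictions[rows])
        table["rho_se"] = boots.std(axis=0, ddof=1)
    return table


def permutation_threshold(measured: np.ndarray | int,
                          predictions: np.ndarray | None = None,
                          p: float = 0.01, n_perm: int = 1000,
                          seed: int = 0) -> float:
    """(1−p) quantile of the null accuracy obtained by permuting trial order.

    The permutation is shared across voxels within each iteration, preserving
    cross-voxel comparability.  ``measured`` may be a (trials, voxels) array
    (with matching predictions) or a bare trial count, in which case the null
    is evaluated on standard-normal surrogate data.
    """
    if not 0 < p < 1:
        raise ValueError("significance level p must be in (0, 1)")
    if n_perm < int(np.ceil(1.0 / p)):
        raise ValueError(f"n_perm={n_perm} too small to resolve p={p}")
    rng = np.random.default_rng(seed)
    if isinstance(measured, (int, np.integer)):
        n = int(measured)
        measured = rng.standard_normal((n, 32))
        predictions = rng.standard_normal((n, 32))
    measured = np.asarray(measured, dtype=np.float64)
    predictions = np.asarray(predictions, dtype=np.float64)
    n = measured.shape[0]
    null = np.empty((n_perm, measured.shape[1]))
    for i in range(n_perm):
        perm = rng.permutation(n)
        null[i] = pearson_columns(measured[perm], predictions)
    return float(np.quantile(null.ravel(), 1.0 - p))


def noise_ceiling(dataset) -> pd.DataFrame:
    """Repeat-based per-voxel noise ceilings (percent) from shared images.

    Uses trials of images with >= 2 repeats: per voxel, noise variance is the
    mean within-image variance across repeats (unbiased, ddof=1); signal
    variance is max(0, total variance − noise variance); the noise ceiling is
    100·signal/(signal+noise), the explainable fraction for single-trial
    prediction.
    """
    trials = dataset.trials
    counts = trials.groupby("image_id")["trial"].count()
    repeated = counts[counts >= 2].index
    if len(repeated) == 0:
        raise ValueError("noise-ceiling estimation requires images with "
                         ">= 2 repeats")
    betas = dataset.betas
    groups = [np.flatnonzero(trials["image_id"].to_numpy() == img)
              for img in repeated]
    rows_all = np.concatenate(groups)
    total_var = betas[rows_all].var(axis=0, ddof=1)
    within = np.stack([betas[g].var(axis=0, ddof=1) for g in groups])
    noise_var = within.mean(axis=0)
    signal_var = np.maximum(0.0, total_var - noise_var)
    denom = signal_var + noise_var
    denom[denom < 1e-300] = 1.0
    nc = 100.0 * signal_var / denom
    table = pd.DataFrame({"voxel": np.arange(betas.shape[1]),
                          "noise_ceiling": np.clip(nc, 0.0, 100.0)})
    if "area" in dataset.voxels.columns:
        table["area"] = dataset.voxels["area"].to_numpy()
    return table


def win_percentage(acc_a: pd.DataFrame, acc_b: pd.DataFrame,
                   by_area: bool = False):
    """Percent of voxels where model A strictly beats model B.

    Ties count as non-wins.  With ``by_area`` a per-area breakdown is
    returned alongside the overall percentage.
    """
    if len(acc_a) != len(acc_b) or not (acc_a["voxel"].to_numpy()
                                        == acc_b["voxel"].to_numpy()).all():
        raise ValueError("accuracy tables must cover the same voxel set")
    wins = acc_a["rho"].to_numpy() > acc_b["rho"].to_numpy()
    overall = 100.0 * wins.mean()
    if not by_area:
        return overall
    if "area" not in acc_a.columns:
        raise ValueError("per-area breakdown needs an 'area' column")
    per_area = (pd.DataFrame({"area": acc_a["area"].to_numpy(), "win": wins})
                .groupby("area")["win"].mean() * 100.0)
    return overall, per_area


def explained_variance_fraction(accuracy: pd.DataFrame, nc: pd.DataFrame,
                                min_nc: float = 5.0) -> pd.DataFrame:
    """Percent of explainable variance explained: 100·ρ²/NC, per area.

    Only voxels with a noise ceiling of at least ``min_nc`` percent enter the
    summary; per-area values are voxel means.
    """
    if min_nc <= 0:
        raise ValueError("min_nc must be > 0")
    if len(accuracy) != len(nc):
        raise ValueError("tables must cover the same voxels")
    merged = accuracy.merge(nc, on="voxel", suffixes=("", "_nc"))
    keep = merged["noise_ceiling"] >= min_nc
    sub = merged[keep].copy()
    # rho^2 is a variance fraction in [0, 1]; NC is in percent, so the
    # explained share of *explainable* variance is 100 * rho^2 / (NC/100)
    sub["fraction"] = 100.0 * sub["rho"] ** 2 / (sub["noise_ceiling"] / 100.0)
    area_col = "area" if "area" in sub.columns else None
    if area_col:
        summary = sub.groupby(area_col).agg(
            fraction=("fraction", "mean"), n_voxels=("voxel", "count"))
    else:
        summary = pd.DataFrame({"fraction": [sub["fraction"].mean()],
                                "n_voxels": [len(sub)]})
    summary.attrs["n_excluded"] = int((~keep).sum())
    return summary.reset_index()


def model_output_correlation(predictions_a: np.ndarray,
                             predictions_b: np.ndarray) -> pd.DataFrame:
    """Per-voxel Pearson correlation between two models' outputs."""
    rho, degenerate = pearson_columns(np.asarray(predictions_a, dtype=float),
                                      np.asarray(predictions_b, dtype=float),
                                      return_degenerate=True)
    table = pd.DataFrame({"voxel": np.arange(len(rho)), "rho": rho,
                          "degenerate": degenerate})
    table.attrs["median"] = float(np.median(rho))
    table.attrs["mean"] = float(np.mean(rho))
    return table


def audit_split_purity(stimuli, dataset) -> None:
    """Assert zero overlap between evaluation and training/holdout image ids."""
    table = stimuli.table
    val_ids = set(table.loc[table["split"] == "shared-validation", "image_id"])
    fit_ids = set(table.loc[table["split"] != "shared-validation", "image_id"])
    overlap = val_ids & fit_ids
    if overlap:
        raise AssertionError(f"evaluation images leak into training: "
                             f"{sorted(overlap)[:5]} ...")
    trial_ids = set(dataset.trials["image_id"])
    unknown = trial_ids - (val_ids | fit_ids)
    if unknown:
        raise AssertionError(f"trials reference unknown images: "
                             f"{sorted(unknown)[:5]} ...")
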