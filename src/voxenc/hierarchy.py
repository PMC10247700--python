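"""Hierarchy tests: layer-contribution variance partition, transfer-learning
shift matrix with the entailment index α, and receptive-field ellipse fitting
with size–eccentricity lines.

The entailment test asks whether a feature extractor optimized for one area's
representations transfers to another area.  The prediction-accuracy shift
Δᵢʲ is the mean, over voxels of tested area i, of the accuracy of a transfer
model (extractor trained on area j, fresh read-out trained on area i) minus
the accuracy of area i's own reference model.  Rows of the shift matrix index
the trained-on area, columns the tested area, both ordered
posterior→anterior (area 1 first).  The entailment index

    α = (a₊ − a₋) / (|a₊| + |a₋|)

contrasts the least-squares slopes (vs. taxicab distance from the diagonal,
free intercept) of the two off-diagonal triangles: a₊ over
train-anterior/test-posterior cells (row > column) and a₋ over
train-posterior/test-anterior cells (row < column).  α = 1 indicates strict
entailment, 0 none, −1 reverse entailment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .coords import pixel_centers
from .stats import pearson_columns
from .training import (EncodingModel, TrainingConfig, TrainingData,
                       train_heads_frozen)


# ---------------------------------------------------------------------------
# Layer-wise contributions

@dataclass(frozen=True)
class LayerPartition:
    """Disjoint bottom/top layer-id sets covering all exposed layers."""

    bottom: tuple[str, ...]
    top: tuple[str, ...]

    def __post_init__(self):
        if not self.bottom or not self.top:
            raise ValueError("both partition halves must be nonempty")
        if set(self.bottom) & set(self.top):
            raise ValueError("bottom and top layer sets must be disjoint")

    def validate(self, exposed: list[str]) -> None:
        if set(self.bottom) | set(self.top) != set(exposed):
            raise ValueError(
                f"partition {sorted(self.bottom + self.top)} does not cover "
                f"the exposed layers {exposed}")


def default_partition(exposed: list[str]) -> LayerPartition:
    """Split exposed layers at the depth midpoint; ties go to the bottom."""
    half = (len(exposed) + 1) // 2
    return LayerPartition(tuple(exposed[:half]), tuple(exposed[half:]))


def masked_accuracy(model: EncodingModel, images: np.ndarray,
                    measured: np.ndarray,
                    partition: LayerPartition) -> pd.DataFrame:
    """Full, bottom-only and top-only accuracy per voxel on the same trials.

    Masking zeroes the read-out feature weights of the excluded layers; the
    forward pass through the extractor is unchanged.
    """
    partition.validate(model.extractor.exposed)
    full = model.predict(images)
    bottom = model.predict(images,
                           weight_mask=model.heads.layer_mask(partition.bottom))
    top = model.predict(images,
                        weight_mask=model.heads.layer_mask(partition.top))
    return pd.DataFrame({
        "voxel": np.arange(measured.shape[1]),
        "rho": pearson_columns(measured, full),
        "rho_bottom": pearson_columns(measured, bottom),
        "rho_top": pearson_columns(measured, top),
    })


def layer_contribution_fractions(masked: pd.DataFrame,
                                 areas: np.ndarray,
                                 threshold: float = 0.055,
                                 n_bootstrap: int = 200,
                                 seed: int = 0) -> pd.DataFrame:
    """Specific and unique bottom/top contribution fractions per area.

    Per voxel with ρ above threshold:
        f_bottom_specific = ρ_bottom² / ρ²,
        f_bottom_unique   = (ρ² − ρ_top²) / ρ²,
    and the top-layer analogs with bottom/top swapped.  Area values are voxel
    means; uncertainty is a bootstrap over voxels.
    """
    rho = masked["rho"].to_numpy()
    keep = rho > threshold
    n_excluded_nonpos = int((~keep).sum())
    rho_b = masked["rho_bottom"].to_numpy()[keep]
    rho_t = masked["rho_top"].to_numpy()[keep]
    rho = rho[keep]
    areas = np.asarray(areas)[keep]
    r2 = rho ** 2
    frac = pd.DataFrame({
        "area": areas,
        "f_bottom_specific": rho_b ** 2 / r2,
        "f_bottom_unique": (r2 - rho_t ** 2) / r2,
        "f_top_specific": rho_t ** 2 / r2,
        "f_top_unique": (r2 - rho_b ** 2) / r2,
    })
    cols = ["f_bottom_specific", "f_bottom_unique",
            "f_top_specific", "f_top_unique"]
    summary = frac.groupby("area")[cols].mean()
    rng = np.random.default_rng(seed)
    if n_bootstrap > 0:
        for area, grp in frac.groupby("area"):
            vals = grp[cols].to_numpy()
            boots = np.empty((n_bootstrap, len(cols)))
            for i in range(n_bootstrap):
                rows = rng.integers(0, len(vals), size=len(vals))
                boots[i] = vals[rows].mean(axis=0)
            for ci, c in enumerate(cols):
                summary.loc[area, c + "_se"] = boots[:, ci].std(ddof=1)
    summary.attrs["n_excluded"] = n_excluded_nonpos
    summary.attrs["threshold"] = threshold
    return summary.reset_index()


# ---------------------------------------------------------------------------
# Transfer-learning shift matrix and α

@dataclass
class ShiftMatrix:
    """Area×area prediction-accuracy shifts Δᵢʲ.

    ``values[j-1, i-1]`` is the mean shift when the extractor trained on area
    j is reused (fresh read-out) for voxels of area i.  Areas are ordered
    posterior→anterior.
    """

    values: np.ndarray
    se: np.ndarray | None = None
    area_labels: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("shift matrix must be square")
        if not np.isfinite(self.values).all():
            raise ValueError("shift matrix entries must be finite")
        if not self.area_labels:
            self.area_labels = [f"A{i+1}" for i in range(len(self.values))]

    @property
    def n_areas(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values,
                            index=[f"trained_on_{a}" for a in self.area_labels],
                            columns=[f"tested_on_{a}" for a in self.area_labels])


@dataclass
class AlphaResult:
    alpha: float
    se: float
    a_plus: float
    a_plus_se: float
    a_minus: float
    a_minus_se: float
    undefined: bool = False

    def to_dict(self) -> dict:
        return {"alpha": self.alpha, "se": self.se, "a_plus": self.a_plus,
                "a_plus_se": self.a_plus_se, "a_minus": self.a_minus,
                "a_minus_se": self.a_minus_se, "undefined": self.undefined}


def _triangle_slope(matrix: np.ndarray, lower: bool) -> tuple[float, float]:
    a = matrix.shape[0]
    ds, vals = [], []
    for r in range(a):
        for c in range(a):
            if (r > c) if lower else (r < c):
                ds.append(abs(r - c))
                vals.append(matrix[r, c])
    fit = stats.linregress(ds, vals)
    return float(fit.slope), float(fit.stderr)


def alpha_index(matrix: ShiftMatrix | np.ndarray) -> AlphaResult:
    """Entailment index α from a shift matrix (free-intercept slope fits).

    Off-diagonal cells are assigned their taxicab distance d = |i−j| from
    the diagonal; a₊ is the least-squares slope of the
    train-anterior/test-posterior triangle (rows below the diagonal), a₋ of
    the opposite triangle; α = (a₊ − a₋)/(|a₊| + |a₋|).  The α standard
    error propagates the slope standard errors, treated as independent.
    """
    values = matrix.values if isinstance(matrix, ShiftMatrix) else np.asarray(matrix, dtype=float)
    a = values.shape[0]
    if a < 3:
        raise ValueError("alpha needs >= 3 areas so each triangle spans "
                         ">= 2 distinct taxicab distances")
    a_plus, se_plus = _triangle_slope(values, lower=True)
    a_minus, se_minus = _triangle_slope(values, lower=False)
    denom = abs(a_plus) + abs(a_minus)
    if denom == 0:
        return AlphaResult(np.nan, np.nan, a_plus, se_plus, a_minus, se_minus,
                           undefined=True)
    alpha = (a_plus - a_minus) / denom
    dplus = (1.0 - alpha * np.sign(a_plus)) / denom
    dminus = (-1.0 - alpha * np.sign(a_minus)) / denom
    se = float(np.sqrt((dplus * se_plus) ** 2 + (dminus * se_minus) ** 2))
    return AlphaResult(float(alpha), se, a_plus, se_plus, a_minus, se_minus)


def transfer_shift_matrix(references: dict[int, dict],
                          targets: dict[int, TrainingData],
                          cfg: TrainingConfig,
                          f_in: str = "tanh_log", f_out: str = "tanh_log",
                          n_bootstrap: int = 200, seed: int = 0,
                          recompute_reference: bool = True) -> ShiftMatrix:
    """Freeze each reference extractor and retrain read-outs for every area.

    ``references[j]`` holds area j's reference model and its per-voxel
    held-out accuracy ``rho_ref``; ``targets[i]`` is the training data for
    area i's voxels (brain activity or teacher outputs).  Returns the matrix
    of Δᵢʲ with bootstrap (over voxels) standard errors.

    With ``recompute_reference`` (the default) ρ_ref of each area is
    re-measured with the same frozen-extractor head-retraining protocol used
    for the transfer models (on the area's own extractor, with an
    independent seed).  Simultaneous and serial training of the read-out
    reach systematically different optima, which would otherwise leak a
    protocol artifact into every cell; re-measuring ρ_ref serially confines
    the comparison to what the frozen representations support.
    """
    area_list = sorted(targets)
    if sorted(references) != area_list:
        raise ValueError(f"need one reference model per area {area_list}, "
                         f"got {sorted(references)}")
    a = len(area_list)
    values = np.zeros((a, a))
    se = np.zeros((a, a))
    rng = np.random.default_rng(seed)

    rho_ref = {}
    for i in area_list:
        if recompute_reference:
            data = targets[i]
            ref_cfg = TrainingConfig(**{**cfg.__dict__,
                                        "seed": cfg.seed + 5000 + 13 * i})
            heads, _ = train_heads_frozen(references[i]["model"].extractor,
                                          data, ref_cfg, f_in=f_in, f_out=f_out)
            preds = EncodingModel(references[i]["model"].extractor,
                                  heads).predict(data.images[data.val_idx])
            rho_ref[i] = pearson_columns(data.y_val, preds)
        else:
            rho_ref[i] = references[i]["rho_ref"]

    for jx, j in enumerate(area_list):
        extractor = references[j]["model"].extractor
        for ix, i in enumerate(area_list):
            data = targets[i]
            head_cfg = TrainingConfig(**{**cfg.__dict__,
                                         "seed": cfg.seed + 1000 + 31 * j + i})
            heads, _ = train_heads_frozen(extractor, data, head_cfg,
                                          f_in=f_in, f_out=f_out)
            model = EncodingModel(extractor, heads)
            preds = model.predict(data.images[data.val_idx])
            rho_transfer = pearson_columns(data.y_val, preds)
            shifts = rho_transfer - rho_ref[i]
            values[jx, ix] = shifts.mean()
            if n_bootstrap > 0 and len(shifts) > 1:
                boots = [shifts[rng.integers(0, len(shifts), len(shifts))].mean()
                         for _ in range(n_bootstrap)]
                se[jx, ix] = float(np.std(boots, ddof=1))
    return ShiftMatrix(values, se, [f"A{i}" for i in area_list])


# ---------------------------------------------------------------------------
# Receptive-field ellipses and size–eccentricity lines

@dataclass
class RFEllipse:
    center: tuple[float, float]   # (x, y), % of span
    a: float                      # one-std major axis, % of span
    b: float                      # one-std minor axis, % of span
    orientation: float            # radians
    fallback: bool = False        # True if the refinement diverged

    def __post_init__(self):
        if not (self.a >= self.b > 0):
            raise ValueError("ellipse axes must satisfy a >= b > 0")

    @property
    def size(self) -> float:
        """√(π a b): square-root area of the one-std ellipse."""
        return float(np.sqrt(np.pi * self.a * self.b))

    @property
    def eccentricity(self) -> float:
        return float(np.hypot(*self.center))


def _moment_ellipse(grid: np.ndarray):
    res = grid.shape[0]
    x, y = pixel_centers(res)
    w = grid / grid.sum()
    mx, my = (w * x).sum(), (w * y).sum()
    cxx = (w * (x - mx) ** 2).sum()
    cyy = (w * (y - my) ** 2).sum()
    cxy = (w * (x - mx) * (y - my)).sum()
    cov = np.array([[cxx, cxy], [cxy, cyy]])
    evals, evecs = np.linalg.eigh(cov)
    evals = np.maximum(evals, 1e-6)
    a = float(np.sqrt(evals[1]))
    b = float(np.sqrt(evals[0]))
    theta = float(np.arctan2(evecs[1, 1], evecs[0, 1]))
    return (mx, my), a, b, theta


def fit_rf_ellipse(grid: np.ndarray) -> RFEllipse:
    """Fit an elliptical 2-D Gaussian to a pooling-field weight grid.

    Moment-based initialization (centroid + second-moment ellipse) refined by
    nonlinear least squares on the pixel values; outputs are in % of span.
    If refinement diverges, the moment estimate is returned with a fallback
    flag.
    """
    grid = np.asarray(grid, dtype=np.float64)
    if (grid < 0).any() or grid.sum() <= 0:
        raise ValueError("pooling-field grid must be nonnegative with "
                         "positive sum")
    res = grid.shape[0]
    x, y = pixel_centers(res)
    (mx, my), a0, b0, th0 = _moment_ellipse(grid)
    amp0 = float(grid.max())

    def residuals(params):
        amp, cx, cy, la, lb, th = params
        sa, sb = np.exp(la), np.exp(lb)
        ct, st = np.cos(th), np.sin(th)
        u = (x - cx) * ct + (y - cy) * st
        v = -(x - cx) * st + (y - cy) * ct
        model = amp * np.exp(-0.5 * ((u / sa) ** 2 + (v / sb) ** 2))
        return (model - grid).ravel()

    p0 = np.array([amp0, mx, my, np.log(a0), np.log(b0), th0])
    try:
        fit = optimize.least_squares(residuals, p0, max_nfev=200)
        ok = fit.success and np.isfinite(fit.x).all()
    except Exception:
        ok = False
    if ok:
        # diffuse, non-localized grids send the Gaussian fit to degenerate
        # optima (vanishing amplitude, exploding width); fall back to moments
        _, cx_, cy_, la_, lb_, _ = fit.x
        if (max(np.exp(la_), np.exp(lb_)) > 75.0
                or max(abs(cx_), abs(cy_)) > 75.0):
            ok = False
    if not ok:
        return RFEllipse((mx, my), max(a0, b0), min(a0, b0), th0,
                         fallback=True)
    amp, cx, cy, la, lb, th = fit.x
    sa, sb = float(np.exp(la)), float(np.exp(lb))
    if sa < sb:
        sa, sb = sb, sa
        th = th + np.pi / 2
    return RFEllipse((float(cx), float(cy)), sa, sb,
                     float(np.mod(th, np.pi)))


def rf_table(model: EncodingModel, resolution: int | None = None,
             accuracy: pd.DataFrame | None = None,
             threshold: float = 0.055) -> pd.DataFrame:
    """Fit RF ellipses to every voxel's flexible pooling field.

    Uses the finest-resolution pooling grid of each voxel.  If an accuracy
    table is given, voxels at or below the threshold are excluded.
    """
    grids = model.heads.effective_grids()
    res = resolution or max(grids)
    g = grids[res]
    keep = np.ones(g.shape[0], dtype=bool)
    if accuracy is not None:
        keep = accuracy["rho"].to_numpy() > threshold
    rows = []
    for v in np.flatnonzero(keep):
        e = fit_rf_ellipse(g[v])
        rows.append({"voxel": v, "x": e.center[0], "y": e.center[1],
                     "a": e.a, "b": e.b, "size": e.size,
                     "eccentricity": e.eccentricity,
                     "orientation": e.orientation, "fallback": e.fallback})
    table = pd.DataFrame(rows)
    if model.areas is not None and len(table):
        table["area"] = np.asarray(model.areas)[table["voxel"].to_numpy()]
    return table


def size_eccentricity_fit(rf: pd.DataFrame, min_voxels: int = 10,
                          reference_ecc: float = 20.0) -> pd.DataFrame:
    """Per-area OLS of RF size vs eccentricity (both in % of span).

    Areas with fewer than ``min_voxels`` usable voxels are skipped with a
    report entry.  ``size_at_ref`` evaluates each line at a matched
    eccentricity for the cross-area ordering test.
    """
    if "area" not in rf.columns:
        rf = rf.assign(area=0)
    rows = []
    for area, grp in rf.groupby("area"):
        if len(grp) < min_voxels:
            rows.append({"area": area, "n_voxels": len(grp), "skipped": True,
                         "slope": np.nan, "intercept": np.nan,
                         "slope_se": np.nan, "intercept_se": np.nan,
                         "size_at_ref": np.nan})
            continue
        fit = stats.linregress(grp["eccentricity"], grp["size"])
        rows.append({"area": area, "n_voxels": len(grp), "skipped": False,
                     "slope": fit.slope, "intercept": fit.intercept,
                     "slope_se": fit.stderr,
                     "intercept_se": fit.intercept_stderr,
                     "size_at_ref": fit.slope * reference_ecc + fit.intercept})
    return pd.DataFrame(rows)
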