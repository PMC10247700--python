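"""End-to-end experiment orchestration and the regime-discrimination study.

``run_experiment`` executes simulate → train (joint and ROI-wise) → evaluate
(accuracy, noise ceilings, win percentages, explainable variance) → hierarchy
analysis (layer-contribution fractions, transfer matrix + α, RF size lines)
from a single config, and writes a validated JSON report plus CSV tables and
figures.

``hierarchy_discrimination`` runs the core comparison: per-area reference
branches (sharing a fixed oriented-energy prefilter) are trained on the
synthetic cortex's noiseless area signals, the transfer analysis yields the
entailment index α, and the reference models' fitted pooling fields give the
receptive-field size ordering.  On a hierarchical-regime cortex α should
exceed the α of a matched parallel-regime cortex, while both regimes show
growing RF sizes across areas.
"""

from __future__ import annotations

import json
import time
import traceback
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel

from . import __version__
from .cortex import (AreaSpec, CortexConfig, build_synthetic_cortex,
                     simulate_responses)
from .evaluation import (audit_split_purity, explained_variance_fraction,
                         noise_ceiling, permutation_threshold,
                         prediction_accuracy, win_percentage)
from .extractors import default_extractor_spec
from .hierarchy import (alpha_index, default_partition,
                        layer_contribution_fractions, masked_accuracy,
                        rf_table, size_eccentricity_fit, transfer_shift_matrix)
from .stats import pearson_columns
from .stimuli import generate_experiment_stimuli
from .training import (EncodingModel, TrainingConfig,
                       train_heads_frozen, train_roiwise, train_single_branch,
                       training_data_from_dataset, training_data_from_outputs)

SCENARIOS = ("hierarchical-brain", "parallel-brain", "custom")


@dataclass
class ScaleConfig:
    """Problem sizes of one experiment run."""

    resolution: int = 24
    n_train: int = 320
    n_shared: int = 80
    voxels_per_area: int = 10
    noise_sd: float = 0.7
    n_repeats: int = 3
    n_sessions: int = 4
    rf_slopes: tuple[float, ...] = (0.10, 0.15, 0.22, 0.30)
    rf_intercepts: tuple[float, ...] = (4.0, 6.0, 8.0, 11.0)
    mix_beta: float | None = None  # generator default when None


@dataclass
class FitConfig:
    """Training budgets of one experiment run."""

    epochs: int = 150          # cap; early stopping below usually ends sooner
    patience: int = 20
    polish_epochs: int = 150
    batch_size: int = 25
    lr: float = 1e-2
    head_lr: float = 3e-2
    dropout: float = 0.05
    prefilter: str = "gabor-energy"


@dataclass
class ExperimentConfig:
    scenario: str = "hierarchical-brain"
    seed: int = 0
    out_dir: str = "voxenc_run"
    scale: ScaleConfig = field(default_factory=ScaleConfig)
    fit: FitConfig = field(default_factory=FitConfig)

    def regime(self) -> str:
        if self.scenario == "hierarchical-brain":
            return "hierarchical"
        if self.scenario == "parallel-brain":
            return "parallel"
        return "hierarchical"

    def to_dict(self) -> dict:
        return asdict(self)


class ExperimentReport(BaseModel):
    """Schema of the JSON report written by run_experiment."""

    package_version: str
    scenario: str
    seed: int
    config_hash: str
    stages_completed: list[str]
    failure_stage: str | None = None
    failure_message: str | None = None
    metrics: dict
    tables: dict
    runtime_seconds: float


def _cortex_config(cfg: ExperimentConfig) -> CortexConfig:
    s = cfg.scale
    areas = [AreaSpec(n_voxels=s.voxels_per_area, rf_slope=sl,
                      rf_intercept=ic, noise_sd=s.noise_sd)
             for sl, ic in zip(s.rf_slopes, s.rf_intercepts)]
    kw = {}
    if s.mix_beta is not None:
        kw["mix_beta"] = s.mix_beta
    return CortexConfig(regime=cfg.regime(), areas=areas,
                        resolution=s.resolution, seed=cfg.seed + 1, **kw)


def train_polished_branch(spec, data, cfg: TrainingConfig,
                          polish_epochs: int = 150,
                          f_in: str = "tanh_log", f_out: str = "tanh_log"):
    """Joint extractor+head training followed by a long head-only polish.

    The polish phase retrains the heads to (near) head-optimality on the
    frozen extractor's cached feature maps; it is cheap and puts every model
    on the same footing the transfer analysis later compares them on.
    """
    model, log = train_single_branch(spec, data, cfg, f_in=f_in, f_out=f_out)
    if polish_epochs > 0:
        pcfg = TrainingConfig(**{**cfg.__dict__,
                                 "max_epochs": polish_epochs,
                                 "patience": max(20, polish_epochs // 5),
                                 "seed": cfg.seed + 1})
        train_heads_frozen(model.extractor, data, pcfg, heads=model.heads)
        model.extractor.freeze(False)
    return model, log


def reference_models_from_signals(cortex, stimuli, fit: FitConfig, seed: int):
    """Per-area reference branches trained on noiseless ground-truth signals."""
    signals = cortex.voxel_signals(stimuli.images)
    areas = np.array([v.area for v in cortex.voxels])
    spec = default_extractor_spec(stimuli.resolution, dropout=fit.dropout,
                                  prefilter=fit.prefilter)
    refs, targets = {}, {}
    for a in sorted(set(areas)):
        data = training_data_from_outputs(stimuli, signals[:, areas == a])
        tc = TrainingConfig(max_epochs=fit.epochs, patience=fit.patience,
                            batch_size=fit.batch_size, lr=fit.lr,
                            head_lr=fit.head_lr, seed=seed + 100 * int(a))
        model, _ = train_polished_branch(spec, data, tc,
                                         polish_epochs=fit.polish_epochs)
        preds = model.predict(data.images[data.val_idx])
        refs[int(a)] = {"model": model,
                        "rho_ref": pearson_columns(data.y_val, preds)}
        targets[int(a)] = data
    return refs, targets


def hierarchy_discrimination(regime: str, seed: int,
                             scale: ScaleConfig | None = None,
                             fit: FitConfig | None = None) -> dict:
    """One regime's transfer analysis + RF ordering at desk scale.

    Returns α (entailment index), the shift matrix, the mean fitted
    pooling-field size per area of the reference models, and the Spearman
    correlation between area index and mean fitted RF size.
    """
    from scipy.stats import spearmanr

    scale = scale or ScaleConfig()
    fit = fit or FitConfig()
    stim = generate_experiment_stimuli(n_train=scale.n_train,
                                       n_shared=scale.n_shared,
                                       resolution=scale.resolution, seed=seed)
    cfg = ExperimentConfig(scenario=f"{regime}-brain", seed=seed, scale=scale,
                           fit=fit)
    cortex = build_synthetic_cortex(_cortex_config(cfg))
    refs, targets = reference_models_from_signals(cortex, stim, fit, seed + 10)
    hc = TrainingConfig(max_epochs=fit.polish_epochs,
                        patience=max(20, fit.polish_epochs // 5),
                        batch_size=fit.batch_size, lr=fit.lr,
                        head_lr=fit.head_lr, seed=seed + 9)
    sm = transfer_shift_matrix(refs, targets, hc, n_bootstrap=0)
    alpha = alpha_index(sm)

    mean_sizes = {}
    for a, ref in refs.items():
        table = rf_table(ref["model"])
        mean_sizes[a] = float(table["size"].mean())
    area_order = sorted(mean_sizes)
    rho_order = spearmanr(area_order,
                          [mean_sizes[a] for a in area_order]).statistic
    return {"regime": regime, "seed": seed, "alpha": alpha.alpha,
            "alpha_se": alpha.se, "shift_matrix": sm,
            "mean_rf_size": mean_sizes,
            "rf_size_spearman": float(rho_order),
            "rho_ref_mean": {a: float(r["rho_ref"].mean())
                             for a, r in refs.items()}}


# ---------------------------------------------------------------------------
# Full experiment

def _table_path(out: Path, name: str) -> Path:
    return out / f"{name}.csv"


def _save_table(df: pd.DataFrame, out: Path, name: str, seed: int) -> str:
    path = _table_path(out, name)
    with open(path, "w") as fh:
        fh.write(f"# voxenc {__version__} seed={seed}\n")
        df.to_csv(fh, index=False)
    return str(path)


def run_experiment(config: ExperimentConfig) -> dict:
    """Execute the full pipeline; on stage failure, keep partial outputs."""
    from .io import config_hash, save_dataset

    t_start = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config_hash(config.to_dict())
    stages_done: list[str] = []
    metrics: dict = {}
    tables: dict = {}
    failure_stage = failure_message = None
    seed = config.seed
    s, f = config.scale, config.fit

    def finish():
        report = ExperimentReport(
            package_version=__version__, scenario=config.scenario, seed=seed,
            config_hash=chash, stages_completed=stages_done,
            failure_stage=failure_stage, failure_message=failure_message,
            metrics=metrics, tables=tables,
            runtime_seconds=time.time() - t_start)
        with open(out / "report.json", "w") as fh:
            json.dump(report.model_dump(), fh, indent=2, default=float)
        return report.model_dump()

    stage = "simulate"
    try:
        stim = generate_experiment_stimuli(n_train=s.n_train,
                                           n_shared=s.n_shared,
                                           resolution=s.resolution, seed=seed)
        cortex = build_synthetic_cortex(_cortex_config(config))
        dataset = simulate_responses(cortex, stim, n_repeats=s.n_repeats,
                                     n_sessions=s.n_sessions, seed=seed + 2)
        audit_split_purity(stim, dataset)
        save_dataset(out / "dataset.h5", stim, dataset)
        data = training_data_from_dataset(stim, dataset)
        stages_done.append(stage)

        stage = "train"
        spec = default_extractor_spec(s.resolution, dropout=f.dropout,
                                      prefilter=f.prefilter)
        tc = TrainingConfig(max_epochs=f.epochs, patience=f.patience,
                            batch_size=f.batch_size, lr=f.lr,
                            head_lr=f.head_lr, seed=seed + 5)
        joint, joint_log = train_polished_branch(spec, data, tc,
                                                 polish_epochs=f.polish_epochs)
        roi_models, _ = train_roiwise(
            {a: spec for a in sorted(set(data.areas))}, data, tc)
        tables["training_log"] = _save_table(joint_log, out, "training_log",
                                             seed)
        stages_done.append(stage)

        stage = "evaluate"
        val_imgs = data.images[data.val_idx]
        preds_joint = joint.predict(val_imgs)
        acc_joint = prediction_accuracy(preds_joint, data.y_val,
                                        dataset.voxels, model_id="joint")
        preds_roi = np.empty_like(preds_joint)
        for a, m in roi_models.items():
            cols = np.flatnonzero(data.areas == a)
            preds_roi[:, cols] = m.predict(val_imgs)
        acc_roi = prediction_accuracy(preds_roi, data.y_val, dataset.voxels,
                                      model_id="roiwise")
        nc = noise_ceiling(dataset)
        thr = permutation_threshold(data.y_val, preds_joint, p=0.01,
                                    n_perm=200, seed=seed + 11)
        win_overall, win_area = win_percentage(acc_joint, acc_roi,
                                               by_area=True)
        evf = explained_variance_fraction(acc_joint, nc)
        metrics["mean_accuracy_joint"] = float(acc_joint["rho"].mean())
        metrics["mean_accuracy_roiwise"] = float(acc_roi["rho"].mean())
        metrics["mean_noise_ceiling"] = float(nc["noise_ceiling"].mean())
        metrics["permutation_threshold_p01"] = thr
        metrics["win_percentage_joint_vs_roiwise"] = win_overall
        tables["accuracy_joint"] = _save_table(acc_joint, out,
                                               "accuracy_joint", seed)
        tables["accuracy_roiwise"] = _save_table(acc_roi, out,
                                                 "accuracy_roiwise", seed)
        tables["noise_ceiling"] = _save_table(nc, out, "noise_ceiling", seed)
        tables["explained_variance"] = _save_table(evf, out,
                                                   "explained_variance", seed)
        stages_done.append(stage)

        stage = "hierarchy"
        partition = default_partition(joint.extractor.exposed)
        masked = masked_accuracy(joint, val_imgs, data.y_val, partition)
        fractions = layer_contribution_fractions(masked, data.areas,
                                                 threshold=thr,
                                                 seed=seed + 13)
        rf = rf_table(joint, accuracy=acc_joint, threshold=thr)
        lines = size_eccentricity_fit(rf, min_voxels=5)
        disc = hierarchy_discrimination(config.regime(), seed,
                                        scale=s, fit=f)
        sm, alpha = disc["shift_matrix"], disc["alpha"]
        metrics["alpha"] = alpha
        metrics["alpha_se"] = disc["alpha_se"]
        metrics["mean_rf_size_by_area"] = disc["mean_rf_size"]
        metrics["rf_size_spearman"] = disc["rf_size_spearman"]
        tables["layer_fractions"] = _save_table(fractions, out,
                                                "layer_fractions", seed)
        tables["rf_ellipses"] = _save_table(rf, out, "rf_ellipses", seed)
        tables["size_eccentricity"] = _save_table(lines, out,
                                                  "size_eccentricity", seed)
        tables["shift_matrix"] = _save_table(sm.to_frame().reset_index(),
                                             out, "shift_matrix", seed)
        stages_done.append(stage)

        stage = "figures"
        _write_figures(out, sm, rf, lines)
        stages_done.append(stage)
    except Exception as exc:  # partial outputs retained
        failure_stage = stage
        failure_message = f"{type(exc).__name__}: {exc}\n" \
                          + traceback.format_exc(limit=3)
    return finish()


def _write_figures(out: Path, shift_matrix, rf: pd.DataFrame,
                   lines: pd.DataFrame) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 3.5))
    vmax = np.abs(shift_matrix.values).max() or 1.0
    im = ax.imshow(shift_matrix.values, cmap="RdBu_r", vmin=-vmax, vmax=vmax)
    ax.set_xlabel("tested area")
    ax.set_ylabel("feature extractor trained on")
    ax.set_xticks(range(shift_matrix.n_areas))
    ax.set_yticks(range(shift_matrix.n_areas))
    ax.set_xticklabels(shift_matrix.area_labels)
    ax.set_yticklabels(shift_matrix.area_labels)
    fig.colorbar(im, ax=ax, label="accuracy shift")
    fig.tight_layout()
    fig.savefig(out / "shift_matrix.png", dpi=120)
    plt.close(fig)

    if len(rf):
        fig, ax = plt.subplots(figsize=(4.5, 3.5))
        for area, grp in rf.groupby("area" if "area" in rf.columns else None):
            ax.scatter(grp["eccentricity"], grp["size"], s=12, alpha=0.6,
                       label=f"area {area}")
        for _, row in lines.iterrows():
            if row.get("skipped", False):
                continue
            x = np.linspace(0, rf["eccentricity"].max(), 10)
            ax.plot(x, row["slope"] * x + row["intercept"], lw=1.5)
        ax.set_xlabel("eccentricity (% span)")
        ax.set_ylabel("pooling-field size (% span)")
        ax.legend(fontsize=7)
        fig.tight_layout()
        fig.savefig(out / "size_eccentricity.png", dpi=120)
        plt.close(fig)
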