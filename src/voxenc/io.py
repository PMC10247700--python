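"""Serialization: HDF5 dataset containers, model archives, CSV exports.

A synthetic subject is stored as one HDF5 file with groups ``/stimuli``
(images, image_id, class, split), ``/betas`` (trials x voxels), ``/trials``
and ``/voxels`` (tables), and a ``span_degrees`` attribute.  Model archives
are .npz bundles of extractor spec + parameters, head parameters, the
training configuration and seed.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .cortex import ResponseDataset
from .extractors import ConvExtractor, ExtractorSpec
from .readout import FlexibleHeadBank
from .stimuli import StimulusSet
from .training import EncodingModel


def _write_table(group: h5py.Group, table: pd.DataFrame) -> None:
    group.attrs["columns"] = json.dumps(list(table.columns))
    for col in table.columns:
        vals = table[col].to_numpy()
        if vals.dtype == object:
            vals = vals.astype("S")
        group.create_dataset(col, data=vals)


def _read_table(group: h5py.Group) -> pd.DataFrame:
    columns = json.loads(group.attrs["columns"])
    data = {}
    for col in columns:
        vals = group[col][...]
        if vals.dtype.kind == "S":
            vals = vals.astype(str)
        data[col] = vals
    return pd.DataFrame(data)


def save_dataset(path: str | Path, stimuli: StimulusSet,
                 dataset: ResponseDataset) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["span_degrees"] = stimuli.span_degrees
        f.attrs["subject"] = dataset.subject
        f.attrs["metadata"] = json.dumps(dataset.metadata)
        g = f.create_group("stimuli")
        g.create_dataset("images", data=stimuli.images,
                         compression="gzip", compression_opts=4)
        _write_table(g.create_group("table"), stimuli.table)
        f.create_dataset("betas", data=dataset.betas,
                         compression="gzip", compression_opts=4)
        if dataset.signal is not None:
            f.create_dataset("signal", data=dataset.signal,
                             compression="gzip", compression_opts=4)
        _write_table(f.create_group("trials"), dataset.trials)
        _write_table(f.create_group("voxels"), dataset.voxels)


def load_dataset(path: str | Path) -> tuple[StimulusSet, ResponseDataset]:
    with h5py.File(path, "r") as f:
        stim = StimulusSet(f["stimuli/images"][...],
                           _read_table(f["stimuli/table"]),
                           float(f.attrs["span_degrees"]))
        dataset = ResponseDataset(
            f["betas"][...], _read_table(f["trials"]), _read_table(f["voxels"]),
            subject=str(f.attrs["subject"]),
            signal=f["signal"][...] if "signal" in f else None,
            metadata=json.loads(f.attrs["metadata"]))
    return stim, dataset


def export_tables_csv(dataset: ResponseDataset, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dataset.trials.to_csv(out / f"{dataset.subject}_trials.csv", index=False)
    dataset.voxels.to_csv(out / f"{dataset.subject}_voxels.csv", index=False)


def spec_hash(spec: ExtractorSpec) -> str:
    return hashlib.sha256(
        json.dumps(spec.to_dict(), sort_keys=True, default=float)
        .encode()).hexdigest()[:16]


def save_model(path: str | Path, model: EncodingModel,
               extra: dict | None = None) -> None:
    arrays = {}
    for i, p in enumerate(model.extractor.params()):
        arrays[f"ext_{i}"] = p.v
    state = model.extractor.state()
    for i, (rm, rv) in enumerate(state["running"]):
        arrays[f"bn_mean_{i}"] = rm
        arrays[f"bn_var_{i}"] = rv
    hstate = model.heads.state()
    for res, grid in hstate["pf_raw"].items():
        arrays[f"pf_{res}"] = grid
    arrays["w"] = hstate["w"]
    arrays["b"] = hstate["b"]
    if model.areas is not None:
        arrays["areas"] = np.asarray(model.areas)
    meta = {"spec": model.extractor.spec.to_dict(),
            "spec_hash": spec_hash(model.extractor.spec),
            "f_in": model.heads.f_in_name, "f_out": model.heads.f_out_name,
            "n_voxels": model.heads.n_voxels,
            "extra": extra or {}}
    arrays["meta"] = np.frombuffer(
        json.dumps(meta, default=float).encode(), dtype=np.uint8)
    np.savez_compressed(path, **arrays)


def load_model(path: str | Path) -> EncodingModel:
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(bytes(z["meta"].tobytes()).decode())
        spec = ExtractorSpec.from_dict(meta["spec"])
        extractor = ConvExtractor(spec, seed=0)
        params = extractor.params()
        for i, p in enumerate(params):
            p.v[...] = z[f"ext_{i}"]
        running = []
        i = 0
        while f"bn_mean_{i}" in z:
            running.append((z[f"bn_mean_{i}"], z[f"bn_var_{i}"]))
            i += 1
        extractor.load_state({"params": [p.v for p in params],
                              "running": running})
        heads = FlexibleHeadBank(extractor.layer_shapes(), meta["n_voxels"],
                                 f_in=meta["f_in"], f_out=meta["f_out"])
        heads.load_state({"pf_raw": {res: z[f"pf_{res}"]
                                     for res in heads.pf_raw},
                          "w": z["w"], "b": z["b"]})
        areas = z["areas"] if "areas" in z else None
    return EncodingModel(extractor, heads, areas=areas)


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        yaml.safe_dump(config, sort_keys=True).encode()).hexdigest()[:16]


def save_feature_maps(path: str | Path, maps) -> None:
    """Export FeatureMaps to HDF5 (one dataset per exposed layer)."""
    with h5py.File(path, "w") as f:
        for lid, vals in maps.layers.items():
            f.create_dataset(lid, data=vals, compression="gzip",
                             compression_opts=4)


def export_pooling_fields(model: EncodingModel, h5_path: str | Path,
                          png_dir: str | Path | None = None) -> None:
    """Export a model's effective pooling-field grids (HDF5, optional PNGs)."""
    grids = model.heads.effective_grids()
    with h5py.File(h5_path, "w") as f:
        for res, g in grids.items():
            f.create_dataset(f"resolution_{res}", data=g)
    if png_dir is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        out = Path(png_dir)
        out.mkdir(parents=True, exist_ok=True)
        res = max(grids)
        for v in range(grids[res].shape[0]):
            fig, ax = plt.subplots(figsize=(2.2, 2.2))
            ax.imshow(grids[res][v], cmap="viridis")
            ax.set_axis_off()
            fig.savefig(out / f"voxel{v:04d}.png", dpi=80,
                        bbox_inches="tight")
            plt.close(fig)
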