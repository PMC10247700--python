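"""Read-out heads: pooling fields, point nonlinearities and linearized prediction.

A read-out head converts the feature maps e_l(x) produced by an extractor into
a predicted voxel response

    r̄_v(x) = b_v + Σ_k w_vk · f_out(Φ_k(x)),
    Φ_k(x) = Σ_ij f_in([e_l(x)]_{k_l ji}) · g^l_{vji},

where g is a nonnegative spatial pooling field normalized to sum to one,
applied per feature-map resolution, and Φ concatenates pooled features across
layers along the feature axis.  Gaussian pooling fields are parametric
(center + isotropic σ); flexible pooling fields learn one nonnegative,
sum-to-one weight grid per distinct feature-map resolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .coords import pixel_centers
from .nn import Param


# ---------------------------------------------------------------------------
# Point nonlinearities

def tanh_log(x):
    """The differentiable readout nonlinearity tanh(x)·ln(1+|x|).

    Odd, differentiable everywhere, with an expansive regime near zero and a
    compressive (but non-plateauing) regime at large |x|.  The logarithm is
    natural.
    """
    x = np.asarray(x, dtype=np.float64)
    return np.tanh(x) * np.log1p(np.abs(x))


def dtanh_log(x):
    x = np.asarray(x, dtype=np.float64)
    t = np.tanh(x)
    return (1.0 - t * t) * np.log1p(np.abs(x)) + t * np.sign(x) / (1.0 + np.abs(x))


def log1p_abs(x):
    x = np.asarray(x, dtype=np.float64)
    return np.log1p(np.abs(x))


def dlog1p_abs(x):
    x = np.asarray(x, dtype=np.float64)
    return np.sign(x) / (1.0 + np.abs(x))


def _identity(x):
    return np.asarray(x, dtype=np.float64)


def _didentity(x):
    return np.ones_like(np.asarray(x, dtype=np.float64))


#: name -> (f, f') registry used by heads and configs
NONLINEARITIES = {
    "identity": (_identity, _didentity),
    "tanh_log": (tanh_log, dtanh_log),
    "log1p_abs": (log1p_abs, dlog1p_abs),
}


def get_nonlinearity(name: str):
    try:
        return NONLINEARITIES[name]
    except KeyError:
        raise ValueError(f"unknown nonlinearity {name!r}; "
                         f"choose from {sorted(NONLINEARITIES)}") from None


# ---------------------------------------------------------------------------
# Pooling fields

@dataclass(frozen=True)
class GaussianPoolingField:
    """Isotropic 2-D Gaussian pooling field.

    ``center`` is (x, y) in % of span (center-origin); ``size`` is the
    standard deviation in % of span.  Rasterization evaluates the Gaussian at
    pixel centers and normalizes the grid to sum to one, so edge truncation
    is absorbed by the normalization.
    """

    center: tuple[float, float]
    size: float

    def __post_init__(self):
        if self.size <= 0:
            raise ValueError("pooling-field size must be > 0")

    def raster(self, resolution: int) -> np.ndarray:
        x, y = pixel_centers(resolution)
        d2 = (x - self.center[0]) ** 2 + (y - self.center[1]) ** 2
        g = np.exp(-0.5 * d2 / self.size ** 2)
        total = g.sum()
        if total <= 0:
            raise ValueError("degenerate pooling field raster")
        return g / total


@dataclass
class FlexiblePoolingField:
    """Per-pixel pooling weights, one grid per feature-map resolution."""

    grids: dict[int, np.ndarray]

    def __post_init__(self):
        for res, g in self.grids.items():
            g = np.asarray(g, dtype=np.float64)
            if (g < 0).any():
                raise ValueError("flexible pooling-field entries must be >= 0")
            if abs(g.sum() - 1.0) > 1e-6:
                raise ValueError("flexible pooling-field grid must sum to 1")
            self.grids[res] = g

    def raster(self, resolution: int) -> np.ndarray:
        try:
            return self.grids[resolution]
        except KeyError:
            raise ValueError(
                f"no pooling grid for resolution {resolution}; "
                f"available: {sorted(self.grids)}") from None


def build_gpf_grid(n_sizes: int = 8, min_size: float = 3.0,
                   max_size: float = 40.0,
                   spacing_factor: float = 1.75) -> list[GaussianPoolingField]:
    """Candidate Gaussian pooling fields tiling the visual field.

    Sizes are log-spaced with endpoints exactly ``min_size`` and ``max_size``
    (% of span).  For each size, centers are laid on a square lattice with
    spacing ``spacing_factor * size`` so that smaller fields are tiled more
    densely; every center lies within the frame.  The candidate count is a
    consequence of this rule and is reported, not asserted.
    """
    if n_sizes < 1:
        raise ValueError("n_sizes must be >= 1")
    if not 0 < min_size < max_size:
        raise ValueError("need 0 < min_size < max_size")
    sizes = np.geomspace(min_size, max_size, n_sizes)
    candidates = []
    for size in sizes:
        spacing = spacing_factor * size
        n = max(1, int(np.floor(100.0 / spacing)))
        offsets = (np.arange(n) - (n - 1) / 2.0) * spacing
        for y in offsets[::-1]:
            for x in offsets:
                candidates.append(GaussianPoolingField((float(x), float(y)),
                                                       float(size)))
    return candidates


# ---------------------------------------------------------------------------
# Functional pooling / prediction (single-voxel reference path)

def pool_features(maps, pf, f_in: str = "identity") -> np.ndarray:
    """Pool feature maps through a pooling field: Φ_k = Σ_ij f_in(e)·g.

    ``maps`` is a FeatureMaps object (see voxenc.extractors) or a dict
    layer_id -> (B, C, H, W) array.  Returns (B, K) with K the total channel
    count across layers, concatenated in extractor depth order.
    """
    fin, _ = get_nonlinearity(f_in)
    layers = maps.layers if hasattr(maps, "layers") else maps
    parts = []
    for vals in layers.values():
        res = vals.shape[-1]
        grid = pf.raster(res)
        parts.append(np.einsum("bchw,hw->bc", fin(vals), grid, optimize=True))
    return np.concatenate(parts, axis=1)


@dataclass
class ReadoutHead:
    """Per-voxel feature weights, bias and point nonlinearities."""

    w: np.ndarray
    b: float
    f_in: str = "identity"
    f_out: str = "identity"
    mask: np.ndarray | None = None  # boolean; False channels contribute 0

    def __post_init__(self):
        self.w = np.asarray(self.w, dtype=np.float64)
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.w.shape:
                raise ValueError("mask shape must match weight shape")


def predict_activity(head: ReadoutHead, phi: np.ndarray) -> np.ndarray:
    """r̄_v = b_v + Σ_k w_vk f_out(Φ_k); masked channels contribute exactly 0."""
    phi = np.asarray(phi, dtype=np.float64)
    if phi.shape[-1] != head.w.shape[0]:
        raise ValueError(f"feature length {phi.shape[-1]} does not match "
                         f"weight length {head.w.shape[0]}")
    fout, _ = get_nonlinearity(head.f_out)
    w = head.w if head.mask is None else np.where(head.mask, head.w, 0.0)
    return head.b + fout(phi) @ w


# ---------------------------------------------------------------------------
# Vectorized flexible-pooling-field head bank (the trainable read-out)

class FlexibleHeadBank:
    """Read-out heads for V voxels sharing one extractor, trained jointly.

    Flexible pooling fields are parameterized by unconstrained grids mapped
    through absolute value and sum-normalization in the forward pass, which
    keeps the pooling weights nonnegative and sum-to-one at every step while
    leaving gradients defined.  One grid per voxel per distinct feature-map
    resolution; weights cover the concatenated feature axis.
    """

    def __init__(self, layer_shapes: list[tuple[str, int, int]], n_voxels: int,
                 f_in: str = "tanh_log", f_out: str = "tanh_log",
                 seed: int = 0):
        # layer_shapes: ordered (layer_id, channels, resolution)
        rng = np.random.default_rng(seed)
        self.f_in_name, self.f_out_name = f_in, f_out
        self.f_in, self.df_in = get_nonlinearity(f_in)
        self.f_out, self.df_out = get_nonlinearity(f_out)
        self.n_voxels = n_voxels
        self.layer_slices: dict[str, tuple[int, int, int]] = {}
        start = 0
        resolutions = []
        for lid, c, res in layer_shapes:
            self.layer_slices[lid] = (start, start + c, res)
            start += c
            if res not in resolutions:
                resolutions.append(res)
        self.n_features = start
        self.pf_raw = {res: Param(1.0 + 0.1 * rng.random((n_voxels, res, res)))
                       for res in resolutions}
        self.w = Param(rng.normal(0.0, 0.01, size=(n_voxels, self.n_features)))
        self.b = Param(np.zeros(n_voxels))
        self._cache = None

    # -- parameter plumbing -------------------------------------------------
    def params(self) -> list[Param]:
        return [*self.pf_raw.values(), self.w, self.b]

    def freeze(self, flag: bool = True) -> None:
        for p in self.params():
            p.frozen = flag

    def state(self) -> dict:
        return {"pf_raw": {r: p.v.copy() for r, p in self.pf_raw.items()},
                "w": self.w.v.copy(), "b": self.b.v.copy()}

    def load_state(self, state: dict) -> None:
        for r, v in state["pf_raw"].items():
            self.pf_raw[r].v[...] = v
        self.w.v[...] = state["w"]
        self.b.v[...] = state["b"]

    # -- effective pooling fields -------------------------------------------
    def effective_grids(self) -> dict[int, np.ndarray]:
        """Normalized nonnegative pooling grids, (V, H, W) per resolution."""
        out = {}
        for res, p in self.pf_raw.items():
            u = np.abs(p.v)
            out[res] = u / u.sum(axis=(1, 2), keepdims=True)
        return out

    def pooling_field(self, voxel: int) -> FlexiblePoolingField:
        grids = self.effective_grids()
        return FlexiblePoolingField({r: g[voxel] for r, g in grids.items()})

    def head(self, voxel: int, mask: np.ndarray | None = None) -> ReadoutHead:
        return ReadoutHead(self.w.v[voxel].copy(), float(self.b.v[voxel]),
                           self.f_in_name, self.f_out_name, mask)

    def layer_mask(self, keep_layers: set[str] | list[str]) -> np.ndarray:
        """Boolean channel mask keeping only the listed layers."""
        mask = np.zeros(self.n_features, dtype=bool)
        for lid in keep_layers:
            if lid not in self.layer_slices:
                raise ValueError(f"unknown layer id {lid!r}")
            s, e, _ = self.layer_slices[lid]
            mask[s:e] = True
        return mask

    # -- forward / backward -------------------------------------------------
    def forward(self, maps, weight_mask: np.ndarray | None = None) -> np.ndarray:
        """Predict (B, V) responses from FeatureMaps; caches for backward."""
        layers = maps.layers if hasattr(maps, "layers") else maps
        grids = {}
        norms = {}
        for res, p in self.pf_raw.items():
            u = np.abs(p.v)
            s = u.sum(axis=(1, 2), keepdims=True)
            grids[res] = u / s
            norms[res] = s
        b = next(iter(layers.values())).shape[0]
        phi = np.empty((b, self.n_voxels, self.n_features))
        fin_vals = {}
        for lid, vals in layers.items():
            s_, e_, res = self.layer_slices[lid]
            a = self.f_in(vals)
            fin_vals[lid] = (vals, a)
            phi[:, :, s_:e_] = np.einsum("bchw,vhw->bvc", a, grids[res],
                                         optimize=True)
        fphi = self.f_out(phi)
        w_eff = self.w.v if weight_mask is None else np.where(weight_mask, self.w.v, 0.0)
        rbar = np.einsum("bvk,vk->bv", fphi, w_eff, optimize=True) + self.b.v[None, :]
        self._cache = (layers, fin_vals, grids, norms, phi, fphi, weight_mask)
        return rbar

    def backward(self, drbar: np.ndarray,
                 need_map_grads: bool = True) -> dict[str, np.ndarray]:
        """Accumulate parameter gradients; return d(loss)/d(feature maps)."""
        layers, fin_vals, grids, norms, phi, fphi, weight_mask = self._cache
        w_eff = self.w.v if weight_mask is None else np.where(weight_mask, self.w.v, 0.0)
        dw = np.einsum("bv,bvk->vk", drbar, fphi, optimize=True)
        if weight_mask is not None:
            dw = np.where(weight_mask, dw, 0.0)
        self.w.g += dw
        self.b.g += drbar.sum(axis=0)
        dphi = drbar[:, :, None] * w_eff[None, :, :] * self.df_out(phi)
        d_maps = {}
        dgrid_acc = {res: np.zeros_like(g) for res, g in grids.items()}
        for lid, (vals, a) in fin_vals.items():
            s_, e_, res = self.layer_slices[lid]
            dpool = dphi[:, :, s_:e_]  # (B, V, C)
            if need_map_grads:
                da = np.einsum("bvc,vhw->bchw", dpool, grids[res], optimize=True)
                d_maps[lid] = da * self.df_in(vals)
            dgrid_acc[res] += np.einsum("bvc,bchw->vhw", dpool, a, optimize=True)
        for res, dgrid in dgrid_acc.items():
            g = grids[res]
            s = norms[res]
            # back through normalization u/sum(u), then through abs
            du = (dgrid - (dgrid * g).sum(axis=(1, 2), keepdims=True)) / s
            self.pf_raw[res].g += du * np.sign(self.pf_raw[res].v)
        return d_maps
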