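"""Feature extractors: trainable convolutional branches, a fixed Gabor bank,
and adapters for frozen backbones.

A trainable extractor is a prefilter (strided convolution) followed by groups
of blocks; each block is batch-normalization -> dropout -> resolution-
preserving convolution -> rectification, and groups are separated by 2x max
pooling.  The set of block outputs exposed to the read-out heads is declared
in the spec; the effective receptive field of the deepest exposed layer must
cover the full input frame, which is verified at build time from the kernel
and stride bookkeeping.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from .filters import FilterBank

from .nn import Conv2d, BatchNorm2d, Dropout, ReLU, MaxPool2d, Param


# ---------------------------------------------------------------------------
# Specs and containers

@dataclass
class BlockSpec:
    channels: int
    kernel: int = 3
    dropout: float = 0.25


@dataclass
class GroupSpec:
    blocks: list[BlockSpec]
    pool_after: bool = False


@dataclass
class ExtractorSpec:
    """Architecture of a trainable convolutional feature extractor.

    ``prefilter_type`` selects the front end: a trainable strided
    convolution ("conv") or a fixed oriented-energy stage
    ("gabor-energy") that stands in for a frozen task-optimized prefilter.
    """

    input_resolution: int
    prefilter_type: str = "conv"
    prefilter_channels: int = 16
    prefilter_kernel: int = 5
    prefilter_stride: int = 2
    prefilter_frequencies: tuple[float, ...] = (3.0, 6.0, 12.0)
    prefilter_orientations: int = 4
    groups: list[GroupSpec] = field(default_factory=list)
    exposed: list[str] | str = "all"  # block ids, or "all"
    expose_prefilter: bool = False

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ExtractorSpec":
        groups = [GroupSpec([BlockSpec(**b) for b in g["blocks"]],
                            g.get("pool_after", False)) for g in d["groups"]]
        kw = {k: v for k, v in d.items() if k != "groups"}
        return cls(groups=groups, **kw)


def default_extractor_spec(resolution: int, base_channels: int = 8,
                           dropout: float = 0.25, prefilter: str = "conv",
                           expose_prefilter: bool | None = None) -> ExtractorSpec:
    """A spec whose deepest exposed layer covers the full frame.

    Groups (two blocks each, channel count doubling per group) separated by
    max-pooling steps are appended until the deepest effective receptive
    field reaches the input resolution.  With the fixed "gabor-energy"
    prefilter the front end already spans the frame and is exposed to the
    read-out by default.
    """
    groups: list[GroupSpec] = []
    rf, jump = 5, 2  # group layout sized as for a k=5 stride-2 front end
    res = resolution // 2
    ch = base_channels
    while True:
        groups.append(GroupSpec([BlockSpec(ch, 3, dropout),
                                 BlockSpec(ch, 3, dropout)]))
        rf += 2 * (2 * jump)  # two 3x3 convs
        if rf >= resolution or res < 8 or len(groups) >= 8:
            break
        groups[-1].pool_after = True  # pool between groups
        rf += jump
        jump *= 2
        res //= 2
        ch *= 2
    if expose_prefilter is None:
        expose_prefilter = prefilter == "gabor-energy"
    return ExtractorSpec(input_resolution=resolution,
                         prefilter_type=prefilter,
                         prefilter_channels=base_channels,
                         prefilter_kernel=5, prefilter_stride=2,
                         groups=groups,
                         expose_prefilter=expose_prefilter)


class GaborEnergyPrefilter:
    """Fixed oriented-energy front end: Gabor amplitude maps + 2x average pool.

    Parameter-free and frozen by construction; serves as the stand-in for a
    pretrained prefilter network so that every model built on it shares an
    identical early-vision representation.  Because the stage is frozen its
    per-image outputs are memoized, so repeated passes over a finite
    stimulus set only pay the convolution cost once per image.
    """

    def __init__(self, resolution: int, frequencies: tuple[float, ...],
                 n_orientations: int, cache_images: int = 8192):
        from skimage.filters import gabor_kernel
        self.resolution = resolution
        thetas = np.arange(n_orientations) * np.pi / n_orientations
        kernels = [np.asarray(gabor_kernel(frequency=f / resolution, theta=t))
                   for f in frequencies for t in thetas]
        self._bank = FilterBank(kernels, resolution)
        self.n_channels = self._bank.n_channels
        self._cache: dict[bytes, np.ndarray] = {}
        self._cache_limit = cache_images

    def params(self):
        return []

    def _compute(self, imgs: np.ndarray) -> np.ndarray:
        out = self._bank.energy(imgs)
        b, c, h, w = out.shape
        return out.reshape(b, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5))

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        imgs = x[:, 0] if x.ndim == 4 else x
        imgs = np.ascontiguousarray(imgs)
        keys = [imgs[i].tobytes() for i in range(imgs.shape[0])]
        missing = [i for i, k in enumerate(keys) if k not in self._cache]
        if missing:
            fresh = self._compute(imgs[missing])
            if len(self._cache) + len(missing) > self._cache_limit:
                self._cache.clear()
            for j, i in enumerate(missing):
                self._cache[keys[i]] = fresh[j]
        return np.stack([self._cache[k] for k in keys])

    def backward(self, dy):  # first element of the stack; gradient unused
        return None


class FeatureMaps:
    """Ordered per-layer feature maps for a batch of stimuli."""

    def __init__(self, layers: dict[str, np.ndarray]):
        self.layers = layers  # insertion order == extractor depth order

    @property
    def n_batch(self) -> int:
        return next(iter(self.layers.values())).shape[0]

    def layer_shapes(self) -> list[tuple[str, int, int]]:
        """Ordered (layer_id, channels, resolution)."""
        return [(lid, v.shape[1], v.shape[2]) for lid, v in self.layers.items()]

    def subset(self, idx) -> "FeatureMaps":
        return FeatureMaps({lid: v[idx] for lid, v in self.layers.items()})

    def concat_channels(self) -> dict[int, np.ndarray]:
        """Concatenate layers sharing a resolution: res -> (B, C_total, H, W)."""
        by_res: dict[int, list[np.ndarray]] = {}
        for v in self.layers.values():
            by_res.setdefault(v.shape[-1], []).append(v)
        return {r: np.concatenate(vs, axis=1) for r, vs in by_res.items()}


# ---------------------------------------------------------------------------
# Trainable convolutional extractor

class ConvExtractor:
    """Trainable layered extractor with explicit backprop.

    The forward pass returns :class:`FeatureMaps` of the exposed layers;
    ``backward`` takes gradients with respect to those exposed maps and
    accumulates parameter gradients.
    """

    def __init__(self, spec: ExtractorSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        self._elements: list[tuple[str, list]] = []  # (id, [layers])
        res = spec.input_resolution
        if spec.prefilter_type == "gabor-energy":
            pre = GaborEnergyPrefilter(res, spec.prefilter_frequencies,
                                       spec.prefilter_orientations)
            # lowest-frequency kernel effectively spans the frame
            rf, jump = res, 2
            res = res // 2
            n_pre = pre.n_channels
        elif spec.prefilter_type == "conv":
            pre = Conv2d(1, spec.prefilter_channels, spec.prefilter_kernel,
                         stride=spec.prefilter_stride,
                         pad=spec.prefilter_kernel // 2, rng=rng)
            rf, jump = spec.prefilter_kernel, spec.prefilter_stride
            res = (res + 2 * (spec.prefilter_kernel // 2) - spec.prefilter_kernel) \
                // spec.prefilter_stride + 1
            n_pre = spec.prefilter_channels
        else:
            raise ValueError(f"unknown prefilter type {spec.prefilter_type!r}")
        self._elements.append(("prefilter", [pre]))
        self._layer_meta = {"prefilter": (n_pre, res, rf)}
        cin = n_pre
        for gi, group in enumerate(spec.groups, start=1):
            for bi, blk in enumerate(group.blocks, start=1):
                lid = f"g{gi}b{bi}"
                ops = [BatchNorm2d(cin), Dropout(blk.dropout),
                       Conv2d(cin, blk.channels, blk.kernel, stride=1, rng=rng),
                       ReLU()]
                rf = rf + (blk.kernel - 1) * jump
                self._elements.append((lid, ops))
                self._layer_meta[lid] = (blk.channels, res, rf)
                cin = blk.channels
            if group.pool_after:
                if res % 2:
                    raise ValueError(f"cannot pool odd resolution {res}")
                rf += jump
                jump *= 2
                res //= 2
                self._elements.append((f"pool{gi}", [MaxPool2d()]))

        if spec.exposed == "all":
            exposed = [lid for lid, _ in self._elements if lid.startswith("g")]
            if spec.expose_prefilter:
                exposed = ["prefilter"] + exposed
        else:
            exposed = list(spec.exposed)
        unknown = set(exposed) - set(self._layer_meta)
        if unknown:
            raise ValueError(f"exposed layer ids not defined: {sorted(unknown)}")
        self.exposed = exposed
        deepest = exposed[-1]
        deepest_rf = self._layer_meta[deepest][2]
        if deepest_rf < spec.input_resolution:
            raise ValueError(
                f"deepest exposed layer {deepest!r} has effective receptive "
                f"field {deepest_rf} px, smaller than the {spec.input_resolution} px "
                f"frame; add groups/pooling so the deepest layer covers the frame")
        self._train_rng: np.random.Generator | None = None

    # -- bookkeeping --------------------------------------------------------
    def layer_shapes(self) -> list[tuple[str, int, int]]:
        return [(lid, *self._layer_meta[lid][:2]) for lid in self.exposed]

    def params(self) -> list[Param]:
        out = []
        for _, ops in self._elements:
            for op in ops:
                out.extend(op.params())
        return out

    def freeze(self, flag: bool = True) -> None:
        for p in self.params():
            p.frozen = flag

    def set_train_rng(self, rng: np.random.Generator) -> None:
        self._train_rng = rng
        for _, ops in self._elements:
            for op in ops:
                if isinstance(op, Dropout):
                    op.rng = rng

    def state(self) -> dict:
        vals = [p.v.copy() for p in self.params()]
        running = []
        for _, ops in self._elements:
            for op in ops:
                if isinstance(op, BatchNorm2d):
                    running.append((op.running_mean.copy(), op.running_var.copy()))
        return {"params": vals, "running": running}

    def load_state(self, state: dict) -> None:
        for p, v in zip(self.params(), state["params"]):
            p.v[...] = v
        it = iter(state["running"])
        for _, ops in self._elements:
            for op in ops:
                if isinstance(op, BatchNorm2d):
                    rm, rv = next(it)
                    op.running_mean[...] = rm
                    op.running_var[...] = rv

    # -- forward / backward -------------------------------------------------
    def forward(self, images: np.ndarray, train: bool = False) -> FeatureMaps:
        """images: (B, R, R) grayscale in [0, 1]."""
        if images.ndim == 3:
            x = images[:, None, :, :]
        else:
            x = images
        if x.shape[-1] != self.spec.input_resolution:
            raise ValueError(
                f"input resolution {x.shape[-1]} does not match extractor "
                f"input resolution {self.spec.input_resolution}")
        out: dict[str, np.ndarray] = {}
        for lid, ops in self._elements:
            for op in ops:
                x = op.forward(x, train=train)
            if lid in self.exposed:
                out[lid] = x
        return FeatureMaps(out)

    def backward(self, d_maps: dict[str, np.ndarray]) -> None:
        grad = None
        for lid, ops in reversed(self._elements):
            if lid in d_maps:
                grad = d_maps[lid] if grad is None else grad + d_maps[lid]
            if grad is None:
                continue
            for op in reversed(ops):
                grad = op.backward(grad)


class MultiBranchExtractor:
    """Independent extractor branches, one per area; branches share nothing."""

    def __init__(self, branches: dict[str, ConvExtractor]):
        self.branches = branches

    def forward(self, images: np.ndarray, train: bool = False) -> dict[str, FeatureMaps]:
        return {name: ext.forward(images, train=train)
                for name, ext in self.branches.items()}


# ---------------------------------------------------------------------------
# Gabor wavelet bank

@dataclass
class GaborBankSpec:
    """Fixed Gabor bank: frequencies in cycles/stimulus, orientations in [0, π)."""

    frequencies: tuple[float, ...] = tuple(np.geomspace(3.0, 72.0, 12))
    orientations: tuple[float, ...] = tuple(np.arange(6) * np.pi / 6)
    quadrature: bool = True

    def __post_init__(self):
        freqs = np.asarray(self.frequencies, dtype=float)
        if not (np.diff(freqs) > 0).all():
            raise ValueError("frequencies must be strictly increasing")
        self.frequencies = tuple(freqs)
        self.orientations = tuple(float(o) for o in self.orientations)


class GaborBank:
    """Fixed (non-trainable) single-layer extractor of Gabor energy maps.

    With quadrature on, the output per (frequency, orientation) is the
    amplitude sqrt(s² + c²) of the sine/cosine pair, which is invariant to
    carrier phase; with quadrature off, the cosine-phase response is returned.
    Kernels come from scikit-image's ``gabor_kernel``.
    """

    layer_id = "gabor"

    def __init__(self, spec: GaborBankSpec, resolution: int):
        from skimage.filters import gabor_kernel
        nyquist = resolution / 2.0
        too_high = [f for f in spec.frequencies if f > nyquist]
        if too_high:
            raise ValueError(
                f"frequencies {too_high} cyc/stimulus exceed the Nyquist limit "
                f"{nyquist} for resolution {resolution}")
        self.spec = spec
        self.resolution = resolution
        self.kernels = []
        for f in spec.frequencies:
            for theta in spec.orientations:
                k = gabor_kernel(frequency=f / resolution, theta=theta)
                self.kernels.append(np.asarray(k))
        self._bank = FilterBank(self.kernels, resolution)

    @property
    def n_channels(self) -> int:
        return len(self.kernels)

    def layer_shapes(self) -> list[tuple[str, int, int]]:
        return [(self.layer_id, self.n_channels, self.resolution)]

    def forward(self, images: np.ndarray, train: bool = False) -> FeatureMaps:
        if images.ndim == 4:
            images = images[:, 0]
        if images.shape[-1] != self.resolution:
            raise ValueError(f"input resolution {images.shape[-1]} does not "
                             f"match bank resolution {self.resolution}")
        resp = self._bank.convolve(np.asarray(images, dtype=np.float64))
        out = np.abs(resp) if self.spec.quadrature else resp.real
        return FeatureMaps({self.layer_id: out})

    def linear_responses(self, images: np.ndarray) -> np.ndarray:
        """Pre-energy (linear-stage) complex filter responses, (B, C, H, W)."""
        if images.ndim == 4:
            images = images[:, 0]
        return self._bank.convolve(np.asarray(images, dtype=np.float64))


class FrozenBackbone:
    """Adapter marking any extractor as a frozen (task-optimized-style) backbone."""

    def __init__(self, extractor):
        self.extractor = extractor
        if hasattr(extractor, "freeze"):
            extractor.freeze(True)

    def layer_shapes(self):
        return self.extractor.layer_shapes()

    def forward(self, images, train: bool = False) -> FeatureMaps:
        return self.extractor.forward(images, train=False)


# ---------------------------------------------------------------------------
# Operations

def extract_features(extractor, stimuli) -> FeatureMaps:
    """Deterministic evaluation-mode feature extraction.

    ``stimuli`` may be a StimulusSet or a bare (N, R, R) image array.
    """
    images = stimuli.images if hasattr(stimuli, "images") else stimuli
    return extractor.forward(np.asarray(images, dtype=np.float64), train=False)


def spec_to_yaml(spec: ExtractorSpec) -> str:
    import yaml
    return yaml.safe_dump(spec.to_dict(), sort_keys=False)


def spec_from_yaml(text: str) -> ExtractorSpec:
    import yaml
    return ExtractorSpec.from_dict(yaml.safe_load(text))


def select_feature_maps(maps: FeatureMaps, n_keep: int) -> dict[str, np.ndarray]:
    """Per-layer boolean channel masks keeping the n_keep highest-variance maps.

    Variance is computed per channel over all reference stimuli and pixels.
    If a layer has at most ``n_keep`` channels the identity mask is returned;
    ties at the cutoff are broken in favor of the lower channel index.
    """
    if n_keep < 1:
        raise ValueError("n_keep must be >= 1")
    masks = {}
    for lid, vals in maps.layers.items():
        c = vals.shape[1]
        if c <= n_keep:
            masks[lid] = np.ones(c, dtype=bool)
            continue
        var = vals.transpose(1, 0, 2, 3).reshape(c, -1).var(axis=1)
        # stable sort on -variance keeps lower indices first among ties
        order = np.argsort(-var, kind="stable")
        keep = np.zeros(c, dtype=bool)
        keep[order[:n_keep]] = True
        masks[lid] = keep
    return masks
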