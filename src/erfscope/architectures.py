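"""ERF-controlled bottleneck-residual architectures.

The probing framework studies how the *effective receptive field* (ERF) of a
convolutional classifier constrains what it can learn.  The family of
networks generated here keeps depth, widths and strides fixed (4 blocks of
2/3/3/2 bottleneck residual units, unit output widths 128/256/512/1024,
block strides 2/2/2/1) and varies only the middle kernel of each bottleneck
unit, which moves the last-layer ERF through 11, 23, 47, 95 or 227 pixels.

Conventions (normative for the printed ERFs to come out exactly):

* a 3x3 stride-1 stem convolution precedes block 1;
* each block's stride is applied on the first 1x1 convolution of its first
  unit (before the k x k layer);
* "same" padding everywhere, so grids depend only on strides.

A bottleneck unit is 1x1 -> k x k -> 1x1 with the k x k layer at one quarter
of the unit's output width; the shortcut is the identity, or a strided 1x1
projection when the stride or width changes.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import nn

__all__ = [
    "LayerGeometry",
    "BlockSpec",
    "ArchitectureSpec",
    "ERFResult",
    "TABLE1_KERNELS",
    "CANONICAL_WIDTHS",
    "make_erf_variant",
    "compute_erf",
    "count_parameters",
    "build_network",
    "ResidualUnit",
    "Network",
]

#: middle-kernel lists of the five canonical variants, keyed by their ERF
TABLE1_KERNELS = {
    "erf11": ((3, 3), (1, 1, 1), (1, 1, 1), (1, 1)),
    "erf23": ((3, 5), (3, 1, 1), (1, 1, 1), (1, 1)),
    "erf47": ((3, 5), (3, 3, 5), (1, 1, 1), (1, 1)),
    "erf95": ((3, 5), (3, 3, 5), (3, 3, 3), (1, 1)),
    "erf227": ((5, 5), (5, 5, 5), (5, 5, 5), (5, 5)),
}

CANONICAL_UNITS = (2, 3, 3, 2)
CANONICAL_WIDTHS = (128, 256, 512, 1024)
CANONICAL_STRIDES = (2, 2, 2, 1)


@dataclass
class LayerGeometry:
    """Geometry of one convolution: odd kernel, stride, per-side padding."""

    kernel_size: int
    stride: int = 1
    padding: int | None = None  # None -> "same", i.e. (k-1)//2

    def __post_init__(self):
        if self.kernel_size < 1:
            raise ValueError("kernel_size must be >= 1")
        if self.kernel_size % 2 == 0:
            raise ValueError("kernel_size must be odd")
        if self.stride < 1:
            raise ValueError("stride must be >= 1")
        if self.padding is None:
            self.padding = (self.kernel_size - 1) // 2


@dataclass
class ResidualUnitSpec:
    """Bottleneck unit: 1x1 (stride) -> middle_kernel -> 1x1."""

    middle_kernel: int
    stride: int = 1
    width: int = 0          # channels of the k x k layer
    output_width: int = 0   # channels after the final 1x1


@dataclass
class BlockSpec:
    n_units: int
    width: int              # unit *output* width at multiplier 1.0
    stride: int             # applied on the first 1x1 of the first unit
    middle_kernels: tuple[int, ...]

    def __post_init__(self):
        self.middle_kernels = tuple(int(k) for k in self.middle_kernels)
        if len(self.middle_kernels) != self.n_units:
            raise ValueError(
                f"block has {self.n_units} units but "
                f"{len(self.middle_kernels)} middle kernels")


@dataclass
class ArchitectureSpec:
    stem: LayerGeometry
    blocks: list[BlockSpec]
    n_classes: int
    input_size: int = 224
    width_multiplier: float = 1.0
    stem_width: int = 64
    seed: int = 0

    # -- derived widths ----------------------------------------------------
    def scaled_width(self, width: int) -> int:
        return max(1, int(round(width * self.width_multiplier)))

    def scaled_stem_width(self) -> int:
        # floored so tiny multipliers keep a functional stem
        return max(8, self.scaled_width(self.stem_width))

    @staticmethod
    def middle_width(output_width: int) -> int:
        """Bottleneck (k x k layer) width: a quarter of the output width.

        Floored at 4 channels so that strongly width-scaled instantiations
        do not squeeze all information through 1-2 random channels; the
        floor never binds at the canonical multiplier 1.0.
        """
        return min(output_width, max(4, output_width // 4))

    @property
    def output_width(self) -> int:
        return self.scaled_width(self.blocks[-1].width)

    # -- (de)serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ArchitectureSpec":
        d = dict(d)
        d["stem"] = LayerGeometry(**d["stem"])
        d["blocks"] = [BlockSpec(**b) for b in d["blocks"]]
        return cls(**d)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        text = (yaml.safe_dump(self.to_dict())
                if path.suffix in {".yml", ".yaml"}
                else json.dumps(self.to_dict(), indent=2))
        path.write_text(text)

    @classmethod
    def load(cls, path: str | Path) -> "ArchitectureSpec":
        path = Path(path)
        raw = path.read_text()
        d = (yaml.safe_load(raw) if path.suffix in {".yml", ".yaml"}
             else json.loads(raw))
        return cls.from_dict(d)


@dataclass
class ERFResult:
    """Per-layer receptive-field bookkeeping in forward order.

    ``layers`` maps layer name -> {"erf": px, "jump": px, "grid": cells};
    the jump is the input-pixel spacing of adjacent units of that layer.
    """

    layers: dict[str, dict] = field(default_factory=dict)

    @property
    def network_erf(self) -> int:
        return list(self.layers.values())[-1]["erf"]

    def __getitem__(self, name: str) -> dict:
        return self.layers[name]


def make_erf_variant(variant_kernels, width_multiplier: float = 1.0,
                     n_classes: int = 1000, input_size: int = 224,
                     seed: int = 0) -> ArchitectureSpec:
    """Build an ArchitectureSpec from the four per-block middle-kernel lists.

    ``variant_kernels`` may also be one of the canonical names
    ("erf11" ... "erf227").
    """
    if isinstance(variant_kernels, str):
        try:
            variant_kernels = TABLE1_KERNELS[variant_kernels.lower()]
        except KeyError:
            raise ValueError(
                f"unknown variant {variant_kernels!r}; "
                f"choose from {sorted(TABLE1_KERNELS)}") from None
    variant_kernels = tuple(tuple(int(k) for k in ks) for ks in variant_kernels)
    if len(variant_kernels) != 4:
        raise ValueError(f"expected 4 kernel sublists, got {len(variant_kernels)}")
    for ks, n in zip(variant_kernels, CANONICAL_UNITS):
        if len(ks) != n:
            raise ValueError(
                f"kernel sublists must have lengths {CANONICAL_UNITS}, "
                f"got {[len(k) for k in variant_kernels]}")
    flat = [k for ks in variant_kernels for k in ks]
    if any(k not in (1, 3, 5) for k in flat):
        warnings.warn("kernel outside {1,3,5}: non-canonical variant",
                      stacklevel=2)

    blocks = [
        BlockSpec(n_units=n, width=w, stride=s, middle_kernels=ks)
        for n, w, s, ks in zip(CANONICAL_UNITS, CANONICAL_WIDTHS,
                               CANONICAL_STRIDES, variant_kernels)
    ]
    return ArchitectureSpec(stem=LayerGeometry(3, 1), blocks=blocks,
                            n_classes=n_classes, input_size=input_size,
                            width_multiplier=width_multiplier, seed=seed)


# ---------------------------------------------------------------------------
# layer plan: single source of truth for ERF arithmetic, parameter counting
# and network construction
# ---------------------------------------------------------------------------

def _layer_plan(spec: ArchitectureSpec):
    """Yield (name, kind, info) in forward order.

    kind "conv": info = (in_ch, out_ch, kernel, stride, on_main_path)
    kind "dense": info = (in_dim, out_dim)
    """
    yield ("stem", "conv",
           (1, spec.scaled_stem_width(), spec.stem.kernel_size,
            spec.stem.stride, True))
    in_ch = spec.scaled_stem_width()
    for b, block in enumerate(spec.blocks, start=1):
        out_ch = spec.scaled_width(block.width)
        mid = spec.middle_width(out_ch)
        for u in range(block.n_units):
            stride = block.stride if u == 0 else 1
            k = block.middle_kernels[u]
            pre = f"block{b}.unit{u + 1}"
            yield (f"{pre}.conv1", "conv", (in_ch, mid, 1, stride, True))
            yield (f"{pre}.conv2", "conv", (mid, mid, k, 1, True))
            yield (f"{pre}.conv3", "conv", (mid, out_ch, 1, 1, True))
            if stride != 1 or in_ch != out_ch:
                yield (f"{pre}.shortcut", "conv",
                       (in_ch, out_ch, 1, stride, False))
            in_ch = out_ch
    yield ("fc", "dense", (in_ch, spec.n_classes))


def compute_erf(spec: ArchitectureSpec) -> ERFResult:
    """Analytic theoretical receptive field of every layer.

    Standard receptive-field arithmetic along the main path, in forward
    order: erf += (k - 1) * jump, then jump *= stride.  Shortcut
    projections (1x1) never extend the field and are skipped.  The grid
    entry is the spatial side of the feature map under "same" padding.
    """
    result = ERFResult()
    erf, jump, grid = 1, 1, spec.input_size
    for name, kind, info in _layer_plan(spec):
        if kind != "conv":
            continue
        in_ch, out_ch, k, stride, main = info
        if not main:
            continue
        erf += (k - 1) * jump
        jump *= stride
        grid = -(-grid // stride)  # ceil for "same" padding
        result.layers[name] = {"erf": erf, "jump": jump, "grid": grid}
    return result


def count_parameters(spec: ArchitectureSpec) -> int:
    """Closed-form trainable-parameter count of the canonical network.

    Convolutions carry no bias (batch normalization follows each one and
    contributes scale+shift per channel); the classifier is a single dense
    layer with bias on the pooled features.
    """
    total = 0
    for name, kind, info in _layer_plan(spec):
        if kind == "conv":
            in_ch, out_ch, k, stride, main = info
            total += k * k * in_ch * out_ch  # weights
            total += 2 * out_ch              # batch-norm affine
        else:
            in_dim, out_dim = info
            total += in_dim * out_dim + out_dim
    return total


# ---------------------------------------------------------------------------
# network construction
# ---------------------------------------------------------------------------

class ResidualUnit(nn.Module):
    """Bottleneck residual unit: 1x1(stride) -> k x k -> 1x1 (+ shortcut)."""

    def __init__(self, in_ch, mid, out_ch, kernel, stride, rng,
                 batchnorm=True, activation="relu"):
        super().__init__()
        act = nn.ReLU if activation == "relu" else nn.Identity
        bn = nn.BatchNorm2d if batchnorm else (lambda c: nn.Identity())
        self.conv1 = nn.Conv2d(in_ch, mid, 1, stride, rng=rng)
        self.bn1 = bn(mid)
        self.act1 = act()
        self.conv2 = nn.Conv2d(mid, mid, kernel, 1, rng=rng)
        self.bn2 = bn(mid)
        self.act2 = act()
        self.conv3 = nn.Conv2d(mid, out_ch, 1, 1, rng=rng)
        self.bn3 = bn(out_ch)
        self.act_out = act()
        if stride != 1 or in_ch != out_ch:
            self.short_conv = nn.Conv2d(in_ch, out_ch, 1, stride, rng=rng)
            self.short_bn = bn(out_ch)
            self._projected = True
        else:
            self._projected = False

    def forward(self, x, training=False):
        h = self.act1(self.bn1(self.conv1(x, training), training), training)
        h = self.act2(self.bn2(self.conv2(h, training), training), training)
        h = self.bn3(self.conv3(h, training), training)
        if self._projected:
            s = self.short_bn(self.short_conv(x, training), training)
        else:
            s = x
        return self.act_out(h + s, training)

    def backward(self, dy):
        dy = self.act_out.backward(dy)
        dh = self.conv1.backward(self.bn1.backward(self.act1.backward(
            self.conv2.backward(self.bn2.backward(self.act2.backward(
                self.conv3.backward(self.bn3.backward(dy))))))))
        if self._projected:
            ds = self.short_conv.backward(self.short_bn.backward(dy))
        else:
            ds = dy
        return dh + ds


class Network(nn.Module):
    """ERF-variant residual classifier.

    ``forward`` returns logits.  ``forward(..., capture=dict)`` fills the
    dict with the output grid of every residual unit ("block{b}.unit{u}"),
    the pooled vector ("gap") and the class probabilities ("softmax") —
    the 12 layers used by the representational analyses.
    """

    def __init__(self, spec: ArchitectureSpec, batchnorm=True,
                 activation="relu", rng: np.random.Generator | None = None):
        super().__init__()
        if rng is None:
            rng = np.random.default_rng(spec.seed)
        self.spec = spec
        sw = spec.scaled_stem_width()
        self.stem_conv = nn.Conv2d(1, sw, spec.stem.kernel_size,
                                   spec.stem.stride, rng=rng)
        self.stem_bn = nn.BatchNorm2d(sw) if batchnorm else nn.Identity()
        self.stem_act = nn.ReLU() if activation == "relu" else nn.Identity()
        self.unit_names: list[str] = []
        units = []
        in_ch = sw
        for b, block in enumerate(spec.blocks, start=1):
            out_ch = spec.scaled_width(block.width)
            mid = spec.middle_width(out_ch)
            for u in range(block.n_units):
                stride = block.stride if u == 0 else 1
                unit = ResidualUnit(in_ch, mid, out_ch,
                                    block.middle_kernels[u], stride, rng,
                                    batchnorm=batchnorm, activation=activation)
                name = f"block{b}.unit{u + 1}"
                setattr(self, name.replace(".", "_"), unit)
                units.append(unit)
                self.unit_names.append(name)
                in_ch = out_ch
        self.units = units
        self.gap = nn.GlobalAvgPool()
        self.fc = nn.Dense(in_ch, spec.n_classes, rng=rng)

    # -- forward -----------------------------------------------------------
    # the backend runs channels-last (NHWC); the public API speaks NCHW and
    # converts at these boundaries only.

    def _features(self, x_nhwc, training=False, capture: dict | None = None):
        h = self.stem_act(self.stem_bn(self.stem_conv(x_nhwc, training),
                                       training), training)
        for name, unit in zip(self.unit_names, self.units):
            h = unit.forward(h, training)
            if capture is not None:
                capture[name] = np.ascontiguousarray(h.transpose(0, 3, 1, 2))
        return h

    def _head(self, feats_nhwc, training=False, capture: dict | None = None):
        pooled = self.gap(feats_nhwc, training)
        logits = self.fc(pooled, training)
        if capture is not None:
            capture["gap"] = pooled
            capture["softmax"] = nn.softmax(logits)
        return logits

    @staticmethod
    def _to_nhwc(x):
        if x.ndim != 4:
            raise ValueError("expected NCHW input")
        if x.shape[2] != x.shape[3]:
            raise ValueError("input images must be square")
        return np.ascontiguousarray(
            np.asarray(x, dtype=np.float32).transpose(0, 2, 3, 1))

    def features(self, x, training=False, capture: dict | None = None):
        """Last-convolutional-layer activation grid (N, C, H, W)."""
        h = self._features(self._to_nhwc(x), training, capture)
        return np.ascontiguousarray(h.transpose(0, 3, 1, 2))

    def head(self, feats, training=False, capture: dict | None = None):
        """GAP + dense classifier on an (N, C, H, W) feature grid."""
        f = np.ascontiguousarray(feats.transpose(0, 2, 3, 1))
        return self._head(f, training, capture)

    def forward(self, x, training=False, capture: dict | None = None):
        h = self._features(self._to_nhwc(x), training, capture)
        return self._head(h, training, capture)

    def predict_proba(self, x):
        return nn.softmax(self.forward(x))

    def predict(self, x):
        return np.argmax(self.forward(x), axis=1)

    # -- backward ----------------------------------------------------------
    def backward(self, dlogits):
        dy = self.gap.backward(self.fc.backward(dlogits))
        return self._backward_units(dy)

    def _backward_units(self, dy_nhwc):
        dy = dy_nhwc
        for unit in reversed(self.units):
            dy = unit.backward(dy)
        return self.stem_conv.backward(
            self.stem_bn.backward(self.stem_act.backward(dy)))

    def backward_from_features(self, dfeat):
        """Input gradient from an (N, C, H, W) last-layer gradient."""
        dy = np.ascontiguousarray(dfeat.transpose(0, 2, 3, 1))
        dx = self._backward_units(dy)
        return np.ascontiguousarray(dx.transpose(0, 3, 1, 2))

    # -- checkpointing -----------------------------------------------------
    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savez_compressed(path, __spec__=json.dumps(self.spec.to_dict()),
                            **self.state_dict())

    @classmethod
    def load_checkpoint(cls, path: str | Path) -> "Network":
        with np.load(Path(path), allow_pickle=False) as z:
            spec = ArchitectureSpec.from_dict(json.loads(str(z["__spec__"])))
            net = cls(spec)
            net.load_state_dict({k: z[k] for k in z.files if k != "__spec__"})
        return net


class FoldedNetwork:
    """Inference-only copy of a Network with batch-norm folded into convs.

    Eval-mode batch normalization is an affine map per channel, so it can
    be absorbed exactly into the preceding convolution's weights plus a
    bias.  Used to speed up repeated feature extraction from a frozen
    base; produces outputs identical to ``Network.features`` (eval mode)
    up to float32 rounding.
    """

    def __init__(self, net: "Network"):
        if not isinstance(net.stem_act, nn.ReLU):
            raise ValueError("folding assumes ReLU activations")
        self.spec = net.spec

        def fold(conv: nn.Conv2d, bn) -> tuple[np.ndarray, np.ndarray, int]:
            w = conv.weight.data
            if isinstance(bn, nn.BatchNorm2d):
                invstd = 1.0 / np.sqrt(bn.running_var + bn.eps)
                scale = (bn.gamma.data * invstd).astype(np.float32)
                bias = (bn.beta.data - bn.running_mean * scale
                        ).astype(np.float32)
            else:
                scale = np.ones(conv.out_ch, dtype=np.float32)
                bias = np.zeros(conv.out_ch, dtype=np.float32)
            return (w * scale[:, None, None, None], bias, conv.stride)

        self.stem = fold(net.stem_conv, net.stem_bn)
        self.units = []
        for unit in net.units:
            folded = {
                "conv1": fold(unit.conv1, unit.bn1),
                "conv2": fold(unit.conv2, unit.bn2),
                "conv3": fold(unit.conv3, unit.bn3),
                "short": (fold(unit.short_conv, unit.short_bn)
                          if unit._projected else None),
            }
            self.units.append(folded)

    @staticmethod
    def _conv(x, folded):
        w, bias, s = folded
        k = w.shape[2]
        if k == 1:
            xs = x[:, ::s, ::s, :]
            y = xs.reshape(-1, w.shape[1]) @ w[:, :, 0, 0].T
            return y.reshape(xs.shape[:3] + (w.shape[0],)) + bias
        p = (k - 1) // 2
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        ho = (x.shape[1] + 2 * p - k) // s + 1
        wo = (x.shape[2] + 2 * p - k) // s + 1
        acc = np.zeros((x.shape[0], ho, wo, w.shape[0]), dtype=np.float32)
        for di in range(k):
            for dj in range(k):
                xs = xp[:, di:di + s * ho:s, dj:dj + s * wo:s, :]
                acc += np.tensordot(xs, w[:, :, di, dj], axes=([3], [1]))
        return acc + bias

    def features_nhwc(self, x_nhwc):
        h = np.maximum(self._conv(x_nhwc, self.stem), 0.0)
        for unit in self.units:
            a = np.maximum(self._conv(h, unit["conv1"]), 0.0)
            a = np.maximum(self._conv(a, unit["conv2"]), 0.0)
            a = self._conv(a, unit["conv3"])
            s = self._conv(h, unit["short"]) if unit["short"] else h
            h = np.maximum(a + s, 0.0)
        return h

    def features(self, x):
        """(N, C, H, W) images -> (N, C, H, W) last-layer features."""
        h = self.features_nhwc(Network._to_nhwc(x))
        return np.ascontiguousarray(h.transpose(0, 3, 1, 2))


def build_network(spec: ArchitectureSpec, batchnorm: bool = True,
                  activation: str = "relu",
                  rng: np.random.Generator | None = None) -> Network:
    """Instantiate the trainable network described by ``spec``.

    ``batchnorm=False`` / ``activation=None`` give the bare linear
    convolution stack (used e.g. to measure receptive-field support
    empirically).  Weights are He-uniform, seeded from ``spec.seed`` unless
    an explicit generator is given.
    """
    if spec.input_size < 8:
        raise ValueError("input_size must be at least 8")
    return Network(spec, batchnorm=batchnorm, activation=activation, rng=rng)
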