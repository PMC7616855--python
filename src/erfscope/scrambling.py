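"""Feature scrambling: base/follow-up composition and spatial permutations.

A trained classifier is frozen and its pooling/classifier head detached;
the activation grid of its last convolutional layer ("base features") is
then fed — optionally through a spatial permutation — into a trainable
follow-up network ending in global average pooling and a softmax head.
Because a permutation moves whole feature columns without altering their
content, any drop in accuracy it causes isolates the contribution of the
*spatial arrangement* of features, as opposed to their presence.

Two follow-up types are supported:

* ``aggregating`` — four bottleneck residual units, middle kernel 3x3,
  strides (2, 2, 1, 1): integrates information across the grid and extends
  the composed ERF to cover the whole input (235 px for the smallest base).
* ``pointwise`` — four units of 1x1 convolutions, no down-sampling: cannot
  integrate across space, so its predictions are provably invariant to any
  permutation (the depth-matched control).

Scrambling scopes:

* ``global`` — one uniformly random bijection over all grid positions;
* ``local`` — independent permutations inside non-overlapping square
  windows, so no feature moves more than (window - 1) grid cells.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .architectures import (ArchitectureSpec, FoldedNetwork, Network,
                            ResidualUnit, compute_erf)

__all__ = [
    "PermutationMap",
    "FollowUpSpec",
    "ComposedModel",
    "make_global_permutation",
    "make_local_permutation",
    "apply_permutation",
    "compose",
    "compute_composed_erf",
    "test_time_scramble",
]


@dataclass
class PermutationMap:
    """A bijection over the H*W spatial positions of a feature grid.

    ``mapping[i]`` is the destination index of the column at flat position
    ``i`` (row-major).  ``scope`` records how it was drawn; ``window`` is
    the tile side for local scrambling.
    """

    grid_height: int
    grid_width: int
    mapping: np.ndarray
    scope: str = "global"
    window: int | None = None
    seed: int | None = None

    def __post_init__(self):
        self.mapping = np.asarray(self.mapping, dtype=np.int64)
        n = self.grid_height * self.grid_width
        if sorted(self.mapping.tolist()) != list(range(n)):
            raise ValueError("mapping is not a bijection on the grid")

    @property
    def n(self) -> int:
        return self.grid_height * self.grid_width

    def inverse(self) -> "PermutationMap":
        inv = np.empty_like(self.mapping)
        inv[self.mapping] = np.arange(self.n)
        return PermutationMap(self.grid_height, self.grid_width, inv,
                              scope=self.scope, window=self.window,
                              seed=self.seed)

    def displacements(self) -> np.ndarray:
        """Chebyshev displacement (grid cells) of every position."""
        src = np.arange(self.n)
        dst = self.mapping
        dr = np.abs(dst // self.grid_width - src // self.grid_width)
        dc = np.abs(dst % self.grid_width - src % self.grid_width)
        return np.maximum(dr, dc)

    def to_json(self) -> str:
        return json.dumps({
            "grid_height": self.grid_height, "grid_width": self.grid_width,
            "mapping": self.mapping.tolist(), "scope": self.scope,
            "window": self.window, "seed": self.seed})

    @classmethod
    def from_json(cls, text: str) -> "PermutationMap":
        return cls(**json.loads(text))


def make_global_permutation(grid_height: int, grid_width: int | None = None,
                            seed: int = 0) -> PermutationMap:
    """Uniformly random bijection over all grid positions."""
    if grid_width is None:
        grid_width = grid_height
    if grid_height < 1 or grid_width < 1:
        raise ValueError("grid dimensions must be >= 1")
    rng = np.random.default_rng(seed)
    mapping = rng.permutation(grid_height * grid_width)
    return PermutationMap(grid_height, grid_width, mapping,
                          scope="global", seed=seed)


def make_local_permutation(grid_height: int, grid_width: int | None = None,
                           window: int = 2, seed: int = 0) -> PermutationMap:
    """Independent permutations within non-overlapping square tiles.

    Tiles start at the top-left corner; remainder tiles at the right/bottom
    edges are permuted among themselves.  No index crosses a tile boundary,
    so displacement is bounded by (window - 1) cells.  A window covering
    the whole grid degenerates to a global permutation (warned).
    """
    if grid_width is None:
        grid_width = grid_height
    if window < 1:
        raise ValueError("window must be >= 1")
    if window > max(grid_height, grid_width):
        warnings.warn("window exceeds grid; falling back to global scrambling",
                      stacklevel=2)
        p = make_global_permutation(grid_height, grid_width, seed)
        return PermutationMap(grid_height, grid_width, p.mapping,
                              scope="local", window=window, seed=seed)
    rng = np.random.default_rng(seed)
    mapping = np.arange(grid_height * grid_width)
    for r0 in range(0, grid_height, window):
        for c0 in range(0, grid_width, window):
            rows = np.arange(r0, min(r0 + window, grid_height))
            cols = np.arange(c0, min(c0 + window, grid_width))
            idx = (rows[:, None] * grid_width + cols[None, :]).ravel()
            mapping[idx] = rng.permutation(idx)
    return PermutationMap(grid_height, grid_width, mapping,
                          scope="local", window=window, seed=seed)


def apply_permutation(features: np.ndarray, perm: PermutationMap) -> np.ndarray:
    """Move whole feature columns: output column perm(i) = input column i.

    ``features`` is (N, C, H, W) (a single (C, H, W) grid is also accepted).
    Channel order within each column is untouched.
    """
    single = features.ndim == 3
    if single:
        features = features[None]
    n, c, h, w = features.shape
    if (h, w) != (perm.grid_height, perm.grid_width):
        raise ValueError(
            f"feature grid {h}x{w} does not match permutation grid "
            f"{perm.grid_height}x{perm.grid_width}")
    flat = features.reshape(n, c, h * w)
    out = np.empty_like(flat)
    out[:, :, perm.mapping] = flat
    out = out.reshape(n, c, h, w)
    return out[0] if single else out


@dataclass
class FollowUpSpec:
    """Follow-up network appended to the frozen base features."""

    mode: str = "aggregating"  # or "pointwise"
    n_units: int = 4
    width: int | None = None   # None -> match the base output width
    seed: int = 0

    def __post_init__(self):
        if self.mode not in ("aggregating", "pointwise"):
            raise ValueError("mode must be 'aggregating' or 'pointwise'")

    @property
    def strides(self) -> tuple[int, ...]:
        base = (2, 2) + (1,) * (self.n_units - 2)
        return base if self.mode == "aggregating" else (1,) * self.n_units

    @property
    def middle_kernel(self) -> int:
        return 3 if self.mode == "aggregating" else 1


class _FollowUpNet(nn.Module):
    """Bottleneck unit stack + GAP + softmax head (the trainable part)."""

    def __init__(self, in_ch: int, spec: FollowUpSpec, n_classes: int,
                 rng: np.random.Generator):
        super().__init__()
        width = spec.width if spec.width is not None else in_ch
        mid = max(1, width // 4)
        self.units = []
        ch = in_ch
        for u, stride in enumerate(spec.strides):
            unit = ResidualUnit(ch, mid, width, spec.middle_kernel, stride, rng)
            setattr(self, f"unit{u + 1}", unit)
            self.units.append(unit)
            ch = width
        self.gap = nn.GlobalAvgPool()
        self.fc = nn.Dense(ch, n_classes, rng=rng)

    def forward(self, x, training=False):
        # public feature grids are NCHW; the backend runs channels-last
        h = np.ascontiguousarray(x.transpose(0, 2, 3, 1))
        for unit in self.units:
            h = unit.forward(h, training)
        return self.fc(self.gap(h, training), training)

    def backward(self, dlogits):
        dy = self.gap.backward(self.fc.backward(dlogits))
        for unit in reversed(self.units):
            dy = unit.backward(dy)
        return np.ascontiguousarray(dy.transpose(0, 3, 1, 2))


class ComposedModel:
    """Frozen base features -> optional fixed permutation -> follow-up.

    The base network's weights are never updated here; its head is ignored
    and only its last-convolutional-layer features are consumed.  When
    ``train_time_scramble`` is set, the (single, fixed) ``permutation`` is
    applied during both training and evaluation, exactly as a constant
    rewiring of the feature grid.
    """

    def __init__(self, base: Network, followup: FollowUpSpec,
                 permutation: PermutationMap | None = None,
                 train_time_scramble: bool = False,
                 rng: np.random.Generator | None = None):
        if train_time_scramble and permutation is None:
            raise ValueError("train_time_scramble requires a permutation")
        self.base = base
        self.followup_spec = followup
        self.permutation = permutation
        self.train_time_scramble = train_time_scramble
        if rng is None:
            rng = np.random.default_rng(followup.seed)
        self.followup = _FollowUpNet(base.spec.output_width, followup,
                                     base.spec.n_classes, rng)
        self.n_classes = base.spec.n_classes
        self._folded = None  # lazy batch-norm-folded copy of the frozen base

    # -- plumbing used by the trainer --------------------------------------
    def parameters(self):
        """Trainable parameters: the follow-up only (base is frozen)."""
        return self.followup.parameters()

    def zero_grad(self):
        self.followup.zero_grad()

    def base_features(self, x: np.ndarray) -> np.ndarray:
        """Frozen-base feature extraction (always in inference mode).

        The base is frozen, so its eval-mode batch norm folds exactly into
        the convolution weights; the folded copy is built once.
        """
        if self._folded is None:
            try:
                self._folded = FoldedNetwork(self.base)
            except ValueError:
                self._folded = self.base  # non-standard activations
        if isinstance(self._folded, FoldedNetwork):
            return self._folded.features(x)
        return self.base.features(x, training=False)

    def _maybe_scramble(self, feats: np.ndarray) -> np.ndarray:
        if self.train_time_scramble and self.permutation is not None:
            return apply_permutation(feats, self.permutation)
        return feats

    def forward_features(self, feats, training=False):
        return self.followup.forward(self._maybe_scramble(feats), training)

    def forward(self, x, training=False):
        return self.forward_features(self.base_features(x), training)

    def backward(self, dlogits):
        return self.followup.backward(dlogits)

    def predict(self, x):
        return np.argmax(self.forward(x), axis=1)

    def predict_proba(self, x):
        return nn.softmax(self.forward(x))


def compose(base: Network, followup: FollowUpSpec,
            permutation: PermutationMap | None = None,
            train_time_scramble: bool = False,
            rng: np.random.Generator | None = None) -> ComposedModel:
    """Attach a follow-up network to a frozen base classifier."""
    return ComposedModel(base, followup, permutation, train_time_scramble, rng)


def compute_composed_erf(base_spec: ArchitectureSpec,
                         followup: FollowUpSpec) -> int:
    """Analytic ERF of base + follow-up at the last follow-up convolution.

    Continues the receptive-field recursion from the base's last layer
    through the follow-up's bottleneck units (stride on the first 1x1,
    then the middle kernel, then a 1x1).
    """
    base_erf = compute_erf(base_spec)
    last = list(base_erf.layers.values())[-1]
    erf, jump = last["erf"], last["jump"]
    for stride in followup.strides:
        jump *= stride                          # first 1x1, strided
        erf += (followup.middle_kernel - 1) * jump  # k x k layer
    return erf


def test_time_scramble(model: ComposedModel, images: np.ndarray,
                       scope: str = "global", window: int = 2,
                       seed: int = 0, batch_size: int = 64):
    """Paired predictions without and with per-image random scrambling.

    The model must have been trained without scrambling; a fresh
    permutation is drawn for every image from a seeded stream.  Returns
    ``(preds_clean, preds_scrambled)``.
    """
    rng = np.random.default_rng(seed)
    clean, scrambled = [], []
    for i in range(0, len(images), batch_size):
        feats = model.base_features(images[i:i + batch_size])
        _, _, h, w = feats.shape
        clean.append(np.argmax(model.forward_features(feats), axis=1))
        sf = np.empty_like(feats)
        for j in range(feats.shape[0]):
            s = int(rng.integers(0, 2**31 - 1))
            if scope == "global":
                perm = make_global_permutation(h, w, seed=s)
            elif scope == "local":
                perm = make_local_permutation(h, w, window=window, seed=s)
            else:
                raise ValueError("scope must be 'global' or 'local'")
            sf[j] = apply_permutation(feats[j], perm)
        scrambled.append(np.argmax(model.forward_features(sf), axis=1))
    return np.concatenate(clean), np.concatenate(scrambled)
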