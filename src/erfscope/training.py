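"""Training schedule, preprocessing, per-class metrics and scrambling ratios.

Optimization follows the reference protocol: SGD with momentum 0.9, initial
learning rate 0.01 held constant for the first 10 epochs, then per-epoch
exponential decay.  Preprocessing crops the central square, resizes to
256 x 256 and takes a (random during training, central during evaluation)
224 x 224 crop with random horizontal flips as the only augmentation.

The scrambling-sensitivity statistic of a class is the ratio of its
one-vs-rest F1 score after spatial feature scrambling to the score before;
only classes the model classifies reliably to begin with (F1 > 0.75 by
default) enter the ranking.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from skimage.transform import resize
from sklearn.metrics import precision_recall_fscore_support

from . import nn
from .scrambling import ComposedModel

__all__ = [
    "TrainConfig",
    "TrainHistory",
    "ClassMetrics",
    "ScramblingReport",
    "preprocess_train",
    "preprocess_eval",
    "train",
    "evaluate",
    "scrambling_ratio",
    "class_set_overlap",
]


@dataclass
class TrainConfig:
    epochs: int = 50
    batch_size: int = 128
    lr_initial: float = 0.01
    constant_epochs: int = 10        # epochs at lr_initial before decay
    decay_rate: float = 0.94         # per-epoch exponential factor
    momentum: float = 0.9
    weight_decay: float = 0.0
    seed: int = 0

    def lr_at(self, epoch: int) -> float:
        """Learning rate during 1-indexed ``epoch``."""
        if epoch <= self.constant_epochs:
            return self.lr_initial
        return self.lr_initial * self.decay_rate ** (epoch - self.constant_epochs)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class TrainHistory:
    loss: list[float] = field(default_factory=list)
    accuracy: list[float] = field(default_factory=list)
    lr: list[float] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"epoch": np.arange(1, len(self.loss) + 1),
                             "loss": self.loss, "accuracy": self.accuracy,
                             "lr": self.lr})


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def _central_square(image: np.ndarray) -> np.ndarray:
    h, w = image.shape[:2]
    side = min(h, w)
    r0, c0 = (h - side) // 2, (w - side) // 2
    return image[r0:r0 + side, c0:c0 + side]


def _resize(image: np.ndarray, side: int) -> np.ndarray:
    if image.shape[0] == side and image.shape[1] == side:
        return image.astype(np.float32)
    return resize(image, (side,) * 2 + image.shape[2:], order=1,
                  anti_aliasing=False, preserve_range=True).astype(np.float32)


def preprocess_train(image: np.ndarray, rng: np.random.Generator,
                     resize_side: int = 256, crop_side: int = 224,
                     flip: bool = True) -> np.ndarray:
    """Central square crop -> resize -> random flip -> random crop."""
    img = _resize(_central_square(image), resize_side)
    if flip and rng.random() < 0.5:
        img = img[:, ::-1]
    margin = resize_side - crop_side
    r0 = int(rng.integers(0, margin + 1))
    c0 = int(rng.integers(0, margin + 1))
    return np.ascontiguousarray(img[r0:r0 + crop_side, c0:c0 + crop_side])


def preprocess_eval(image: np.ndarray, resize_side: int = 256,
                    crop_side: int = 224) -> np.ndarray:
    """Central square crop -> resize -> central crop; deterministic."""
    img = _resize(_central_square(image), resize_side)
    off = (resize_side - crop_side) // 2
    return np.ascontiguousarray(img[off:off + crop_side, off:off + crop_side])


def upsample_images(x: np.ndarray, factor: int) -> np.ndarray:
    """Bilinear upsampling of an NCHW batch by an integer factor."""
    if factor == 1:
        return x
    n, c, h, w = x.shape
    out = np.empty((n, c, factor * h, factor * w), dtype=np.float32)
    for i in range(n):
        for j in range(c):
            out[i, j] = resize(x[i, j], (factor * h, factor * w), order=1,
                               anti_aliasing=False, preserve_range=True)
    return out


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------

def shift_augment(max_shift: int):
    """Random integer translation (zero-filled) of NCHW batches.

    The desk-scale analog of random-crop augmentation: grids are shifted
    by up to ``max_shift`` cells in each direction per batch.
    """
    def aug(xb: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        dy, dx = (int(v) for v in rng.integers(-max_shift, max_shift + 1, 2))
        if dy == 0 and dx == 0:
            return xb
        out = np.zeros_like(xb)
        h, w = xb.shape[2], xb.shape[3]
        ys, yd = (slice(0, h - dy), slice(dy, h)) if dy >= 0 else \
                 (slice(-dy, h), slice(0, h + dy))
        xs, xd = (slice(0, w - dx), slice(dx, w)) if dx >= 0 else \
                 (slice(-dx, w), slice(0, w + dx))
        out[:, :, yd, xd] = xb[:, :, ys, xs]
        return out
    return aug


def train(model, x: np.ndarray, y: np.ndarray, config: TrainConfig,
          feature_space: bool = False, augment=None,
          verbose: bool = False) -> TrainHistory:
    """Minimize softmax cross-entropy with SGD + momentum on (x, y).

    ``model`` is a standalone Network or a ComposedModel; for the latter
    only the follow-up parameters are updated (the base stays frozen) and
    ``feature_space=True`` lets ``x`` be precomputed base features instead
    of images.  ``augment(batch, rng)`` is applied per batch when given.
    Returns the per-epoch history.
    """
    if len(x) == 0:
        raise ValueError("empty training set")
    is_composed = isinstance(model, ComposedModel)
    if feature_space and not is_composed:
        raise ValueError("feature_space training requires a ComposedModel")
    rng = np.random.default_rng(config.seed)
    opt = nn.SGD(model.parameters(), momentum=config.momentum,
                 weight_decay=config.weight_decay)
    history = TrainHistory()
    for epoch in range(1, config.epochs + 1):
        lr = config.lr_at(epoch)
        order = rng.permutation(len(x))
        losses, correct = [], 0
        for i in range(0, len(order), config.batch_size):
            idx = order[i:i + config.batch_size]
            xb, yb = x[idx], y[idx]
            if augment is not None:
                xb = augment(xb, rng)
            model.zero_grad()
            if is_composed:
                feats = xb if feature_space else model.base_features(xb)
                logits = model.forward_features(feats, training=True)
            else:
                logits = model.forward(xb, training=True)
            loss, dlogits = nn.softmax_cross_entropy(logits, yb)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}: {loss}")
            model.backward(dlogits)
            opt.step(lr)
            losses.append(loss)
            correct += int((np.argmax(logits, axis=1) == yb).sum())
        history.loss.append(float(np.mean(losses)))
        history.accuracy.append(correct / len(order))
        history.lr.append(lr)
        if verbose:
            print(f"epoch {epoch:3d}  lr {lr:.5f}  loss {history.loss[-1]:.4f}"
                  f"  acc {history.accuracy[-1]:.3f}")
    return history


# ---------------------------------------------------------------------------
# evaluation and scrambling statistics
# ---------------------------------------------------------------------------

@dataclass
class ClassMetrics:
    """One-vs-rest precision/recall/F1 per class plus top-1 accuracy."""

    table: pd.DataFrame          # index: class id; columns tp/fp/fn/precision/recall/f1
    accuracy: float
    missing_classes: list[int] = field(default_factory=list)

    def f1(self, label) -> float:
        return float(self.table.loc[label, "f1"])


def evaluate(model, x: np.ndarray, y: np.ndarray,
             labels: list | None = None, batch_size: int = 128,
             predictions: np.ndarray | None = None) -> ClassMetrics:
    """Top-1 metrics; pass ``predictions`` to score precomputed outputs."""
    if predictions is None:
        preds = [model.predict(x[i:i + batch_size])
                 for i in range(0, len(x), batch_size)]
        predictions = np.concatenate(preds)
    if labels is None:
        labels = sorted(np.unique(y).tolist())
    missing = [c for c in labels if (y == c).sum() == 0]
    if missing:
        warnings.warn(f"classes absent from the test set: {missing}",
                      stacklevel=2)
    prec, rec, f1, _ = precision_recall_fscore_support(
        y, predictions, labels=labels, zero_division=0)
    tp = np.array([int(((y == c) & (predictions == c)).sum()) for c in labels])
    fp = np.array([int(((y != c) & (predictions == c)).sum()) for c in labels])
    fn = np.array([int(((y == c) & (predictions != c)).sum()) for c in labels])
    table = pd.DataFrame({"tp": tp, "fp": fp, "fn": fn, "precision": prec,
                          "recall": rec, "f1": f1}, index=labels)
    return ClassMetrics(table, float((predictions == y).mean()), missing)


@dataclass
class ScramblingReport:
    """Per-class before/after F1 ratios and sensitivity rankings."""

    table: pd.DataFrame          # f1_before, f1_after, ratio, eligible
    threshold: float

    @property
    def eligible(self) -> pd.DataFrame:
        return self.table[self.table["eligible"]]

    def most_sensitive(self, k: int | None = None) -> list:
        """Classes ranked ascending by ratio (most sensitive first)."""
        ranked = self.eligible.sort_values(["ratio", "f1_before"]).index.tolist()
        return ranked if k is None else ranked[:k]

    def least_sensitive(self, k: int | None = None) -> list:
        ranked = self.eligible.sort_values(
            ["ratio", "f1_before"], ascending=[False, False]).index.tolist()
        return ranked if k is None else ranked[:k]


def scrambling_ratio(before: ClassMetrics, after: ClassMetrics,
                     threshold: float = 0.75) -> ScramblingReport:
    """F1-after / F1-before per class, restricted to reliable classes.

    A class enters the ranking only when its pre-scrambling F1 exceeds
    ``threshold``; its ratio is then well defined (the denominator is
    positive) and equals 0 when scrambling destroys the class entirely.
    """
    if list(before.table.index) != list(after.table.index):
        raise ValueError("metric sets cover different class lists")
    f1b = before.table["f1"]
    f1a = after.table["f1"]
    eligible = f1b > threshold
    ratio = pd.Series(np.nan, index=f1b.index)
    ratio[eligible] = f1a[eligible] / f1b[eligible]
    table = pd.DataFrame({"f1_before": f1b, "f1_after": f1a,
                          "ratio": ratio, "eligible": eligible})
    if not eligible.any():
        warnings.warn("no class exceeds the reliability threshold; "
                      "empty scrambling report", stacklevel=2)
    return ScramblingReport(table, threshold)


def class_set_overlap(rankings: dict[str, list], k: int = 20) -> pd.DataFrame:
    """Pairwise |top-k ∩ top-k| over per-model ranked class lists."""
    names = list(rankings)
    tops = {}
    for name in names:
        lst = rankings[name]
        if k > len(lst):
            warnings.warn(f"k={k} exceeds ranking length for {name}; "
                          "using the full list", stacklevel=2)
        tops[name] = set(lst[:k])
    mat = pd.DataFrame(0, index=names, columns=names, dtype=int)
    for a in names:
        for b in names:
            mat.loc[a, b] = len(tops[a] & tops[b])
    return mat
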