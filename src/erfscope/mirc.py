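"""Minimal recognizable configuration (MIRC) search.

Starting from a correctly classified image, four descendant patches are
carved from each patch — each spanning 75% of its height and width,
anchored at one of the four corners — upsampled to the model's input size
and re-classified.  Correct patches are subdivided recursively; a patch
whose four descendants are all misclassified is a MIRC, the smallest
configuration at that position the model still recognizes.  The recursion
yields a tree whose leaves are the MIRCs; the deeper the leaf, the smaller
the diagnostic patch.

Dimension rounding uses floor (clamped to >= 1); a descendant identical to
its parent (degenerate 1 x 1 patches) stops the recursion, and a
configurable level cap (default 10) bounds the search, with capped leaves
flagged separately.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.transform import resize
from sklearn.cluster import KMeans

from . import nn

__all__ = [
    "Patch",
    "MIRCNode",
    "MIRCTree",
    "descendants",
    "classify_patch",
    "model_patch_classifier",
    "mirc_search",
    "mirc_level_hist",
    "cluster_mircs",
]

SHRINK = 0.75


@dataclass(frozen=True)
class Patch:
    """Axis-aligned box in original-image pixels, 0-based, half-open."""

    row: int
    col: int
    height: int
    width: int
    level: int = 0

    @property
    def bbox(self) -> tuple[int, int, int, int]:
        return (self.row, self.col, self.height, self.width)

    def crop(self, image: np.ndarray) -> np.ndarray:
        """Extract the patch from a (C, H, W) image."""
        if (self.row < 0 or self.col < 0
                or self.row + self.height > image.shape[-2]
                or self.col + self.width > image.shape[-1]):
            raise ValueError(f"patch {self.bbox} outside image bounds")
        return image[..., self.row:self.row + self.height,
                     self.col:self.col + self.width]

    @classmethod
    def full(cls, image: np.ndarray) -> "Patch":
        return cls(0, 0, image.shape[-2], image.shape[-1], level=0)


def descendants(patch: Patch) -> list[Patch]:
    """Four corner-anchored 75% sub-patches, one level deeper."""
    h = max(1, int(SHRINK * patch.height))
    w = max(1, int(SHRINK * patch.width))
    r0, c0 = patch.row, patch.col
    r1, c1 = patch.row + patch.height - h, patch.col + patch.width - w
    lvl = patch.level + 1
    return [Patch(r0, c0, h, w, lvl), Patch(r0, c1, h, w, lvl),
            Patch(r1, c0, h, w, lvl), Patch(r1, c1, h, w, lvl)]


def classify_patch(model, image: np.ndarray, patch: Patch, true_class: int,
                   input_side: int = 224):
    """Crop, bilinear-upsample to the input size, classify.

    Returns ``(correct, probability)``: correctness of the top-1
    prediction and the softmax mass assigned to the true class.
    """
    crop = patch.crop(image).astype(np.float64)
    up = np.stack([
        resize(ch, (input_side, input_side), order=1,
               anti_aliasing=False, preserve_range=True)
        for ch in crop])
    probs = model.predict_proba(up[None].astype(np.float32))[0]
    pred = int(np.argmax(probs))
    return pred == true_class, float(probs[true_class])


def model_patch_classifier(model, true_class: int, input_side: int = 224):
    """Wrap a network as the ``classify(image, patch)`` callable."""
    def classify(image, patch):
        return classify_patch(model, image, patch, true_class, input_side)
    return classify


@dataclass
class MIRCNode:
    patch: Patch
    correct: bool
    probability: float
    children: list["MIRCNode"] = field(default_factory=list)
    is_mirc: bool = False
    capped: bool = False

    def to_dict(self) -> dict:
        return {"bbox": list(self.patch.bbox), "level": self.patch.level,
                "correct": bool(self.correct),
                "probability": self.probability,
                "is_mirc": self.is_mirc, "capped": self.capped,
                "children": [c.to_dict() for c in self.children]}

    @classmethod
    def from_dict(cls, d: dict) -> "MIRCNode":
        r, c, h, w = d["bbox"]
        node = cls(Patch(r, c, h, w, d["level"]), d["correct"],
                   d["probability"], is_mirc=d["is_mirc"], capped=d["capped"])
        node.children = [cls.from_dict(x) for x in d["children"]]
        return node


@dataclass
class MIRCTree:
    root: MIRCNode | None
    reason: str = ""
    max_level: int = 10
    image_id: int | None = None

    def mircs(self) -> list[MIRCNode]:
        out: list[MIRCNode] = []

        def walk(node):
            if node.is_mirc:
                out.append(node)
            for ch in node.children:
                walk(ch)

        if self.root is not None:
            walk(self.root)
        return out

    def max_mirc_level(self) -> int | None:
        levels = [m.patch.level for m in self.mircs()]
        return max(levels) if levels else None

    def deepest_mirc(self) -> MIRCNode | None:
        """Highest-probability MIRC among those at the deepest level."""
        ms = self.mircs()
        if not ms:
            return None
        top = max(m.patch.level for m in ms)
        return max((m for m in ms if m.patch.level == top),
                   key=lambda m: m.probability)

    def validate(self) -> None:
        """Structural invariants of the search tree."""

        def walk(node, parent_correct):
            if node.children:
                if not node.correct:
                    raise AssertionError("incorrect node with children")
            if node.is_mirc:
                if not node.correct:
                    raise AssertionError("misclassified MIRC")
                if not node.capped and any(c.correct for c in node.children):
                    raise AssertionError("MIRC with a correct descendant")
            for ch in node.children:
                walk(ch, node.correct)

        if self.root is not None:
            walk(self.root, True)

    def to_json(self) -> str:
        return json.dumps({
            "root": self.root.to_dict() if self.root else None,
            "reason": self.reason, "max_level": self.max_level,
            "image_id": self.image_id})

    @classmethod
    def from_json(cls, text: str) -> "MIRCTree":
        d = json.loads(text)
        root = MIRCNode.from_dict(d["root"]) if d["root"] else None
        return cls(root, d["reason"], d["max_level"], d["image_id"])


def mirc_search(classify, image: np.ndarray, max_level: int = 10,
                image_id: int | None = None) -> MIRCTree:
    """Recursive subdivision of correct patches down to the MIRCs.

    ``classify(image, patch) -> (correct, probability)`` encapsulates the
    model (see :func:`model_patch_classifier`).  Identical bounding boxes
    are evaluated once (memoized).  Leaves are correct patches with four
    incorrect descendants, patches at the level cap (flagged ``capped``),
    or no-progress patches whose descendants equal themselves.
    """
    cache: dict[tuple, tuple[bool, float]] = {}

    def judged(patch: Patch):
        key = patch.bbox
        if key not in cache:
            cache[key] = classify(image, patch)
        return cache[key]

    root_patch = Patch.full(image)
    correct, prob = judged(root_patch)
    if not correct:
        return MIRCTree(None, reason="root misclassified",
                        max_level=max_level, image_id=image_id)

    def expand(patch: Patch) -> MIRCNode:
        correct, prob = judged(patch)
        node = MIRCNode(patch, correct, prob)
        if not correct:
            return node
        if patch.level >= max_level:
            node.is_mirc = True
            node.capped = True
            return node
        kids = descendants(patch)
        if any(k.bbox == patch.bbox for k in kids):  # degenerate, no progress
            node.is_mirc = True
            node.capped = True
            return node
        node.children = [expand(k) for k in kids]
        if not any(c.correct for c in node.children):
            node.is_mirc = True
        return node

    tree = MIRCTree(expand(root_patch), max_level=max_level,
                    image_id=image_id)
    return tree


def mirc_level_hist(trees: list[MIRCTree], max_level: int = 10) -> pd.Series:
    """Histogram of the per-image deepest MIRC level (0 ... max_level)."""
    counts = pd.Series(0, index=pd.RangeIndex(max_level + 1, name="level"))
    for t in trees:
        lvl = t.max_mirc_level()
        if lvl is not None:
            counts[lvl] += 1
    return counts


def save_mirc_crops(trees: list[MIRCTree], images: np.ndarray,
                    out_dir, deepest_only: bool = True) -> list[str]:
    """Write MIRC patches as PNG files; returns the relative paths.

    ``deepest_only`` exports the highest-probability MIRC of the deepest
    level per image (the standard visualization); otherwise every MIRC.
    """
    from pathlib import Path

    from PIL import Image

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for t in trees:
        mircs = ([t.deepest_mirc()] if deepest_only else t.mircs())
        for j, m in enumerate(m for m in mircs if m is not None):
            crop = m.patch.crop(images[t.image_id])[0]
            arr = np.clip(crop * 255.0 + 0.5, 0, 255).astype(np.uint8)
            rel = (f"img{t.image_id:04d}_lvl{m.patch.level}_{j}.png")
            Image.fromarray(arr, mode="L").save(out / rel)
            written.append(rel)
    return written


def cluster_mircs(extractor, trees: list[MIRCTree], images: np.ndarray,
                  k: int = 5, n_exemplars: int = 8, seed: int = 0,
                  input_side: int = 224):
    """K-means over MIRC latent representations with exemplar selection.

    ``extractor(batch) -> (n, features)`` maps upsampled MIRC crops to
    latent vectors (typically the GAP layer).  Per cluster the
    ``n_exemplars`` members closest to the centre under Euclidean distance
    are returned, constrained to originate from distinct source images.
    Returns ``(assignments DataFrame, exemplars: list of row-index lists)``.
    """
    records = []
    crops = []
    for t in trees:
        for m in t.mircs():
            crop = m.patch.crop(images[t.image_id]).astype(np.float64)
            up = np.stack([resize(ch, (input_side, input_side), order=1,
                                  anti_aliasing=False, preserve_range=True)
                           for ch in crop])
            crops.append(up.astype(np.float32))
            records.append({"image_id": t.image_id, "level": m.patch.level,
                            "bbox": m.patch.bbox,
                            "probability": m.probability})
    if not records:
        raise ValueError("no MIRCs to cluster")
    latents = extractor(np.stack(crops))
    n_images = len({r["image_id"] for r in records})
    if len(records) < k or n_images < n_exemplars:
        new_k = max(1, min(k, len(records)))
        warnings.warn(f"too few MIRCs for k={k}; using k={new_k}",
                      stacklevel=2)
        k = new_k
    km = KMeans(n_clusters=k, random_state=seed, n_init=10)
    assign = km.fit_predict(latents)
    table = pd.DataFrame(records)
    table["cluster"] = assign
    exemplars: list[list[int]] = []
    for c in range(k):
        idx = np.nonzero(assign == c)[0]
        dist = np.linalg.norm(latents[idx] - km.cluster_centers_[c], axis=1)
        chosen, seen = [], set()
        for i in idx[np.argsort(dist)]:
            img = records[i]["image_id"]
            if img in seen:
                continue
            seen.add(img)
            chosen.append(int(i))
            if len(chosen) == n_exemplars:
                break
        exemplars.append(chosen)
    return table, exemplars
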