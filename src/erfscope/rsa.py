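"""Representational similarity analysis across layers and models.

First-order representational dissimilarity matrices (RDMs) hold the
pairwise correlation distance (1 - Pearson) between the activation
patterns evoked by different stimuli.  A second-order RDM applies the same
distance to the vectorized upper triangles of layer RDMs, comparing
representations *between* layers and models; metric MDS then embeds it for
visualization.  Agreement between two RDMs is summarized as R², the
squared Pearson correlation of their upper triangles.

The layer set analysed per model is the output grid of each of the 10
residual units plus the pooled (GAP) vector and the softmax output — 12
layers, hence a 60 x 60 second-order RDM across the five ERF variants.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.manifold import MDS

__all__ = [
    "RDM",
    "compute_rdm",
    "average_rdms",
    "second_order_rdm",
    "rdm_r2",
    "mds_embed",
    "model_layer_rdms",
    "sensitivity_contrast",
]


@dataclass
class RDM:
    """Symmetric correlation-distance matrix with zero diagonal."""

    matrix: np.ndarray
    labels: list = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=np.float64)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("RDM must be square")
        self.matrix = m

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    def upper_triangle(self) -> np.ndarray:
        iu = np.triu_indices(self.n, k=1)
        return self.matrix[iu]

    def validate(self, atol: float = 1e-8) -> None:
        m = self.matrix
        if not np.allclose(m, m.T, atol=atol):
            raise ValueError("RDM is not symmetric")
        if not np.allclose(np.diag(m), 0.0, atol=atol):
            raise ValueError("RDM diagonal is not zero")
        if m.min() < -atol or m.max() > 2.0 + atol:
            raise ValueError("RDM entries outside [0, 2]")


def _flatten(activations: np.ndarray) -> np.ndarray:
    a = np.asarray(activations, dtype=np.float64)
    return a.reshape(a.shape[0], -1)


def compute_rdm(activations: np.ndarray, labels: list | None = None,
                provenance: dict | None = None) -> RDM:
    """1 - Pearson correlation between stimulus activation vectors.

    ``activations`` is stimuli x features; spatial activation grids are
    flattened per stimulus.  A zero-variance stimulus vector has no
    defined correlation and raises, naming the stimulus.
    """
    a = _flatten(activations)
    if a.shape[0] < 2:
        raise ValueError("need at least 2 stimuli")
    sd = a.std(axis=1)
    bad = np.nonzero(sd == 0)[0]
    if bad.size:
        name = labels[bad[0]] if labels else int(bad[0])
        raise ValueError(f"zero-variance activation vector for stimulus {name!r}")
    c = np.corrcoef(a)
    m = 1.0 - c
    np.fill_diagonal(m, 0.0)
    m = np.clip((m + m.T) / 2.0, 0.0, 2.0)
    return RDM(m, labels or [], provenance or {})


def average_rdms(rdms: list[RDM]) -> RDM:
    """Element-wise mean (e.g. across training repetitions)."""
    if not rdms:
        raise ValueError("no RDMs to average")
    n = rdms[0].n
    if any(r.n != n for r in rdms):
        raise ValueError("RDM sizes differ")
    m = np.mean([r.matrix for r in rdms], axis=0)
    prov = dict(rdms[0].provenance)
    prov["seed_average_count"] = len(rdms)
    return RDM(m, rdms[0].labels, prov)


def second_order_rdm(rdms: list[RDM], names: list | None = None) -> RDM:
    """Correlation distance between the upper triangles of layer RDMs."""
    if len(rdms) < 2:
        raise ValueError("need at least 2 RDMs")
    n = rdms[0].n
    if any(r.n != n for r in rdms):
        raise ValueError("layer RDMs have mismatched sizes")
    tri = np.stack([r.upper_triangle() for r in rdms])
    sd = tri.std(axis=1)
    const = np.nonzero(sd == 0)[0]
    if const.size:
        nm = names[const[0]] if names else int(const[0])
        raise ValueError(f"constant upper triangle for layer {nm!r}")
    m = 1.0 - np.corrcoef(tri)
    np.fill_diagonal(m, 0.0)
    m = np.clip((m + m.T) / 2.0, 0.0, 2.0)
    labels = names if names is not None else [
        r.provenance.get("layer", i) for i, r in enumerate(rdms)]
    return RDM(m, labels, {"order": 2})


def rdm_r2(a: RDM, b: RDM) -> float:
    """Variance explained: squared Pearson correlation of upper triangles."""
    if a.n != b.n:
        raise ValueError("RDM sizes differ")
    ta, tb = a.upper_triangle(), b.upper_triangle()
    if ta.std() == 0 or tb.std() == 0:
        raise ValueError("R^2 undefined for a constant upper triangle")
    r = np.corrcoef(ta, tb)[0, 1]
    return float(r * r)


def mds_embed(rdm: RDM, dims: int = 2, seed: int = 0,
              return_stress: bool = False):
    """Metric (stress-minimizing) MDS coordinates of the RDM entries."""
    mds = MDS(n_components=dims, metric="precomputed", metric_mds=True,
              init="classical_mds", n_init=1, max_iter=3000, eps=1e-12,
              random_state=seed, normalized_stress=False)
    with warnings.catch_warnings():
        # all-zero dissimilarities trigger a harmless 0/0 in the stress test
        warnings.simplefilter("ignore", RuntimeWarning)
        coords = mds.fit_transform(rdm.matrix)
    if return_stress:
        return coords, float(mds.stress_)
    return coords


def model_layer_rdms(model, images: np.ndarray, batch_size: int = 64,
                     model_name: str = "model") -> dict[str, RDM]:
    """RDMs of the 12 analysis layers of a residual classifier.

    Runs the images through the network, capturing every residual unit's
    output grid plus the GAP vector and the softmax output, flattening
    each to stimuli x features.
    """
    captured: dict[str, list[np.ndarray]] = {}
    for i in range(0, len(images), batch_size):
        cap: dict = {}
        model.forward(images[i:i + batch_size], capture=cap)
        for k, v in cap.items():
            captured.setdefault(k, []).append(_flatten(v))
    return {
        name: compute_rdm(np.concatenate(chunks),
                          provenance={"model": model_name, "layer": name})
        for name, chunks in captured.items()
    }


def sensitivity_contrast(extract_small, extract_large,
                         images_by_class: dict, sensitive_classes: list,
                         insensitive_classes: list, reps: int = 100,
                         n_classes: int = 20, n_images: int = 20,
                         seed: int = 0) -> np.ndarray:
    """Distribution of R² differences between class conditions.

    Per repetition, ``n_images`` images are drawn from each of (up to)
    ``n_classes`` classes of each condition; both models' activations are
    extracted (``extract_*``: images -> stimuli x features), the two RDMs
    built per condition, and R²(small vs. large) computed.  Returns the
    ``reps`` values of R²_sensitive - R²_insensitive.
    """
    rng = np.random.default_rng(seed)
    conditions = {"sensitive": list(sensitive_classes)[:n_classes],
                  "insensitive": list(insensitive_classes)[:n_classes]}
    deltas = np.empty(reps)
    for rep in range(reps):
        r2 = {}
        for cond, classes in conditions.items():
            batches = []
            for c in classes:
                pool = images_by_class[c]
                if len(pool) < n_images:
                    warnings.warn(f"class {c!r} has {len(pool)} images; "
                                  "sampling with replacement", stacklevel=2)
                    idx = rng.integers(0, len(pool), size=n_images)
                else:
                    idx = rng.choice(len(pool), size=n_images, replace=False)
                batches.append(pool[idx])
            imgs = np.concatenate(batches)
            rdm_s = compute_rdm(extract_small(imgs))
            rdm_l = compute_rdm(extract_large(imgs))
            r2[cond] = rdm_r2(rdm_s, rdm_l)
        deltas[rep] = r2["sensitive"] - r2["insensitive"]
    return deltas
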