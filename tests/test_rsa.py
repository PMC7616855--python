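"""Representational dissimilarity analysis oracles and invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra.numpy import arrays

from erfscope.rsa import (
    RDM,
    average_rdms,
    compute_rdm,
    mds_embed,
    model_layer_rdms,
    rdm_r2,
    second_order_rdm,
    sensitivity_contrast,
)


def _pearson(a, b):
    return np.corrcoef(a, b)[0, 1]


# ---------------------------------------------------------------------------
# first-order RDMs
# ---------------------------------------------------------------------------

def test_identical_rows_distance_zero():
    acts = np.array([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0], [3.0, 1.0, 2.0]])
    rdm = compute_rdm(acts)
    assert np.isclose(rdm.matrix[0, 1], 0.0)


def test_anticorrelated_rows_distance_two():
    rdm = compute_rdm(np.array([[1.0, 2.0, 3.0], [3.0, 2.0, 1.0]]))
    assert np.isclose(rdm.matrix[0, 1], 2.0)


def test_rdm_matches_hand_pearson():
    acts = np.array([[1, 2, 3, 4], [2, 2, 5, 1], [0, 7, 1, 3]], dtype=float)
    rdm = compute_rdm(acts)
    for i in range(3):
        for j in range(3):
            expected = 0.0 if i == j else 1 - _pearson(acts[i], acts[j])
            assert np.isclose(rdm.matrix[i, j], expected)


def test_zero_variance_row_raises_with_name():
    acts = np.array([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]])
    with pytest.raises(ValueError, match="stim_a"):
        compute_rdm(acts, labels=["stim_a", "stim_b"])


@given(arrays(np.float64, (6, 5),
              elements=st.floats(-10, 10, allow_nan=False)))
@settings(max_examples=50, deadline=None)
def test_rdm_invariants_on_random_activations(acts):
    acts = acts + np.arange(5) * 1e-3  # avoid exactly constant rows
    rdm = compute_rdm(acts)
    rdm.validate()


# ---------------------------------------------------------------------------
# second-order analysis
# ---------------------------------------------------------------------------

def _rdm_from(tri3):
    """3x3 RDM from its 3 upper-triangle entries."""
    m = np.zeros((3, 3))
    m[0, 1], m[0, 2], m[1, 2] = tri3
    return RDM(m + m.T)


def test_second_order_identical_rdms_zero():
    rdms = [_rdm_from([0.1, 0.4, 0.9])] * 3
    so = second_order_rdm(rdms)
    assert np.allclose(so.matrix, 0.0)


def test_second_order_matches_hand_correlation():
    a, b = _rdm_from([0.1, 0.5, 0.9]), _rdm_from([0.2, 0.3, 0.7])
    so = second_order_rdm([a, b])
    expected = 1 - _pearson([0.1, 0.5, 0.9], [0.2, 0.3, 0.7])
    assert np.isclose(so.matrix[0, 1], expected)


def test_second_order_size_mismatch():
    with pytest.raises(ValueError):
        second_order_rdm([_rdm_from([0.1, 0.2, 0.3]), RDM(np.zeros((4, 4)))])


def test_rdm_r2_self_affine_and_hand_value(rng):
    m = np.abs(rng.normal(size=(4, 4)))
    m = (m + m.T) / 2
    np.fill_diagonal(m, 0.0)
    a = RDM(np.clip(m, 0, 2))
    assert np.isclose(rdm_r2(a, a), 1.0)
    b = RDM(np.clip(0.5 * a.matrix + 0.1, 0, 2))
    np.fill_diagonal(b.matrix, 0.0)
    # affine rescaling of the triangle leaves the correlation untouched
    tri_b = 0.5 * a.upper_triangle() + 0.1
    bb = RDM(a.matrix.copy())
    iu = np.triu_indices(4, 1)
    bb.matrix[iu] = tri_b
    bb.matrix.T[iu] = tri_b
    assert np.isclose(rdm_r2(a, bb), 1.0)
    # hand value on two fixed 4x4 RDMs
    tri1 = np.array([0.1, 0.2, 0.3, 0.4, 0.5, 0.6])
    tri2 = np.array([0.15, 0.1, 0.42, 0.31, 0.55, 0.49])
    r_hand = _pearson(tri1, tri2) ** 2
    m1, m2 = np.zeros((4, 4)), np.zeros((4, 4))
    m1[iu], m2[iu] = tri1, tri2
    assert np.isclose(rdm_r2(RDM(m1 + m1.T), RDM(m2 + m2.T)), r_hand)


def test_rdm_r2_symmetric_in_arguments(rng):
    def rand_rdm():
        m = np.abs(rng.normal(size=(5, 5)))
        m = np.clip((m + m.T) / 2, 0, 2)
        np.fill_diagonal(m, 0)
        return RDM(m)
    a, b = rand_rdm(), rand_rdm()
    assert np.isclose(rdm_r2(a, b), rdm_r2(b, a))


def test_constant_triangle_r2_undefined():
    a = RDM(np.ones((3, 3)) - np.eye(3))
    with pytest.raises(ValueError):
        rdm_r2(a, a)


def test_average_preserves_invariants(rng):
    rdms = []
    for _ in range(5):
        acts = rng.normal(size=(6, 10))
        rdms.append(compute_rdm(acts))
    avg = average_rdms(rdms)
    avg.validate()
    assert avg.provenance["seed_average_count"] == 5


# ---------------------------------------------------------------------------
# MDS embedding
# ---------------------------------------------------------------------------

def test_mds_recovers_planar_configuration():
    pts = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
    d = np.linalg.norm(pts[:, None] - pts[None], axis=-1)
    coords = mds_embed(RDM(d), dims=2, seed=0)
    d2 = np.linalg.norm(coords[:, None] - coords[None], axis=-1)
    assert np.allclose(d2, d, atol=1e-6)


def test_mds_zero_rdm_collapses_points():
    coords = mds_embed(RDM(np.zeros((4, 4))), dims=2, seed=0)
    assert np.allclose(coords - coords[0], 0.0, atol=1e-8)


def test_mds_stress_non_increasing_with_dims(rng):
    m = np.abs(rng.normal(size=(8, 8)))
    m = np.clip((m + m.T) / 2, 0, 2)
    np.fill_diagonal(m, 0)
    rdm = RDM(m)
    _, s2 = mds_embed(rdm, dims=2, seed=0, return_stress=True)
    _, s3 = mds_embed(rdm, dims=3, seed=0, return_stress=True)
    assert s3 <= s2 + 1e-9


# ---------------------------------------------------------------------------
# layer enumeration and the sensitivity contrast
# ---------------------------------------------------------------------------

def test_twelve_layers_per_model(tiny_network, rng):
    images = rng.normal(size=(6, 1, 32, 32)).astype(np.float32)
    rdms = model_layer_rdms(tiny_network, images)
    assert len(rdms) == 12          # 10 residual units + GAP + softmax
    for rdm in rdms.values():
        rdm.validate()
        assert rdm.n == 6


def test_contrast_of_model_with_itself_is_zero(rng):
    def extract(images):
        return images.reshape(len(images), -1)
    pools = {c: rng.normal(size=(30, 8)) + c for c in range(4)}
    deltas = sensitivity_contrast(extract, extract, pools,
                                  sensitive_classes=[0, 1],
                                  insensitive_classes=[2, 3],
                                  reps=5, n_classes=2, n_images=10, seed=0)
    assert np.allclose(deltas, 0.0)


def test_contrast_detects_constructed_collapse(rng):
    """A model collapsing only the 'sensitive' classes yields delta < 0.

    The large model separates all classes; the small model projects the
    sensitive classes onto a shared mean (losing their distinctions), so
    R2(small, large) is lower in the sensitive condition.
    """
    centres = {c: rng.normal(size=16) * 4 for c in range(4)}
    pools = {c: centres[c] + rng.normal(0, 0.5, size=(40, 16))
             for c in range(4)}

    def extract_large(images):
        return images

    collapse = (centres[0] + centres[1]) / 2

    def extract_small(images):
        out = images.copy()
        for c in (0, 1):
            near = np.linalg.norm(images - centres[c], axis=1) < 3.0
            out[near] = collapse + 0.05 * (images[near] - collapse)
        return out + rng.normal(0, 0.01, images.shape)

    deltas = sensitivity_contrast(extract_small, extract_large, pools,
                                  sensitive_classes=[0, 1],
                                  insensitive_classes=[2, 3],
                                  reps=20, n_classes=2, n_images=15, seed=1)
    assert (deltas < 0).mean() > 0.5


def test_contrast_single_rep_reproducible(rng):
    pools = {c: rng.normal(size=(25, 6)) + 2 * c for c in range(4)}

    def extract(images):
        return images

    kwargs = dict(images_by_class=pools, sensitive_classes=[0, 1],
                  insensitive_classes=[2, 3], reps=1, n_classes=2,
                  n_images=8, seed=7)

    def noisy(images):
        return images + 0.3 * np.sin(images)

    d1 = sensitivity_contrast(noisy, extract, **kwargs)
    d2 = sensitivity_contrast(noisy, extract, **kwargs)
    assert d1.shape == (1,)
    assert np.array_equal(d1, d2)


def test_contrast_small_pool_samples_with_replacement(rng):
    pools = {0: rng.normal(size=(3, 5)), 1: rng.normal(size=(20, 5)),
             2: rng.normal(size=(20, 5)), 3: rng.normal(size=(20, 5))}

    def extract(images):
        return images + rng.normal(0, 0.01, images.shape)

    with pytest.warns(UserWarning):
        sensitivity_contrast(extract, lambda im: im, pools, [0, 1], [2, 3],
                             reps=1, n_classes=2, n_images=10, seed=0)
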