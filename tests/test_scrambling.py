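"""Permutation maps, composed models and invariance theorems."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from erfscope import nn
from erfscope.architectures import build_network, make_erf_variant
from erfscope.scrambling import (
    FollowUpSpec,
    PermutationMap,
    apply_permutation,
    compose,
    compute_composed_erf,
    make_global_permutation,
    make_local_permutation,
)
from erfscope import scrambling
from erfscope.training import TrainConfig, train


# ---------------------------------------------------------------------------
# permutation maps
# ---------------------------------------------------------------------------

@given(h=st.integers(1, 9), w=st.integers(1, 9), seed=st.integers(0, 1000))
@settings(max_examples=30, deadline=None)
def test_global_permutation_is_bijection(h, w, seed):
    perm = make_global_permutation(h, w, seed=seed)
    assert sorted(perm.mapping.tolist()) == list(range(h * w))


def test_global_permutation_reproducible_and_trivial_grid():
    assert make_global_permutation(1, 1, seed=3).mapping.tolist() == [0]
    a = make_global_permutation(2, 2, seed=42)
    b = make_global_permutation(2, 2, seed=42)
    assert np.array_equal(a.mapping, b.mapping)
    big = make_global_permutation(28, 28, seed=0)
    assert sorted(big.mapping.tolist()) == list(range(784))


@given(grid=st.integers(2, 10), window=st.integers(2, 5),
       seed=st.integers(0, 500))
@settings(max_examples=40, deadline=None)
def test_local_permutation_confined_to_tiles(grid, window, seed):
    """No index crosses its tile; displacement bounded by window - 1."""
    if window > grid:
        with pytest.warns(UserWarning):
            perm = make_local_permutation(grid, grid, window=window, seed=seed)
        assert sorted(perm.mapping.tolist()) == list(range(grid * grid))
        return
    perm = make_local_permutation(grid, grid, window=window, seed=seed)
    assert sorted(perm.mapping.tolist()) == list(range(grid * grid))
    for src, dst in enumerate(perm.mapping):
        sr, sc = divmod(src, grid)
        dr, dc = divmod(int(dst), grid)
        assert sr // window == dr // window
        assert sc // window == dc // window
    assert perm.displacements().max() <= window - 1


def test_local_window_one_is_identity():
    perm = make_local_permutation(6, 6, window=1, seed=9)
    assert np.array_equal(perm.mapping, np.arange(36))


def test_local_window_equals_grid_is_one_tile():
    perm = make_local_permutation(4, 4, window=4, seed=1)
    assert perm.scope == "local"
    assert sorted(perm.mapping.tolist()) == list(range(16))


def test_permutation_json_roundtrip():
    perm = make_local_permutation(4, 4, window=2, seed=5)
    back = PermutationMap.from_json(perm.to_json())
    assert np.array_equal(back.mapping, perm.mapping)
    assert (back.scope, back.window, back.seed) == ("local", 2, 5)


def test_non_bijection_rejected():
    with pytest.raises(ValueError):
        PermutationMap(2, 2, np.array([0, 0, 1, 2]))


# ---------------------------------------------------------------------------
# applying permutations
# ---------------------------------------------------------------------------

def test_apply_identity_and_inverse(rng):
    feats = rng.normal(size=(2, 3, 4, 4)).astype(np.float32)
    ident = PermutationMap(4, 4, np.arange(16))
    assert np.array_equal(apply_permutation(feats, ident), feats)
    perm = make_global_permutation(4, 4, seed=8)
    back = apply_permutation(apply_permutation(feats, perm), perm.inverse())
    assert np.array_equal(back, feats)


def test_apply_corner_swap_hand_checked():
    """2x2 swap (0<->3, 1<->2) exchanges whole feature columns."""
    feats = np.arange(2 * 2 * 2, dtype=np.float32).reshape(1, 2, 2, 2)
    perm = PermutationMap(2, 2, np.array([3, 2, 1, 0]))
    out = apply_permutation(feats, perm)
    assert np.array_equal(out[0, :, 0, 0], feats[0, :, 1, 1])
    assert np.array_equal(out[0, :, 0, 1], feats[0, :, 1, 0])
    assert np.array_equal(out[0, :, 1, 1], feats[0, :, 0, 0])


def test_apply_dimension_mismatch():
    perm = make_global_permutation(3, 3, seed=0)
    with pytest.raises(ValueError):
        apply_permutation(np.zeros((1, 2, 4, 4), dtype=np.float32), perm)


# ---------------------------------------------------------------------------
# composition and invariance theorems
# ---------------------------------------------------------------------------

def test_composed_erf_of_smallest_base_covers_input():
    base = make_erf_variant("erf11")
    assert compute_composed_erf(base, FollowUpSpec("aggregating")) == 235
    assert compute_composed_erf(base, FollowUpSpec("pointwise")) == 11


def test_followup_spec_conventions():
    agg = FollowUpSpec("aggregating")
    assert agg.strides == (2, 2, 1, 1) and agg.middle_kernel == 3
    pw = FollowUpSpec("pointwise")
    assert pw.strides == (1, 1, 1, 1) and pw.middle_kernel == 1
    with pytest.raises(ValueError):
        FollowUpSpec("fancy")


def test_base_classifier_invariant_to_feature_permutation(tiny_network, rng):
    """GAP + dense head cannot see spatial order: logits unchanged."""
    x = rng.normal(size=(8, 1, 32, 32)).astype(np.float32)
    feats = tiny_network.features(x)
    ref = tiny_network.head(feats)
    for seed in range(5):
        perm = make_global_permutation(*feats.shape[2:], seed=seed)
        moved = tiny_network.head(apply_permutation(feats, perm))
        assert np.max(np.abs(moved - ref)) < 1e-4


def test_pointwise_followup_invariant_to_any_permutation(tiny_network, rng):
    """1x1 convolutions + GAP commute with spatial permutation."""
    model = compose(tiny_network, FollowUpSpec("pointwise", width=16, seed=3))
    x = rng.normal(size=(8, 1, 32, 32)).astype(np.float32)
    feats = model.base_features(x)
    ref = model.forward_features(feats)
    for seed in range(3):
        for perm in (make_global_permutation(*feats.shape[2:], seed=seed),
                     make_local_permutation(*feats.shape[2:], window=2,
                                            seed=seed)):
            out = model.forward_features(apply_permutation(feats, perm))
            assert np.max(np.abs(out - ref)) < 1e-4


def test_base_frozen_during_composed_training(tiny_network, rng):
    snapshot = {k: v.copy() for k, v in tiny_network.state_dict().items()}
    model = compose(tiny_network, FollowUpSpec("aggregating", width=16,
                                               seed=3))
    x = rng.normal(size=(16, 1, 32, 32)).astype(np.float32)
    y = rng.integers(0, 4, size=16)
    train(model, x, y, TrainConfig(epochs=2, batch_size=8, seed=0))
    after = tiny_network.state_dict()
    for k, v in snapshot.items():
        assert np.array_equal(v, after[k]), f"base weights changed: {k}"


def test_train_time_permutation_constant_across_training(tiny_network, rng):
    perm = make_global_permutation(4, 4, seed=5)
    serialized = perm.to_json()
    model = compose(tiny_network, FollowUpSpec("aggregating", width=16,
                                               seed=3),
                    permutation=perm, train_time_scramble=True)
    x = rng.normal(size=(16, 1, 32, 32)).astype(np.float32)
    y = rng.integers(0, 4, size=16)
    train(model, x, y, TrainConfig(epochs=3, batch_size=8, seed=0))
    assert model.permutation.to_json() == serialized


def test_test_time_scramble_pointwise_identical(tiny_network, rng):
    model = compose(tiny_network, FollowUpSpec("pointwise", width=16, seed=3))
    x = rng.normal(size=(12, 1, 32, 32)).astype(np.float32)
    clean, scrambled = scrambling.test_time_scramble(model, x, scope="global", seed=0)
    assert np.array_equal(clean, scrambled)
    clean, scrambled = scrambling.test_time_scramble(model, x, scope="local", window=1,
                                          seed=0)
    assert np.array_equal(clean, scrambled)


def test_followup_width_mismatch_rejected(tiny_network, rng):
    model = compose(tiny_network, FollowUpSpec("aggregating", width=16,
                                               seed=3))
    bad = rng.normal(size=(2, 7, 4, 4)).astype(np.float32)
    with pytest.raises(ValueError):
        model.forward_features(bad)
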