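"""MIRC search: patch arithmetic, oracle equivalence, clustering."""

import numpy as np
import pytest

from erfscope.mirc import (
    MIRCTree,
    Patch,
    cluster_mircs,
    descendants,
    mirc_level_hist,
    mirc_search,
)


def side_at_level(side0: int, level: int) -> int:
    for _ in range(level):
        side0 = max(1, int(0.75 * side0))
    return side0


def threshold_oracle(threshold: int):
    """Correct iff the patch's smaller side is at least ``threshold``."""
    def classify(image, patch):
        ok = min(patch.height, patch.width) >= threshold
        return ok, 1.0 if ok else 0.0
    return classify


def analytic_mirc_level(side0: int, threshold: int, max_level: int) -> int:
    level = 0
    while (side_at_level(side0, level + 1) >= threshold
           and level + 1 <= max_level):
        level += 1
    return min(level, max_level)


# ---------------------------------------------------------------------------
# patch arithmetic
# ---------------------------------------------------------------------------

def test_descendants_geometry_224():
    patch = Patch(0, 0, 224, 224)
    kids = descendants(patch)
    assert all(k.height == 168 and k.width == 168 for k in kids)
    assert {(k.row, k.col) for k in kids} == {(0, 0), (0, 56), (56, 0),
                                              (56, 56)}
    assert all(k.level == 1 for k in kids)


def test_descendant_rounding_floor():
    kids = descendants(Patch(0, 0, 126, 126, level=2))
    assert kids[0].height == 94            # floor(0.75 * 126) = 94
    assert side_at_level(224, 2) == 126    # 224 -> 168 -> 126 exactly


def test_degenerate_one_pixel_patch():
    kids = descendants(Patch(5, 5, 1, 1, level=3))
    assert all(k.bbox == (5, 5, 1, 1) for k in kids)


def test_patch_crop_bounds():
    img = np.zeros((1, 10, 10))
    with pytest.raises(ValueError):
        Patch(5, 5, 10, 10).crop(img)


# ---------------------------------------------------------------------------
# oracle equivalence of the search
# ---------------------------------------------------------------------------

def test_misclassified_root_gives_empty_tree():
    img = np.zeros((1, 224, 224), dtype=np.float32)
    tree = mirc_search(threshold_oracle(500), img)
    assert tree.root is None
    assert tree.mircs() == []
    assert tree.max_mirc_level() is None
    assert "misclassified" in tree.reason


def test_threshold_100_gives_16_mircs_at_level_2():
    """Sides 224 -> 168 -> 126 -> 94: recognition dies at level 3."""
    img = np.zeros((1, 224, 224), dtype=np.float32)
    tree = mirc_search(threshold_oracle(100), img)
    tree.validate()
    mircs = tree.mircs()
    assert len(mircs) == 16
    assert all(m.patch.level == 2 for m in mircs)


@pytest.mark.parametrize("threshold", [50, 80, 100, 130, 200, 224])
def test_search_matches_closed_form_over_thresholds(threshold):
    img = np.zeros((1, 224, 224), dtype=np.float32)
    tree = mirc_search(threshold_oracle(threshold), img, max_level=10)
    tree.validate()
    expected_level = analytic_mirc_level(224, threshold, 10)
    assert tree.max_mirc_level() == expected_level
    levels = {m.patch.level for m in tree.mircs()}
    assert levels == {expected_level}
    if expected_level < 10:
        assert len(tree.mircs()) == 4 ** expected_level


def test_relaxing_threshold_never_shrinks_mirc_level():
    img = np.zeros((1, 224, 224), dtype=np.float32)
    levels = [mirc_search(threshold_oracle(t), img).max_mirc_level()
              for t in (200, 150, 100, 60, 30)]
    assert levels == sorted(levels)


def test_always_correct_oracle_capped_at_max_level():
    img = np.zeros((1, 64, 64), dtype=np.float32)
    tree = mirc_search(lambda image, patch: (True, 1.0), img, max_level=4)
    mircs = tree.mircs()
    assert all(m.patch.level == 4 and m.capped for m in mircs)


def test_memoization_evaluates_each_bbox_once():
    calls = []

    def counting(image, patch):
        calls.append(patch.bbox)
        return min(patch.height, patch.width) >= 100, 1.0

    img = np.zeros((1, 224, 224), dtype=np.float32)
    mirc_search(counting, img)
    assert len(calls) == len(set(calls))


def test_tree_json_roundtrip():
    img = np.zeros((1, 224, 224), dtype=np.float32)
    tree = mirc_search(threshold_oracle(150), img, image_id=3)
    back = MIRCTree.from_json(tree.to_json())
    assert back.max_mirc_level() == tree.max_mirc_level()
    assert len(back.mircs()) == len(tree.mircs())
    assert back.image_id == 3


# ---------------------------------------------------------------------------
# histograms
# ---------------------------------------------------------------------------

def test_level_histogram_point_mass_and_conservation():
    img = np.zeros((1, 224, 224), dtype=np.float32)
    trees = [mirc_search(threshold_oracle(100), img) for _ in range(5)]
    trees.append(mirc_search(threshold_oracle(500), img))  # empty tree
    hist = mirc_level_hist(trees)
    assert hist[2] == 5
    assert hist.sum() == 5          # empty trees contribute nothing
    assert mirc_level_hist([]).sum() == 0


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

def _toy_trees(n_images, level=1, size=32):
    trees = []
    for i in range(n_images):
        img = np.full((1, size, size), i / n_images, dtype=np.float32)
        t = mirc_search(
            lambda image, patch: (patch.level <= level - 1, 0.9), img,
            image_id=i, max_level=level)
        trees.append(t)
    return trees


def test_cluster_two_blobs_perfect_partition(rng):
    trees = _toy_trees(10)
    images = np.stack([np.full((1, 32, 32), i / 10, dtype=np.float32)
                       for i in range(10)])

    def extractor(batch):
        # two well-separated latent blobs keyed on intensity
        base = batch.mean(axis=(1, 2, 3), keepdims=False)[:, None]
        blob = (base > 0.45).astype(float) * 10
        return np.hstack([blob, base]) + rng.normal(0, 0.01, (len(batch), 2))

    table, exemplars = cluster_mircs(extractor, trees, images, k=2,
                                     n_exemplars=3, seed=0, input_side=32)
    by_cluster = table.groupby("cluster")["image_id"].apply(set)
    lo = {i for i in range(10) if i / 10 <= 0.45}
    assert set(map(frozenset, by_cluster)) == {frozenset(lo),
                                               frozenset(set(range(10)) - lo)}


def test_cluster_exemplars_from_distinct_images(rng):
    trees = _toy_trees(8)
    images = np.stack([np.full((1, 32, 32), i / 8, dtype=np.float32)
                       for i in range(8)])

    def extractor(batch):
        return rng.normal(size=(len(batch), 4))

    table, exemplars = cluster_mircs(extractor, trees, images, k=2,
                                     n_exemplars=4, seed=0, input_side=32)
    for ex in exemplars:
        ids = [table.iloc[i]["image_id"] for i in ex]
        assert len(ids) == len(set(ids))


def test_save_mirc_crops_writes_pngs(tmp_path):
    from erfscope.mirc import save_mirc_crops
    trees = _toy_trees(3, level=1)
    images = np.stack([np.full((1, 32, 32), i / 3, dtype=np.float32)
                       for i in range(3)])
    written = save_mirc_crops(trees, images, tmp_path)
    assert len(written) == 3
    assert all((tmp_path / w).exists() for w in written)


def test_cluster_too_few_mircs_reduces_k(rng):
    trees = _toy_trees(2)
    images = np.stack([np.full((1, 32, 32), i / 2, dtype=np.float32)
                       for i in range(2)])
    with pytest.warns(UserWarning):
        table, exemplars = cluster_mircs(
            lambda b: rng.normal(size=(len(b), 3)), trees, images, k=5,
            n_exemplars=8, seed=0, input_side=32)
    assert table["cluster"].nunique() <= 2
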