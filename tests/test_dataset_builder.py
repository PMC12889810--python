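import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gridtraj.dataset_builder import (
    GridDataset,
    augment_minority,
    load_dataset,
    rotate_grid,
    save_dataset,
    split_dataset,
    stack_dataset,
)
from gridtraj.grid_encoding import BinaryGrid, GridSpec

from conftest import random_grid


def make_dataset(rng, n_normal, n_abnormal, H=16, W=16):
    grids = [
        random_grid(rng, H, W, trip_id=f"n{i}", label="normal") for i in range(n_normal)
    ] + [
        random_grid(rng, H, W, trip_id=f"a{i}", label="abnormal")
        for i in range(n_abnormal)
    ]
    return stack_dataset(grids)


class TestRotateGrid:
    def test_180_on_2x2(self):
        grid = BinaryGrid(np.array([[1, 0], [0, 0]], dtype=np.uint8), GridSpec(2, 2), "t", "normal")
        np.testing.assert_array_equal(
            rotate_grid(grid, 180).values, np.array([[0, 0], [0, 1]])
        )

    def test_four_quarter_turns_are_identity(self):
        rng = np.random.default_rng(0)
        grid = random_grid(rng, 16, 16)
        out = grid
        for _ in range(4):
            out = rotate_grid(out, 90)
        np.testing.assert_array_equal(out.values, grid.values)

    def test_90_then_270_is_identity_and_popcount_invariant(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            grid = random_grid(rng, 64, 64)
            r = rotate_grid(grid, 90)
            assert r.popcount() == grid.popcount()
            assert r.label == grid.label and r.trip_id == grid.trip_id
            np.testing.assert_array_equal(rotate_grid(r, 270).values, grid.values)

    def test_90_matches_exhaustive_index_map(self):
        rng = np.random.default_rng(2)
        H = W = 8
        grid = random_grid(rng, H, W)
        rotated = rotate_grid(grid, 90)
        # counterclockwise: cell (i, j) -> (W-1-j, i)
        for i in range(H):
            for j in range(W):
                assert rotated.values[W - 1 - j, i] == grid.values[i, j]

    def test_group_laws(self):
        rng = np.random.default_rng(3)
        grid = random_grid(rng, 12, 12)
        r90_twice = rotate_grid(rotate_grid(grid, 90), 90)
        np.testing.assert_array_equal(r90_twice.values, rotate_grid(grid, 180).values)
        r180_twice = rotate_grid(rotate_grid(grid, 180), 180)
        np.testing.assert_array_equal(r180_twice.values, grid.values)

    def test_non_square_rejected_for_quarter_turns(self):
        grid = BinaryGrid(np.ones((2, 4), dtype=np.uint8), GridSpec(2, 4), "t")
        with pytest.raises(ValueError):
            rotate_grid(grid, 90)
        rotate_grid(grid, 180)  # 180 is fine on rectangles


class TestStack:
    def test_shape_and_parallel_vectors(self):
        rng = np.random.default_rng(4)
        ds = make_dataset(rng, 2, 1, H=128, W=128)
        assert ds.grids.shape == (3, 1, 128, 128)
        assert ds.labels.tolist() == [0, 0, 1]
        assert list(ds.trip_ids) == ["n0", "n1", "a0"]
        assert set(ds.provenance) == {"original"}

    def test_empty_stack_with_declared_resolution(self):
        ds = stack_dataset([], resolution=(32, 32))
        assert ds.grids.shape == (0, 1, 32, 32)

    def test_mixed_resolutions_rejected(self):
        rng = np.random.default_rng(5)
        with pytest.raises(ValueError, match="resolution"):
            stack_dataset([random_grid(rng, 8, 8), random_grid(rng, 16, 16)])

    def test_missing_label_rejected(self):
        rng = np.random.default_rng(6)
        with pytest.raises(ValueError):
            stack_dataset([random_grid(rng, 8, 8, label=None)])

    def test_save_load_round_trip(self, tmp_path):
        rng = np.random.default_rng(7)
        ds = make_dataset(rng, 3, 2)
        path = tmp_path / "ds.npz"
        save_dataset(ds, path)
        back = load_dataset(path)
        np.testing.assert_array_equal(back.grids, ds.grids)
        np.testing.assert_array_equal(back.labels, ds.labels)
        assert list(back.trip_ids) == list(ds.trip_ids)
        assert list(back.provenance) == list(ds.provenance)


class TestAugmentMinority:
    def test_counts_10_normal_2_abnormal(self):
        rng = np.random.default_rng(8)
        ds = make_dataset(rng, 10, 2)
        out = augment_minority(ds, (90, 180, 270))
        assert (out.labels == 0).sum() == 10
        assert (out.labels == 1).sum() == 8  # 2 original + 6 rotated

    def test_balanced_ties_toward_abnormal(self):
        rng = np.random.default_rng(9)
        ds = make_dataset(rng, 4, 4)
        out = augment_minority(ds, (90,))
        assert len(out) == 8 + 4
        assert (out.labels == 1).sum() == 8

    def test_originals_untouched_and_majority_count_preserved(self):
        rng = np.random.default_rng(10)
        ds = make_dataset(rng, 6, 3)
        before = ds.grids.copy()
        out = augment_minority(ds)
        np.testing.assert_array_equal(out.grids[: len(ds)], before)
        assert (out.labels == 0).sum() == (ds.labels == 0).sum()

    def test_augmented_samples_equal_rotate_grid_of_source(self):
        rng = np.random.default_rng(11)
        ds = make_dataset(rng, 5, 2)
        out = augment_minority(ds, (90, 180, 270))
        sources = {tid: g for tid, g in zip(ds.trip_ids, ds.grids[:, 0])}
        for grid, tid, prov, label in zip(
            out.grids[len(ds):, 0], out.trip_ids[len(ds):],
            out.provenance[len(ds):], out.labels[len(ds):],
        ):
            angle = int(prov.replace("rot", ""))
            src = BinaryGrid(sources[str(tid)], GridSpec(16, 16), str(tid), "abnormal")
            np.testing.assert_array_equal(grid, rotate_grid(src, angle).values)
            assert label == 1

    def test_single_class_rejected(self):
        rng = np.random.default_rng(12)
        grids = [random_grid(rng, 8, 8, trip_id=f"n{i}", label="normal") for i in range(4)]
        with pytest.raises(ValueError, match="two classes"):
            augment_minority(stack_dataset(grids))


class TestSplit:
    def test_stratified_counts(self):
        rng = np.random.default_rng(13)
        ds = make_dataset(rng, 80, 20)
        train, test = split_dataset(ds, 0.2, seed=0)
        assert (test.labels == 0).sum() == 16
        assert (test.labels == 1).sum() == 4
        assert len(train) == 80

    def test_deterministic_and_disjoint_union(self):
        rng = np.random.default_rng(14)
        ds = make_dataset(rng, 30, 10)
        t1, s1 = split_dataset(ds, 0.25, seed=5)
        t2, s2 = split_dataset(ds, 0.25, seed=5)
        assert list(t1.trip_ids) == list(t2.trip_ids)
        assert list(s1.trip_ids) == list(s2.trip_ids)
        union = set(t1.trip_ids) | set(s1.trip_ids)
        assert union == set(ds.trip_ids)
        assert not (set(t1.trip_ids) & set(s1.trip_ids))

    def test_rotated_copies_follow_their_source(self):
        rng = np.random.default_rng(15)
        ds = augment_minority(make_dataset(rng, 12, 4))
        train, test = split_dataset(ds, 0.25, seed=1)
        for part in (train, test):
            for tid in set(part.trip_ids):
                where_train = (train.trip_ids == tid).sum()
                where_test = (test.trip_ids == tid).sum()
                assert where_train == 0 or where_test == 0

    def test_tiny_class_rejected(self):
        rng = np.random.default_rng(16)
        ds = make_dataset(rng, 5, 1)
        with pytest.raises(ValueError, match="abnormal"):
            split_dataset(ds, 0.5, seed=0)


@given(st.integers(2, 12), st.integers(2, 12), st.integers(0, 2**16))
@settings(max_examples=25, deadline=None)
def test_augmentation_is_popcount_and_label_preserving(n_norm, n_abn, seed):
    rng = np.random.default_rng(seed)
    ds = make_dataset(rng, n_norm, n_abn)
    out = augment_minority(ds, (90, 180, 270))
    minority = 1 if n_abn <= n_norm else 0
    n_min = min(n_norm, n_abn) if n_norm != n_abn else n_abn
    assert len(out) == len(ds) + 3 * n_min
    # each rotated copy preserves its source's popcount
    sources = {tid: g.sum() for tid, g in zip(ds.trip_ids, ds.grids[:, 0])}
    for grid, tid in zip(out.grids[len(ds):, 0], out.trip_ids[len(ds):]):
        assert grid.sum() == sources[str(tid)]
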