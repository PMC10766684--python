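import numpy as np
import pytest

from lamseg.classifier import CenterLabelOracle
from lamseg.localization import split_slices
from lamseg.metrics import score_structure
from lamseg.reconstruction import (SparseMap, assemble_volume, assign_labels,
                                   build_sparse_map, density_scan,
                                   reassign_small_components,
                                   reconstruct_slice, ConfidenceMaps)
from lamseg.stack_io import LabelScheme


def naive_density(counts, w):
    """O(H W w^2) double-loop window sum, zero-padded — the oracle."""
    c, h, wd = counts.shape
    half = w // 2
    out = np.zeros_like(counts)
    for k in range(c):
        for y in range(h):
            for x in range(wd):
                acc = 0
                for dy in range(-half, half + 1):
                    for dx in range(-half, half + 1):
                        yy, xx = y + dy, x + dx
                        if 0 <= yy < h and 0 <= xx < wd:
                            acc += counts[k, yy, xx]
                out[k, y, x] = acc
    return out


class TestSparseMap:
    def test_empty_predictions_give_zero_map(self):
        sm = build_sparse_map([], (5, 5), 3)
        assert sm.counts.shape == (3, 5, 5) and not sm.counts.any()
        assert sm.n_filled == 0

    def test_single_vote_lands_on_its_channel(self):
        oh = np.array([0, 0, 0, 1, 0])
        sm = build_sparse_map([((10, 10), oh)], (20, 20), 5)
        assert sm.counts[3, 10, 10] == 1 and sm.counts.sum() == 1

    def test_collisions_accumulate_per_channel(self):
        votes = [((2, 2), np.array([0, 1, 0])), ((2, 2), np.array([0, 0, 1]))]
        sm = build_sparse_map(votes, (4, 4), 3)
        assert sm.counts[1, 2, 2] == 1 and sm.counts[2, 2, 2] == 1
        assert sm.counts.sum() == sm.n_filled == 2

    def test_out_of_bounds_center_rejected(self):
        with pytest.raises(ValueError):
            build_sparse_map([((5, 0), np.array([1, 0]))], (5, 5), 2)


class TestDensityScan:
    def test_zero_map_gives_zero_density(self):
        sm = SparseMap(np.zeros((2, 10, 10), np.int64), 0)
        assert not density_scan(sm, 5).density.any()

    def test_single_count_spreads_to_window_block(self):
        counts = np.zeros((1, 120, 120), np.int64)
        counts[0, 60, 60] = 1
        conf = density_scan(SparseMap(counts, 1), 51)
        block = conf.density[0, 35:86, 35:86]
        assert np.all(block == 1)
        assert conf.density.sum() == 51 * 51

    @pytest.mark.parametrize("shape,w", [((3, 40, 40), 7), ((2, 15, 23), 5),
                                         ((1, 9, 9), 9)])
    def test_exactly_matches_double_loop_oracle(self, rng, shape, w):
        counts = rng.integers(0, 4, size=shape).astype(np.int64)
        conf = density_scan(SparseMap(counts, int(counts.sum())), w)
        np.testing.assert_array_equal(conf.density, naive_density(counts, w))

    def test_even_or_nonpositive_window_rejected(self):
        sm = SparseMap(np.zeros((1, 5, 5), np.int64), 0)
        with pytest.raises(ValueError):
            density_scan(sm, 4)
        with pytest.raises(ValueError):
            density_scan(sm, 0)


class TestAssignLabels:
    def test_all_zero_confidence_is_background(self):
        conf = ConfidenceMaps(np.zeros((3, 6, 6)), 5)
        assert not assign_labels(conf, np.ones((6, 6), bool)).any()

    def test_dominant_channel_wins_one_based(self):
        density = np.zeros((4, 3, 3))
        density[2, 1, 1] = 9.0
        labels = assign_labels(ConfidenceMaps(density, 3), np.ones((3, 3), bool))
        assert labels[1, 1] == 3

    def test_tie_goes_to_lower_structure_and_matches_brute_force(self, rng):
        density = rng.integers(0, 5, size=(4, 12, 12)).astype(float)
        fg = rng.random((12, 12)) < 0.7
        labels = assign_labels(ConfidenceMaps(density, 5), fg)
        for y in range(12):
            for x in range(12):
                if not fg[y, x] or density[:, y, x].sum() == 0:
                    assert labels[y, x] == 0
                else:
                    best = min(np.flatnonzero(
                        density[:, y, x] == density[:, y, x].max()))
                    assert labels[y, x] == best + 1

    def test_output_is_a_partition_in_range(self, rng):
        density = rng.random((5, 20, 20))
        fg = rng.random((20, 20)) < 0.5
        labels = assign_labels(ConfidenceMaps(density, 3), fg)
        assert labels.min() >= 0 and labels.max() <= 5


class TestReassignSmallComponents:
    def test_single_component_per_structure_unchanged(self):
        rr = np.zeros((10, 10), np.uint8)
        rr[2:5, 2:5] = 1
        rr[6:9, 6:9] = 2
        np.testing.assert_array_equal(reassign_small_components(rr, 0.1), rr)

    def test_island_goes_to_longest_boundary_neighbor(self):
        """A 5 px island of structure 1 embedded in structure 2 is handed to 2."""
        rr = np.zeros((30, 30), np.uint8)
        rr[:, :15] = 1          # large component of 1 (area 450)
        rr[:, 15:] = 2          # structure 2
        rr[10:15, 20] = 1       # 5 px island of 1 inside 2
        out = reassign_small_components(rr, 0.1)
        assert np.all(out[10:15, 20] == 2)
        assert np.all(out[:, :15] == 1)

    def test_island_surrounded_by_background_becomes_background(self):
        rr = np.zeros((20, 20), np.uint8)
        rr[2:10, 2:10] = 1
        rr[15, 15] = 1  # isolated pixel, only background neighbors
        out = reassign_small_components(rr, 0.1)
        assert out[15, 15] == 0

    def test_invariants_on_random_label_maps(self, rng):
        from skimage.measure import label as cc_label
        for _ in range(20):
            rr = rng.integers(0, 4, size=(25, 25)).astype(np.uint8)
            out = reassign_small_components(rr, 0.3)
            assert set(np.unique(out)) <= set(np.unique(rr)) | {0}
            for s in np.unique(rr):
                if s == 0:
                    continue
                before = cc_label(rr == s, connectivity=2)
                areas = np.bincount(before.ravel())[1:]
                largest = areas.max()
                # the largest component never shrinks
                keep = before == (np.argmax(areas) + 1)
                assert np.all(out[keep] == s)
                # every sub-threshold component is gone
                for ci in np.flatnonzero(areas < 0.3 * largest):
                    assert not np.any(out[before == ci + 1] == s)

    def test_bad_fraction_rejected(self):
        with pytest.raises(ValueError):
            reassign_small_components(np.zeros((4, 4), np.uint8), 1.0)


class TestReconstructSlice:
    def test_oracle_classifier_recovers_ground_truth(self, tiny_phantom, rng):
        stack, gt = tiny_phantom
        z = 1
        fg = gt.labels[z] > 0
        oracle = CenterLabelOracle(gt.labels[z], gt.scheme.c)
        out = reconstruct_slice(stack[z], fg, oracle, m=8000, p=5, w=15,
                                rng=rng)
        for s in range(1, gt.scheme.c + 1):
            dsc = score_structure(out == s, gt.labels[z] == s).dsc
            assert dsc >= 0.9, f"structure {s}: DSC {dsc:.3f}"

    def test_every_pixel_sampled_once_is_near_perfect(self, tiny_phantom):
        """Dense sampling limit: one vote per foreground pixel -> DSC ~ 1
        up to window effects at structure borders."""
        _, gt = tiny_phantom
        z = 0
        labels = gt.labels[z]
        fg = labels > 0
        ys, xs = np.nonzero(fg)
        votes = []
        for y, x in zip(ys, xs):
            oh = np.zeros(gt.scheme.c, np.uint8)
            oh[labels[y, x] - 1] = 1
            votes.append(((y, x), oh))
        sm = build_sparse_map(votes, labels.shape, gt.scheme.c)
        conf = density_scan(sm, 15)
        out = reassign_small_components(assign_labels(conf, fg), 0.05)
        for s in range(1, gt.scheme.c + 1):
            assert score_structure(out == s, labels == s).dsc >= 0.95

    def test_dsc_non_decreasing_in_patch_number(self, tiny_phantom):
        """More prediction patches help (on average over seeds)."""
        stack, gt = tiny_phantom
        z = 2
        fg = gt.labels[z] > 0
        oracle = CenterLabelOracle(gt.labels[z], gt.scheme.c)

        def mean_dsc(m, seed):
            out = reconstruct_slice(stack[z], fg, oracle, m=m, p=5, w=15,
                                    rng=np.random.default_rng(seed))
            return np.mean([score_structure(out == s, gt.labels[z] == s).dsc
                            for s in range(1, gt.scheme.c + 1)])

        lo = np.mean([mean_dsc(500, s) for s in range(5)])
        hi = np.mean([mean_dsc(5000, s) for s in range(5)])
        assert hi >= lo - 0.02

    def test_zero_patches_warns_and_returns_background(self, tiny_phantom, rng):
        stack, gt = tiny_phantom
        oracle = CenterLabelOracle(gt.labels[0], gt.scheme.c)
        with pytest.warns(UserWarning):
            out = reconstruct_slice(stack[0], gt.labels[0] > 0, oracle,
                                    m=0, p=5, w=25, rng=rng)
        assert not out.any()

    def test_fixed_seed_reproduces_output(self, tiny_phantom):
        stack, gt = tiny_phantom
        oracle = CenterLabelOracle(gt.labels[0], gt.scheme.c)
        outs = [reconstruct_slice(stack[0], gt.labels[0] > 0, oracle, m=2000,
                                  p=5, w=25, rng=np.random.default_rng(9))
                for _ in range(2)]
        np.testing.assert_array_equal(outs[0], outs[1])


class TestAssembleVolume:
    def _scheme(self):
        return LabelScheme(("a", "b", "c"))

    def test_all_training_passes_through(self):
        split = split_slices(3, 1)
        anns = {i: np.full((4, 4), i, np.uint8) for i in range(3)}
        vol = assemble_volume(split, anns, {}, self._scheme())
        for i in range(3):
            np.testing.assert_array_equal(vol.labels[i], anns[i])

    def test_z_order_interleaves_maps(self):
        split = split_slices(3, 2)  # TC = {0, 2}, PC = {1}
        ta = {0: np.full((2, 2), 1, np.uint8), 2: np.full((2, 2), 2, np.uint8)}
        pr = {1: np.full((2, 2), 3, np.uint8)}
        vol = assemble_volume(split, ta, pr, self._scheme())
        assert (vol.labels[0, 0, 0], vol.labels[1, 0, 0],
                vol.labels[2, 0, 0]) == (1, 3, 2)

    def test_training_slices_are_bit_identical(self, rng):
        split = split_slices(5, 2)
        ta = {i: rng.integers(0, 4, (6, 6)).astype(np.uint8) for i in (0, 2, 4)}
        pr = {i: np.zeros((6, 6), np.uint8) for i in (1, 3)}
        vol = assemble_volume(split, ta, pr, self._scheme())
        for i in (0, 2, 4):
            np.testing.assert_array_equal(vol.labels[i], ta[i])

    def test_missing_and_duplicate_slices_rejected(self):
        split = split_slices(3, 2)
        ta = {0: np.zeros((2, 2), np.uint8), 2: np.zeros((2, 2), np.uint8)}
        with pytest.raises(ValueError, match="neither"):
            assemble_volume(split, ta, {}, self._scheme())
        with pytest.raises(ValueError, match="both"):
            assemble_volume(split, ta, {0: np.zeros((2, 2), np.uint8),
                                        1: np.zeros((2, 2), np.uint8)},
                            self._scheme())
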