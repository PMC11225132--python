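import numpy as np
import pytest

from hippofill import (
    FillingParams,
    MaskVolume,
    bridge_slice_regions,
    fill_holes_slice,
    filling_technique,
    keep_largest_components,
    label_components,
    largest_connected_component,
    postprocess_pipeline,
)
from oracles import (
    border_flood_fill_holes,
    bridged_component_count,
    flood_fill_label,
    random_blob_mask,
)


def two_squares_slice():
    """Canonical geometry: two 3x3 squares, closest points one column apart
    (Manhattan distance 2)."""
    s = np.zeros((9, 9), dtype=np.uint8)
    s[3:6, 1:4] = 1
    s[3:6, 5:8] = 1
    return s


class TestLabelComponents:
    def test_two_separated_blocks(self):
        g = np.zeros((8, 8, 8), dtype=np.uint8)
        g[0:2, 0:2, 0:2] = 1
        g[0:2, 0:2, 5:7] = 1
        lab = label_components(MaskVolume(g))
        assert lab.n_components == 2
        assert sorted(lab.sizes) == [8, 8]

    def test_empty_mask(self):
        lab = label_components(MaskVolume(np.zeros((4, 4, 4), dtype=np.uint8)))
        assert lab.n_components == 0
        assert lab.sizes.size == 0

    def test_invalid_connectivity(self):
        with pytest.raises(ValueError, match="connectivity"):
            label_components(np.zeros((4, 4)), connectivity=6)

    @pytest.mark.parametrize("connectivity", [6, 26])
    def test_matches_flood_fill_oracle(self, rng, connectivity):
        for _ in range(10):
            g = (rng.random((8, 8, 8)) < 0.3).astype(np.uint8)
            lab = label_components(g, connectivity)
            oracle_labels, oracle_n = flood_fill_label(g, connectivity)
            assert lab.n_components == oracle_n
            # identical partition AND identical raster-order label assignment
            assert np.array_equal(lab.labels, oracle_labels)
            assert lab.sizes.sum() == g.sum()

    def test_sizes_sum_to_foreground(self, rng):
        g = (rng.random((10, 10, 10)) < 0.2).astype(np.uint8)
        lab = label_components(g)
        assert lab.sizes.sum() == g.sum()


class TestLargestComponent:
    def test_removes_isolated_voxel(self):
        g = np.zeros((10, 10, 10), dtype=np.uint8)
        g[1:6, 1:6, 1:6] = 1
        g[8, 8, 8] = 1
        out = largest_connected_component(MaskVolume(g))
        assert out.foreground_count() == 125
        assert out.grid[8, 8, 8] == 0

    def test_empty_in_empty_out(self):
        out = largest_connected_component(MaskVolume(np.zeros((4, 4, 4), dtype=np.uint8)))
        assert out.is_empty()

    def test_equal_size_tie_break_keeps_first_raster(self):
        g = np.zeros((8, 8, 8), dtype=np.uint8)
        g[5, 5, 5] = 1  # later in raster order
        g[0, 0, 0] = 1  # earlier
        out = largest_connected_component(MaskVolume(g))
        assert out.grid[0, 0, 0] == 1 and out.grid[5, 5, 5] == 0

    def test_output_subset_single_component(self, rng):
        g = (rng.random((10, 10, 10)) < 0.2).astype(np.uint8)
        out = largest_connected_component(MaskVolume(g))
        assert ((out.grid == 1) <= (g == 1)).all()
        if g.any():
            assert label_components(out).n_components == 1

    def test_keep_two_preserves_bilateral(self):
        g = np.zeros((10, 10, 20), dtype=np.uint8)
        g[2:7, 2:7, 2:6] = 1
        g[2:7, 2:7, 14:18] = 1
        g[9, 9, 9] = 1  # noise
        out = keep_largest_components(MaskVolume(g), n_keep=2)
        assert label_components(out).n_components == 2
        assert out.grid[9, 9, 9] == 0


class TestBridgeSliceRegions:
    def test_canonical_theta_1_vs_3(self):
        s = two_squares_slice()
        assert label_components(bridge_slice_regions(s, 1), 8).n_components == 2
        assert label_components(bridge_slice_regions(s, 3), 8).n_components == 1

    def test_theta_zero_is_identity(self, rng):
        s = (rng.random((16, 16)) < 0.2).astype(np.uint8)
        assert np.array_equal(bridge_slice_regions(s, 0), s)

    def test_output_superset(self, rng):
        for theta in (1, 3, 5):
            s = random_blob_mask(rng, (24, 24), n_blobs=4)
            out = bridge_slice_regions(s, theta)
            assert ((s == 1) <= (out == 1)).all()

    def test_matches_transitive_closure_oracle(self, rng):
        for _ in range(20):
            s = random_blob_mask(rng, (32, 32), n_blobs=5)
            theta = int(rng.integers(0, 8))
            out = bridge_slice_regions(s, theta)
            assert label_components(out, 8).n_components == bridged_component_count(s, theta)

    def test_monotone_in_theta(self, rng):
        s = random_blob_mask(rng, (32, 32), n_blobs=5)
        counts = [label_components(bridge_slice_regions(s, t), 8).n_components for t in range(8)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_negative_theta_rejected(self):
        with pytest.raises(ValueError):
            bridge_slice_regions(np.zeros((4, 4)), -1)


class TestFillHoles:
    def test_ring_filled(self):
        s = np.zeros((7, 7), dtype=np.uint8)
        s[1:6, 1:6] = 1
        s[3, 3] = 0
        out = fill_holes_slice(s)
        assert out[3, 3] == 1
        assert out.sum() == 25

    def test_no_enclosed_background_unchanged(self):
        s = np.zeros((6, 6), dtype=np.uint8)
        s[0:3, 0:3] = 1
        assert np.array_equal(fill_holes_slice(s), s)

    def test_matches_border_flood_fill_oracle(self, rng):
        for _ in range(20):
            s = (rng.random((16, 16)) < 0.45).astype(np.uint8)
            assert np.array_equal(fill_holes_slice(s), border_flood_fill_holes(s))


class TestFillingTechnique:
    def test_solid_mask_unchanged(self):
        g = np.zeros((6, 8, 8), dtype=np.uint8)
        g[1:5, 2:6, 2:6] = 1
        out = filling_technique(MaskVolume(g), FillingParams(theta=3))
        assert np.array_equal(out.grid, g)

    def test_two_region_stack_theta_3_single_component_per_slice(self):
        s = two_squares_slice()
        g = np.stack([s] * 4)
        out = filling_technique(MaskVolume(g), FillingParams(theta=3))
        for k in range(4):
            assert label_components(out.grid[k], 8).n_components == 1
        out1 = filling_technique(MaskVolume(g), FillingParams(theta=1))
        for k in range(4):
            assert label_components(out1.grid[k], 8).n_components == 2

    def test_idempotent_and_grows(self, rng):
        g = (rng.random((8, 20, 20)) < 0.15).astype(np.uint8)
        params = FillingParams(theta=4)
        once = filling_technique(MaskVolume(g), params)
        twice = filling_technique(once, params)
        assert np.array_equal(once.grid, twice.grid)
        assert ((g == 1) <= (once.grid == 1)).all()

    def test_slice_axis_override(self):
        s = two_squares_slice()
        g = np.stack([s] * 4, axis=2)  # slices now along axis 2
        out = filling_technique(MaskVolume(g), FillingParams(theta=3, slice_axis=2))
        for k in range(4):
            assert label_components(out.grid[:, :, k], 8).n_components == 1

    def test_hollow_phantom_dice_strictly_increases(self):
        from hippofill import corrupt, dice, generate_gt

        _, gt = generate_gt(seed=11)
        pred, _ = corrupt(gt, modes=("hollow",), seed=12)
        repaired = filling_technique(pred, FillingParams(theta=3))
        assert dice(gt, repaired) > dice(gt, pred)


class TestPipeline:
    def test_clean_mask_unchanged(self):
        g = np.zeros((8, 10, 10), dtype=np.uint8)
        g[2:6, 3:8, 3:8] = 1
        out = postprocess_pipeline(MaskVolume(g))
        assert np.array_equal(out.grid, g)

    def test_blob_noise_hole_repaired(self):
        g = np.zeros((12, 16, 16), dtype=np.uint8)
        g[2:9, 3:12, 3:12] = 1
        g[4:7, 6:9, 6:9] = 0  # internal cavity
        g[11, 14, 14] = 1  # distant noise voxel
        out = postprocess_pipeline(MaskVolume(g), FillingParams(theta=3), n_keep=1)
        assert label_components(out).n_components == 1
        assert out.grid[5, 7, 7] == 1  # cavity filled
        assert out.grid[11, 14, 14] == 0  # noise removed

    def test_empty_prediction_stays_empty(self):
        out = postprocess_pipeline(MaskVolume(np.zeros((6, 6, 6), dtype=np.uint8)))
        assert out.is_empty()

    def test_output_binary(self, rng):
        g = (rng.random((8, 12, 12)) < 0.2).astype(np.uint8)
        out = postprocess_pipeline(MaskVolume(g))
        assert set(np.unique(out.grid)) <= {0, 1}
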