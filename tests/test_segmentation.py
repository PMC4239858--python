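"""HU-window classification, VOI masking, pooling and mask filtering."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import ndimage

from ctcomp import (
    ADIPOSE,
    ADIPOSE_NARROW,
    BODY,
    BONE,
    LEAN,
    HUWindow,
    TissueMask,
    VoxelGrid,
    apply_voi_mask,
    auto_body_voi,
    median_filter_mask,
    parse_window,
    reduce_by_two,
    resample_to,
    segment_window,
)


def naive_segment(data, lo, hi):
    """Triple-loop reference classifier (independent oracle)."""
    out = np.zeros(data.shape, dtype=np.uint8)
    for z in range(data.shape[0]):
        for y in range(data.shape[1]):
            for x in range(data.shape[2]):
                if lo <= data[z, y, x] < hi:
                    out[z, y, x] = 1
    return out


class TestSegmentWindow:
    def test_uniform_grids(self):
        grid = VoxelGrid(np.full((3, 3, 3), -100.0), 250.0)
        assert segment_window(grid, ADIPOSE).count() == 27
        grid0 = VoxelGrid(np.zeros((3, 3, 3)), 250.0)
        assert segment_window(grid0, ADIPOSE).count() == 0

    def test_half_open_boundaries(self):
        # -300 is in, -50 belongs to the next window up
        grid = VoxelGrid(np.array([[[-400.0, -300.0, -51.0, -50.0]]]), 250.0)
        mask = segment_window(grid, ADIPOSE)
        np.testing.assert_array_equal(mask.data[0, 0], [0, 1, 1, 0])
        assert segment_window(grid, LEAN).data[0, 0, 3] == 1

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_naive_triple_loop(self, seed):
        rng = np.random.default_rng(seed)
        data = rng.uniform(-1024, 4000, size=(8, 8, 8)).astype(np.float32)
        grid = VoxelGrid(data, 250.0)
        for window in (ADIPOSE, LEAN, BONE, BODY):
            np.testing.assert_array_equal(
                segment_window(grid, window).data,
                naive_segment(grid.data, window.lo, window.hi),
            )

    def test_window_validation_and_parsing(self):
        with pytest.raises(ValueError):
            HUWindow(10, 10)
        assert parse_window("adipose") is ADIPOSE
        w = parse_window("-250:-80")
        assert (w.lo, w.hi) == (-250.0, -80.0)
        with pytest.raises(ValueError):
            parse_window("marrow")


class TestWindowInvariants:
    def test_compartments_disjoint_and_nested(self, random_grid):
        adipose = segment_window(random_grid, ADIPOSE).data.astype(bool)
        lean = segment_window(random_grid, LEAN).data.astype(bool)
        bone = segment_window(random_grid, BONE).data.astype(bool)
        body = segment_window(random_grid, BODY).data.astype(bool)
        assert not (adipose & lean).any()
        assert not (lean & bone).any()
        assert not (adipose & bone).any()
        union = adipose | lean | bone
        assert (union <= body).all()

    @given(lo=st.floats(-1000, 0), width=st.floats(10, 500), extra=st.floats(1, 500))
    @settings(max_examples=30, deadline=None)
    def test_widening_never_decreases_count(self, lo, width, extra):
        rng = np.random.default_rng(99)
        grid = VoxelGrid(rng.uniform(-1024, 1000, size=(6, 6, 6)), 250.0)
        narrow = segment_window(grid, HUWindow(lo, lo + width))
        wide = segment_window(grid, HUWindow(lo - extra, lo + width + extra))
        assert wide.count() >= narrow.count()


class TestVoiMask:
    def test_identity_and_blanking(self, random_grid):
        ones = TissueMask(np.ones(random_grid.shape), random_grid.edge_um)
        np.testing.assert_array_equal(
            apply_voi_mask(random_grid, ones).data, random_grid.data
        )
        zeros = TissueMask(np.zeros(random_grid.shape), random_grid.edge_um)
        assert (apply_voi_mask(random_grid, zeros).data == -1000.0).all()

    def test_single_voxel_exclusion(self, random_grid):
        voi = np.ones(random_grid.shape)
        voi[2, 3, 4] = 0
        out = apply_voi_mask(random_grid, TissueMask(voi, random_grid.edge_um))
        assert out.data[2, 3, 4] == -1000.0
        changed = out.data != random_grid.data
        assert changed.sum() == 1

    def test_shape_mismatch(self, random_grid):
        with pytest.raises(ValueError, match="shape"):
            apply_voi_mask(random_grid, TissueMask(np.ones((2, 2, 2)), 250.0))


class TestAutoBodyVoi:
    @staticmethod
    def _ellipsoid_grid():
        z, y, x = np.mgrid[0:24, 0:20, 0:20]
        inside = ((z - 12) / 9) ** 2 + ((y - 10) / 6) ** 2 + ((x - 10) / 6) ** 2 <= 1
        data = np.where(inside, 60.0, -1000.0).astype(np.float32)
        return inside, VoxelGrid(data, 250.0)

    def test_recovers_solid_ellipsoid(self):
        inside, grid = self._ellipsoid_grid()
        voi = auto_body_voi(grid)
        np.testing.assert_array_equal(voi.data.astype(bool), inside)

    def test_discards_detached_artifact(self):
        inside, grid = self._ellipsoid_grid()
        grid.data[0:2, 0:2, 0:2] = 200.0  # small detached bed artifact
        voi = auto_body_voi(grid)
        np.testing.assert_array_equal(voi.data.astype(bool), inside)

    def test_fills_internal_holes(self):
        inside, grid = self._ellipsoid_grid()
        grid.data[12, 10, 10] = -1000.0  # air pocket (e.g. gut lumen)
        voi = auto_body_voi(grid)
        assert voi.data[12, 10, 10] == 1

    def test_tail_crop_removes_slices(self):
        inside, grid = self._ellipsoid_grid()
        voi = auto_body_voi(grid, tail_crop=(20, 24))
        assert voi.data[20:].sum() == 0
        assert voi.data[:20].sum() == inside[:20].sum()

    def test_pure_air_errors(self):
        grid = VoxelGrid(np.full((4, 4, 4), -1000.0), 250.0)
        with pytest.raises(ValueError, match="air"):
            auto_body_voi(grid)


class TestPooling:
    def test_uniform_grid_reduces_to_uniform(self):
        grid = VoxelGrid(np.full((4, 4, 4), -123.0), 125.0)
        out = reduce_by_two(grid)
        assert out.shape == (2, 2, 2)
        assert out.edge_um == 250.0
        assert (out.data == -123.0).all()

    def test_block_mean(self):
        data = np.zeros((2, 2, 2))
        data[0] = -100.0  # four voxels at -100, four at 0
        out = reduce_by_two(VoxelGrid(data, 125.0))
        assert out.data[0, 0, 0] == pytest.approx(-50.0)

    def test_odd_trailing_slices_dropped(self):
        grid = VoxelGrid(np.zeros((5, 5, 5)), 125.0)
        assert reduce_by_two(grid).shape == (2, 2, 2)

    def test_too_small_errors(self):
        with pytest.raises(ValueError):
            reduce_by_two(VoxelGrid(np.zeros((1, 4, 4)), 125.0))

    def test_decimate_mode_picks_block_corner(self, rng):
        grid = VoxelGrid(rng.normal(size=(4, 4, 4)), 125.0)
        out = reduce_by_two(grid, reduce="decimate")
        np.testing.assert_array_equal(out.data, grid.data[::2, ::2, ::2])

    def test_resample_identity_and_composition(self, rng):
        grid = VoxelGrid(rng.normal(size=(8, 8, 8)).astype(np.float32), 125.0)
        same = resample_to(grid, 125.0)
        np.testing.assert_array_equal(same.data, grid.data)
        np.testing.assert_allclose(
            resample_to(grid, 250.0).data, reduce_by_two(grid).data, rtol=1e-6
        )
        np.testing.assert_allclose(
            resample_to(grid, 500.0).data,
            reduce_by_two(reduce_by_two(grid)).data,
            rtol=1e-6,
        )

    def test_resample_non_integer_factor_errors(self, rng):
        grid = VoxelGrid(rng.normal(size=(4, 4, 4)), 125.0)
        with pytest.raises(ValueError, match="integer multiple"):
            resample_to(grid, 300.0)


class TestMedianFilter:
    def test_isolated_voxel_removed(self):
        data = np.zeros((7, 7, 7))
        data[3, 3, 3] = 1
        out = median_filter_mask(TissueMask(data, 500.0), 1.0)
        assert out.count() == 0

    def test_solid_cube_interior_preserved(self):
        data = np.zeros((12, 12, 12))
        data[2:10, 2:10, 2:10] = 1
        out = median_filter_mask(TissueMask(data, 500.0), 1.0)  # r = 2
        assert (out.data[4:8, 4:8, 4:8] == 1).all()

    def test_sub_voxel_distance_is_identity_with_warning(self):
        data = np.zeros((4, 4, 4))
        data[1, 1, 1] = 1
        mask = TissueMask(data, 500.0)
        with pytest.warns(UserWarning, match="half a voxel"):
            out = median_filter_mask(mask, 0.2)
        np.testing.assert_array_equal(out.data, mask.data)

    @pytest.mark.parametrize("seed", [0, 3])
    @pytest.mark.parametrize("distance_mm", [0.5, 1.0])
    def test_matches_rank_filter_oracle(self, seed, distance_mm):
        # majority-vote implementation vs scipy's true median rank filter
        rng = np.random.default_rng(seed)
        data = (rng.random((10, 10, 10)) < 0.4).astype(np.uint8)
        mask = TissueMask(data, 500.0)
        r = int(round(1000 * distance_mm / 500.0))
        expected = ndimage.median_filter(data, size=2 * r + 1, mode="constant", cval=0)
        out = median_filter_mask(mask, distance_mm)
        np.testing.assert_array_equal(out.data, expected)

    def test_never_increases_convex_solids_and_islands(self, rng):
        # convex solid: random box
        data = np.zeros((14, 14, 14))
        data[3:11, 4:10, 2:12] = 1
        before = int(data.sum())
        out = median_filter_mask(TissueMask(data, 500.0), 1.0)
        assert out.count() <= before
        # scattered single voxels
        scatter = np.zeros((14, 14, 14))
        idx = rng.integers(0, 14, size=(20, 3))
        scatter[idx[:, 0], idx[:, 1], idx[:, 2]] = 1
        out2 = median_filter_mask(TissueMask(scatter, 500.0), 1.0)
        assert out2.count() <= int(scatter.sum())
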