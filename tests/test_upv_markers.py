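"""Imaging-core tests: thresholding, skeletonization, classification, markers.

Expected values come from independent oracles: hand-built voxel figures,
brute-force neighbour recounts, scipy connected-component labelling, and
analytic tube geometry.
"""

import numpy as np
import pytest
from scipy import ndimage

from uterovasc._thinning import neighbor_counts, thin
from uterovasc.upv_markers import (
    KLASS_BIFURCATION,
    KLASS_CROSSING,
    KLASS_END,
    KLASS_VESSEL,
    METRIC_COLUMNS,
    Skeleton,
    VascularVolume,
    classify_skeleton,
    compute_pv,
    extract_upvv,
    run_marker_pipeline,
    skeletonize,
    summarize_upvs,
)
from uterovasc.volume_io import PlacentalMask, VoxelGrid

from conftest import random_blob_volume, random_sparse_volume

STRUCT26 = np.ones((3, 3, 3))


def brute_force_degrees(vol: np.ndarray) -> np.ndarray:
    """Triple-loop 26-neighbour recount; the independent classification oracle."""
    deg = np.zeros(vol.shape, dtype=int)
    nx, ny, nz = vol.shape
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                if not vol[x, y, z]:
                    continue
                c = 0
                for dx in (-1, 0, 1):
                    for dy in (-1, 0, 1):
                        for dz in (-1, 0, 1):
                            if (dx, dy, dz) == (0, 0, 0):
                                continue
                            xx, yy, zz = x + dx, y + dy, z + dz
                            if 0 <= xx < nx and 0 <= yy < ny and 0 <= zz < nz and vol[xx, yy, zz]:
                                c += 1
                deg[x, y, z] = c
    return deg


def make_vv(vol: np.ndarray, spacing: float = 1.0) -> VascularVolume:
    return VascularVolume(voxels=vol, spacing_mm=spacing, threshold=0.0)


class TestComputePV:
    def test_full_mask_arithmetic(self):
        mask = PlacentalMask(include=np.ones((30, 30, 30)))
        assert compute_pv(mask, 0.5) == pytest.approx(27000 * 0.125 / 1000)

    def test_empty_mask_warns_zero(self):
        mask = PlacentalMask(include=np.zeros((5, 5, 5)))
        with pytest.warns(UserWarning, match="empty"):
            assert compute_pv(mask, 0.5) == 0.0

    def test_matches_hand_count(self):
        rng = np.random.default_rng(3)
        inc = rng.random((9, 9, 9)) > 0.6
        n = sum(
            bool(inc[x, y, z]) for x in range(9) for y in range(9) for z in range(9)
        )
        assert compute_pv(PlacentalMask(include=inc), 0.7) == pytest.approx(n * 0.7**3 / 1000)


class TestExtractUPVV:
    def test_threshold_selects_inside_mask(self):
        grid = VoxelGrid(values=np.full((10, 10, 10), 100.0), spacing_mm=1.0)
        mask = PlacentalMask(include=np.ones((10, 10, 10)))
        vv = extract_upvv(grid, mask, 50.0)
        assert vv.upvv_cm3 == pytest.approx(1.0)

    def test_strict_greater_than(self):
        grid = VoxelGrid(values=np.full((10, 10, 10), 100.0), spacing_mm=1.0)
        mask = PlacentalMask(include=np.ones((10, 10, 10)))
        assert extract_upvv(grid, mask, 100.0).upvv_cm3 == 0.0

    def test_shape_mismatch(self):
        grid = VoxelGrid(values=np.zeros((5, 5, 5)))
        mask = PlacentalMask(include=np.ones((5, 5, 6)))
        with pytest.raises(ValueError, match="shape"):
            extract_upvv(grid, mask, 0.0)

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(11)
        grid = VoxelGrid(values=rng.random((12, 12, 12)) * 100)
        mask = PlacentalMask(include=rng.random((12, 12, 12)) > 0.3)
        lo = extract_upvv(grid, mask, 20.0).voxels
        hi = extract_upvv(grid, mask, 60.0).voxels
        assert np.all(hi <= lo)  # larger threshold => subset foreground

    def test_nothing_outside_mask(self):
        rng = np.random.default_rng(12)
        grid = VoxelGrid(values=rng.random((10, 10, 10)) * 100)
        mask = PlacentalMask(include=rng.random((10, 10, 10)) > 0.5)
        vv = extract_upvv(grid, mask, 10.0)
        assert not np.any(vv.voxels & (mask.include == 0))


class TestSkeletonize:
    def test_thin_line_unchanged(self):
        vol = np.zeros((7, 7, 7), dtype=bool)
        vol[1:6, 3, 3] = True
        s = skeletonize(make_vv(vol))
        np.testing.assert_array_equal(s.mask, vol)
        assert (s.peel_depth == 0).all()

    def test_solid_bar_single_centerline(self):
        vol = np.zeros((11, 11, 34), dtype=bool)
        vol[2:9, 2:9, 2:32] = True
        s = skeletonize(make_vv(vol))
        assert s.n_components() == 1
        assert 20 <= s.n_voxels <= 34  # ~30-voxel path along the long axis
        deg = neighbor_counts(s.mask)
        assert deg[s.mask].max() <= 2  # a simple path, no junctions

    def test_solid_ball_degenerate(self):
        x, y, z = np.mgrid[-7:8, -7:8, -7:8]
        ball = x * x + y * y + z * z <= 25
        s = skeletonize(make_vv(ball))
        assert s.n_voxels >= 1
        assert s.n_components() == 1

    def test_empty_input(self):
        s = skeletonize(make_vv(np.zeros((5, 5, 5), dtype=bool)))
        assert s.n_voxels == 0

    def test_deterministic(self):
        rng = np.random.default_rng(5)
        vol = random_blob_volume(rng, (16, 16, 16))
        a = skeletonize(make_vv(vol))
        b = skeletonize(make_vv(vol))
        np.testing.assert_array_equal(a.mask, b.mask)
        np.testing.assert_array_equal(a.peel_depth_map, b.peel_depth_map)

    @pytest.mark.parametrize("seed", range(8))
    def test_component_count_preserved_on_blobs(self, seed):
        rng = np.random.default_rng(seed)
        vol = random_blob_volume(rng, (18, 18, 18))
        vv = make_vv(vol)
        s = skeletonize(vv)
        assert s.n_components() == vv.n_components()
        assert np.all(vol[s.mask])  # skeleton is a subset of the input

    def test_peel_depth_tracks_tube_radius(self):
        # tube of radius 2 voxels: the surviving centerline was exposed to a
        # deletion in the second (final) peel round
        x, y, z = np.mgrid[-4:5, -4:5, 0:20]
        tube = x * x + y * y <= 4
        skel, depth = thin(tube)
        assert skel.sum() > 0
        assert depth[skel].max() == 2


class TestClassify:
    def test_three_collinear(self):
        vol = np.zeros((5, 5, 5), dtype=bool)
        vol[1:4, 2, 2] = True
        s = classify_skeleton(Skeleton(mask=vol, peel_depth_map=np.zeros_like(vol, int),
                                       spacing_mm=1.0))
        assert sorted(s.klass) == [KLASS_END, KLASS_END, KLASS_VESSEL]

    def test_y_junction(self):
        vol = np.zeros((9, 9, 9), dtype=bool)
        vol[4, 4, 4] = True
        vol[4, 4, 1:4] = True        # stem
        vol[4, 5:8, 4] = True        # arm 1
        vol[5:8, 4, 4] = True        # arm 2 (axis-separated from arm 1)
        s = classify_skeleton(Skeleton(mask=vol, peel_depth_map=np.zeros_like(vol, int),
                                       spacing_mm=1.0))
        klass = s.klass
        assert (klass == KLASS_BIFURCATION).sum() == 1
        assert (klass == KLASS_END).sum() == 3

    def test_x_junction(self):
        # four diagonal arms meeting at one voxel (diagonal arms keep the
        # first arm voxels mutually non-adjacent, so the junction is clean)
        vol = np.zeros((9, 9, 9), dtype=bool)
        vol[4, 4, 4] = True
        for sx, sy in ((1, 1), (1, -1), (-1, 1), (-1, -1)):
            for k in (1, 2, 3):
                vol[4 + sx * k, 4 + sy * k, 4] = True
        s = classify_skeleton(Skeleton(mask=vol, peel_depth_map=np.zeros_like(vol, int),
                                       spacing_mm=1.0))
        assert (s.klass == KLASS_CROSSING).sum() == 1
        assert (s.klass == KLASS_END).sum() == 4

    def test_isolated_voxel_counts_as_end(self):
        vol = np.zeros((3, 3, 3), dtype=bool)
        vol[1, 1, 1] = True
        s = classify_skeleton(Skeleton(mask=vol, peel_depth_map=np.zeros_like(vol, int),
                                       spacing_mm=1.0))
        assert list(s.klass) == [KLASS_END]

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        vol = random_sparse_volume(rng, (14, 14, 14))
        s = classify_skeleton(Skeleton(mask=vol, peel_depth_map=np.zeros(vol.shape, int),
                                       spacing_mm=1.0))
        deg = brute_force_degrees(vol)
        expected = np.select(
            [deg <= 1, deg == 2, deg == 3], [KLASS_END, KLASS_VESSEL, KLASS_BIFURCATION],
            default=KLASS_CROSSING,
        )
        np.testing.assert_array_equal(s.klass_map[vol], expected[vol])

    @pytest.mark.parametrize("seed", range(5))
    def test_class_partition_exhaustive(self, seed):
        rng = np.random.default_rng(100 + seed)
        vol = random_blob_volume(rng, (16, 16, 16))
        s = classify_skeleton(skeletonize(make_vv(vol)))
        assert (s.klass > 0).all()
        assert len(s.klass) == s.n_voxels


class TestSummarize:
    def _line_skeleton(self, n=100, spacing=0.6):
        vol = np.zeros((n + 2, 3, 3), dtype=bool)
        vol[1:n + 1, 1, 1] = True
        s = classify_skeleton(Skeleton(mask=vol, peel_depth_map=np.zeros(vol.shape, int),
                                       spacing_mm=spacing))
        vv = VascularVolume(voxels=vol, spacing_mm=spacing, threshold=0.0)
        return s, vv

    def test_total_length_formula(self):
        s, vv = self._line_skeleton(n=100, spacing=0.6)
        m = summarize_upvs(s, vv, pv_cm3=1.0)
        assert m.total_length_mm == pytest.approx(60.0)

    def test_density_formula(self):
        # two separated lines -> 4 end points; fabricate upvv of 0.2 cm^3
        vol = np.zeros((12, 5, 5), dtype=bool)
        vol[1:5, 1, 1] = True
        vol[7:11, 3, 3] = True
        spacing = (0.2 * 1000 / vol.sum()) ** (1 / 3)
        vv = VascularVolume(voxels=vol, spacing_mm=spacing, threshold=0.0)
        s = classify_skeleton(Skeleton(mask=vol, peel_depth_map=np.zeros(vol.shape, int),
                                       spacing_mm=spacing))
        m = summarize_upvs(s, vv, pv_cm3=1.0)
        assert m.end_points == 4
        assert m.density_end == pytest.approx(4 / vv.upvv_cm3)

    def test_zero_peel_depth_zero_thickness(self):
        s, vv = self._line_skeleton()
        m = summarize_upvs(s, vv, pv_cm3=1.0)
        assert m.avg_thickness_mm == 0.0
        # optional half-voxel offset for one-voxel-wide vessels
        m2 = summarize_upvs(s, vv, pv_cm3=1.0, thickness_offset_voxels=0.5)
        assert m2.avg_thickness_mm == pytest.approx(0.5 * s.spacing_mm)

    def test_inconsistent_zero_upvv(self):
        vol = np.zeros((5, 3, 3), dtype=bool)
        vol[1:4, 1, 1] = True
        s = classify_skeleton(Skeleton(mask=vol, peel_depth_map=np.zeros(vol.shape, int),
                                       spacing_mm=1.0))
        empty_vv = VascularVolume(voxels=np.zeros_like(vol), spacing_mm=1.0, threshold=0.0)
        with pytest.raises(ValueError, match="inconsistent"):
            summarize_upvs(s, empty_vv, pv_cm3=1.0)

    def test_partition_sums_to_skeleton_size(self):
        rng = np.random.default_rng(42)
        vol = random_blob_volume(rng, (20, 20, 20))
        vv = make_vv(vol)
        s = classify_skeleton(skeletonize(vv))
        m = summarize_upvs(s, vv, pv_cm3=compute_pv(PlacentalMask(include=vol), 1.0))
        total = m.end_points + m.bifurcation_points + m.crossing_points + m.vessel_points
        assert total == s.n_voxels
        assert m.total_length_mm == pytest.approx(s.n_voxels * 1.0)


class TestPipeline:
    def test_empty_grid_all_zero(self):
        grid = VoxelGrid(values=np.zeros((8, 8, 8)), spacing_mm=0.5)
        mask = PlacentalMask(include=np.ones((8, 8, 8)))
        m, prov = run_marker_pipeline(grid, mask, threshold=0.0)
        assert m.upvv_cm3 == 0.0
        assert m.end_points == m.bifurcation_points == m.vessel_points == 0
        assert m.total_length_mm == 0.0
        assert prov["foreground_voxels"] == 0

    def test_metric_columns_complete(self):
        grid = VoxelGrid(values=np.zeros((6, 6, 6)), spacing_mm=0.5)
        mask = PlacentalMask(include=np.ones((6, 6, 6)))
        m, _ = run_marker_pipeline(grid, mask, threshold=0.0)
        assert list(m.to_frame().columns) == METRIC_COLUMNS

    def test_single_tube_thickness_near_radius(self):
        # radius 1.0 mm at 0.5 mm spacing: mean peel depth ~2 rounds -> ~1 mm
        from uterovasc.synth_vasculature import PhantomConfig, generate_tree, rasterize_tree

        cfg = PhantomConfig(generations=0, trunk_length_mm=20, trunk_radius_mm=1.0, seed=0)
        grid, mask = rasterize_tree(generate_tree(cfg), 0.5, cfg)
        m, _ = run_marker_pipeline(grid, mask, threshold=0.0)
        assert abs(m.avg_thickness_mm - 1.0) <= 0.5  # within one voxel length
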