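"""Point-cloud-to-CHM pipeline: each stage against brute-force oracles."""

import numpy as np
import pytest
import shapely
from hypothesis import given, settings, strategies as st

import forestacd as fa
from forestacd.cloud import merge_clouds


def cloud_of(*points):
    return fa.PointCloud(np.array(points, dtype=float))


class TestTileCloud:
    def test_square_cloud_four_tiles(self):
        rng = np.random.default_rng(0)
        pts = np.column_stack([rng.uniform(0, 100, 500), rng.uniform(0, 100, 500), np.zeros(500)])
        tiles = fa.tile_cloud(fa.PointCloud(pts), 50.0)
        assert len(tiles) == 4
        assert sum(len(t) for t in tiles) == 500

    def test_point_count_conserved_and_disjoint(self):
        rng = np.random.default_rng(1)
        pts = np.column_stack([rng.uniform(0, 73, 1000), rng.uniform(0, 41, 1000), rng.normal(0, 1, 1000)])
        cloud = fa.PointCloud(pts)
        tiles = fa.tile_cloud(cloud, 20.0)
        merged = merge_clouds(tiles)
        assert len(merged) == len(cloud)
        # every original point appears exactly once
        assert np.array_equal(
            np.sort(merged.xyz.view([("", float)] * 3), axis=0),
            np.sort(cloud.xyz.view([("", float)] * 3), axis=0),
        )

    def test_oversized_tile_returns_input(self):
        cloud = cloud_of([0, 0, 1], [5, 5, 2])
        tiles = fa.tile_cloud(cloud, 1000.0)
        assert len(tiles) == 1
        assert np.array_equal(tiles[0].xyz, cloud.xyz)

    def test_empty_cloud(self):
        assert fa.tile_cloud(fa.PointCloud(np.empty((0, 3))), 10.0) == []


class TestRemoveNoise:
    def brute_force_noise(self, xyz, cell, threshold):
        """Independent O(n^2) neighborhood count."""
        idx = np.floor(xyz / cell).astype(int)
        noise = []
        for i in range(len(xyz)):
            same = np.all(np.abs(idx - idx[i]) <= 1, axis=1)
            noise.append(same.sum() - 1 <= threshold)
        return np.array(noise)

    def test_isolated_high_point_removed(self):
        rng = np.random.default_rng(2)
        sheet = np.column_stack([rng.uniform(0, 10, 500), rng.uniform(0, 10, 500), np.zeros(500)])
        outlier = np.array([[5.0, 5.0, 50.0]])
        cloud = fa.PointCloud(np.vstack([sheet, outlier]))
        cleaned = fa.remove_noise(cloud, cell=1.0, max_neighbors_for_noise=2)
        assert len(cleaned) == 500
        assert cleaned.z.max() < 1.0

    def test_dense_cloud_untouched(self):
        rng = np.random.default_rng(3)
        pts = np.column_stack([rng.uniform(0, 5, 2000), rng.uniform(0, 5, 2000), rng.uniform(0, 1, 2000)])
        cloud = fa.PointCloud(pts)
        assert len(fa.remove_noise(cloud, 1.0, 2)) == 2000

    def test_empty_cloud(self):
        cloud = fa.PointCloud(np.empty((0, 3)))
        assert len(fa.remove_noise(cloud, 1.0, 2)) == 0

    def test_matches_brute_force_on_random_cloud(self):
        rng = np.random.default_rng(4)
        xyz = rng.uniform(0, 8, size=(300, 3))
        expected_noise = self.brute_force_noise(xyz, cell=1.0, threshold=1)
        cleaned = fa.remove_noise(fa.PointCloud(xyz.copy()), 1.0, 1)
        assert len(cleaned) == (~expected_noise).sum()
        assert np.array_equal(np.sort(cleaned.z), np.sort(xyz[~expected_noise, 2]))


class TestClassifyGround:
    def test_sheet_plus_tree_membership(self):
        rng = np.random.default_rng(5)
        n = 2000
        ground = np.column_stack([rng.uniform(0, 30, n), rng.uniform(0, 30, n), np.full(n, 10.0)])
        tree = np.column_stack(
            [rng.uniform(14, 16, 200), rng.uniform(14, 16, 200), rng.uniform(15, 20, 200)]
        )
        cloud = fa.PointCloud(np.vstack([ground, tree]))
        labelled = fa.classify_ground(cloud, grid=2.0, max_ground_offset=0.5)
        assert np.all(labelled.classification[:n] == fa.GROUND)
        assert np.all(labelled.classification[n:] == fa.NON_GROUND)

    def test_pure_ground_sheet_all_ground(self):
        rng = np.random.default_rng(6)
        pts = np.column_stack([rng.uniform(0, 20, 500), rng.uniform(0, 20, 500), np.full(500, 3.0)])
        labelled = fa.classify_ground(fa.PointCloud(pts), 2.0, 0.3)
        assert np.all(labelled.classification == fa.GROUND)

    def test_degenerate_identical_points(self):
        cloud = fa.PointCloud(np.tile([[1.0, 2.0, 3.0]], (10, 1)))
        labelled = fa.classify_ground(cloud, 2.0, 0.3)
        assert np.all(labelled.classification == fa.GROUND)


class TestThinExtremes:
    def test_keep_highest(self):
        cloud = cloud_of([0.51, 0.52, 1.0], [0.52, 0.51, 5.0])
        thinned = fa.thin_extremes(cloud, grid=1.0, mode="highest")
        assert len(thinned) == 1 and thinned.z[0] == 5.0

    def test_keep_lowest(self):
        cloud = cloud_of([0.51, 0.52, 1.0], [0.52, 0.51, 5.0])
        thinned = fa.thin_extremes(cloud, grid=1.0, mode="lowest")
        assert len(thinned) == 1 and thinned.z[0] == 1.0

    def test_one_point_per_occupied_cell(self):
        rng = np.random.default_rng(7)
        xyz = np.column_stack([rng.uniform(0, 4, 500), rng.uniform(0, 4, 500), rng.normal(size=500)])
        thinned = fa.thin_extremes(fa.PointCloud(xyz), grid=0.5, mode="highest")
        cells = set(zip(*np.floor(xyz[:, :2] / 0.5).astype(int).T))
        assert len(thinned) == len(cells)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_thinning_never_grows_cloud(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 80))
        xyz = rng.uniform(0, 3, size=(n, 3))
        thinned = fa.thin_extremes(fa.PointCloud(xyz), grid=0.7, mode="lowest")
        assert 1 <= len(thinned) <= n
        assert set(thinned.z) <= set(xyz[:, 2])


class TestRasterize:
    def test_identity_one_point_per_cell(self):
        cloud = cloud_of([0.5, 0.5, 2.0], [1.5, 0.5, 3.0], [0.5, 1.5, 4.0], [1.5, 1.5, 5.0])
        raster = fa.rasterize(cloud, 1.0, "max", bounds=(0, 0, 2, 2), fill_max_distance=0)
        assert np.array_equal(raster.values, [[4.0, 5.0], [2.0, 3.0]])

    def test_mean_reducer(self):
        cloud = cloud_of([0.2, 0.2, 2.0], [0.8, 0.8, 4.0])
        raster = fa.rasterize(cloud, 1.0, "mean", bounds=(0, 0, 1, 1))
        assert raster.values[0, 0] == 3.0

    def test_empty_with_bounds_all_nodata(self):
        raster = fa.rasterize(fa.PointCloud(np.empty((0, 3))), 1.0, "max", bounds=(0, 0, 3, 2))
        assert raster.values.shape == (2, 3)
        assert np.all(np.isnan(raster.values))

    def test_paraboloid_apex_recovered(self):
        tree = fa.TreeTruth(x=5, y=5, height=8.0, crown_radius=2.5)
        scene = fa.SceneSpec(extent=(0, 0, 10, 10), ground_elevation=0.0, trees=[tree])
        cloud = fa.render_point_cloud(scene, 400.0, 1.0, 0.0, seed=8)
        raster = fa.rasterize(cloud, 0.1, "max")
        r, c = np.unravel_index(np.nanargmax(raster.values), raster.values.shape)
        x, y = raster.cell_center(r, c)
        assert abs(x - 5) <= 0.15 and abs(y - 5) <= 0.15
        assert raster.values[r, c] == pytest.approx(8.0, abs=0.05)

    def test_monotone_in_point_height(self):
        """Raising one point's z never lowers its cell's DSM value."""
        rng = np.random.default_rng(9)
        xyz = np.column_stack([rng.uniform(0, 5, 100), rng.uniform(0, 5, 100), rng.normal(size=100)])
        base = fa.rasterize(fa.PointCloud(xyz.copy()), 1.0, "max", bounds=(0, 0, 5, 5))
        xyz[0, 2] += 3.0
        bumped = fa.rasterize(fa.PointCloud(xyz), 1.0, "max", bounds=(0, 0, 5, 5))
        finite = np.isfinite(base.values)
        assert np.all(bumped.values[finite] >= base.values[finite])


class TestFlatDem:
    @staticmethod
    def sort_oracle(values, pct):
        """Independent linear-interpolation percentile by explicit sorting."""
        v = np.sort(np.asarray(values, dtype=float))
        pos = pct / 100.0 * (len(v) - 1)
        lo = int(np.floor(pos))
        hi = min(lo + 1, len(v) - 1)
        return v[lo] + (pos - lo) * (v[hi] - v[lo])

    def test_constant_dem(self):
        dem = fa.GridRaster((0, 0), 1.0, np.full((4, 4), 10.0))
        ground, check = fa.flat_dem(dem, 15.0)
        assert ground == 10.0 and check.passed

    def test_percentile_matches_sort_oracle_1_to_100(self):
        dem = fa.GridRaster((0, 0), 1.0, np.arange(1.0, 101.0).reshape(10, 10))
        ground, _ = fa.flat_dem(dem, 15.0)
        assert ground == pytest.approx(self.sort_oracle(np.arange(1.0, 101.0), 15.0))
        assert ground == pytest.approx(15.85)

    def test_contaminated_dem_peak_detected(self):
        """80% floodplain cells at 5 m + 20% spurious canopy-height cells."""
        rng = np.random.default_rng(10)
        vals = np.concatenate([np.full(800, 5.0), rng.uniform(15, 25, 200)])
        rng.shuffle(vals)
        dem = fa.GridRaster((0, 0), 1.0, vals.reshape(25, 40))
        ground, check = fa.flat_dem(dem, 15.0)
        assert ground == 5.0
        assert check.passed
        assert check.modal_bin[0] <= 5.0 <= check.modal_bin[1]

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_percentile_matches_oracle_random_rasters(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 400))
        vals = rng.normal(50, 10, n)
        pct = float(rng.uniform(0, 100))
        dem = fa.GridRaster((0, 0), 1.0, vals.reshape(1, -1))
        ground, _ = fa.flat_dem(dem, pct)
        assert ground == pytest.approx(self.sort_oracle(vals, pct), rel=1e-12)

    def test_all_nodata_rejected(self):
        dem = fa.GridRaster((0, 0), 1.0, np.full((3, 3), np.nan))
        with pytest.raises(ValueError):
            fa.flat_dem(dem)


class TestMakeChm:
    def test_subtraction_and_clamp(self):
        dsm = fa.GridRaster((0, 0), 1.0, np.array([[12.0, 9.5], [np.nan, 10.0]]))
        chm = fa.make_chm(dsm, 10.0, clamp_negative=True)
        assert chm.values[0, 0] == 2.0
        assert chm.values[0, 1] == 0.0
        assert np.isnan(chm.values[1, 0])
        unclamped = fa.make_chm(dsm, 10.0, clamp_negative=False)
        assert unclamped.values[0, 1] == -0.5

    def test_zero_canopy_end_to_end_exact(self):
        """A bare noise-free floodplain normalizes to an identically-zero CHM."""
        scene = fa.SceneSpec(extent=(0, 0, 30, 30), ground_elevation=12.0)
        cloud = fa.render_point_cloud(scene, 50.0, 1.0, 0.0, seed=13)
        result = fa.build_chm(cloud, clamp_negative=False)
        assert result.ground_elevation == pytest.approx(12.0, abs=1e-9)
        vals = result.chm.finite_values()
        assert np.abs(vals).max() == pytest.approx(0.0, abs=1e-9)

    def test_translation_equivariance(self, sparse_scene):
        """Shifting all z by a constant shifts the ground estimate and leaves
        the CHM unchanged."""
        cloud = fa.render_point_cloud(sparse_scene, 20.0, 1.0, 0.02, seed=14)
        shifted = fa.PointCloud(cloud.xyz + np.array([0.0, 0.0, 7.5]))
        a = fa.build_chm(cloud)
        b = fa.build_chm(shifted)
        assert b.ground_elevation == pytest.approx(a.ground_elevation + 7.5, abs=1e-9)
        assert np.allclose(a.chm.values, b.chm.values, atol=1e-9, equal_nan=True)


class TestPlotCanopyStats:
    def test_constant_chm(self):
        chm = fa.GridRaster((0, 0), 1.0, np.full((10, 10), 4.0))
        stats = fa.plot_canopy_stats(chm, shapely.box(2, 2, 8, 8))
        assert stats.mean_tch == 4.0 and stats.sd == 0.0

    def test_half_raster_selection(self):
        values = np.hstack([np.full((4, 2), 2.0), np.full((4, 2), 6.0)])
        chm = fa.GridRaster((0, 0), 1.0, values)
        stats = fa.plot_canopy_stats(chm, shapely.box(0, 0, 2, 4))  # left half only
        assert stats.mean_tch == 2.0
        assert stats.n_cells == 8

    def test_no_cells_inside_rejected(self):
        chm = fa.GridRaster((0, 0), 1.0, np.full((5, 5), 1.0))
        with pytest.raises(ValueError):
            fa.plot_canopy_stats(chm, shapely.box(100, 100, 110, 110))

    def test_mean_tch_recovers_analytic_truth(self, sparse_scene, noise_free_chm):
        xmin, ymin, xmax, ymax = sparse_scene.extent
        stats = fa.plot_canopy_stats(noise_free_chm.chm, shapely.box(xmin, ymin, xmax, ymax))
        assert stats.mean_tch == pytest.approx(sparse_scene.true_mean_tch(0.1), abs=0.03)
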