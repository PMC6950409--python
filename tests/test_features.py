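"""Buffer kernels, focal statistics, distances and point extraction."""

import numpy as np
import pytest

from lurkit import (
    FeatureRaster,
    GridSpec,
    build_feature_stack,
    circular_kernel,
    extract_at,
    focal_at_points,
    focal_stat,
    nearest_distance,
    parse_feature_name,
)
from lurkit.features import BufferLadder, nearest_distance_raster
from shapely import LineString, Point


def brute_kernel_count(radius, cell):
    """Independent brute-force enumeration of kernel membership."""
    reach = int(radius // cell)
    count = 0
    for di in range(-reach, reach + 1):
        for dj in range(-reach, reach + 1):
            if np.hypot(di * cell, dj * cell) <= radius:
                count += 1
    return count


class TestCircularKernel:
    def test_radius_equal_cell_gives_plus_shape(self):
        offs = {tuple(o) for o in circular_kernel(50, 50)}
        assert offs == {(0, 0), (1, 0), (-1, 0), (0, 1), (0, -1)}

    def test_tiny_radius_keeps_only_center(self):
        offs = circular_kernel(10, 50)
        assert offs.tolist() == [[0, 0]]

    @pytest.mark.parametrize("radius", [250, 450, 1500, 5000])
    def test_count_matches_brute_force(self, radius):
        assert len(circular_kernel(radius, 50)) == brute_kernel_count(radius, 50)

    def test_symmetry_under_rotation_and_reflection(self):
        offs = {tuple(o) for o in circular_kernel(730, 50)}
        assert offs == {(-i, j) for i, j in offs}
        assert offs == {(j, i) for i, j in offs}

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            circular_kernel(0, 50)
        with pytest.raises(ValueError):
            circular_kernel(100, -1)


def brute_focal(values, radius, cell, stat):
    """Per-cell windowed enumeration oracle (vectorized over the window)."""
    n, m = values.shape
    reach = int(radius // cell)
    d = np.arange(-reach, reach + 1)
    inside = (d[:, None] ** 2 + d[None, :] ** 2) * cell * cell <= radius * radius
    out = np.empty((n, m))
    for i in range(n):
        for j in range(m):
            r0, r1 = max(i - reach, 0), min(i + reach + 1, n)
            c0, c1 = max(j - reach, 0), min(j + reach + 1, m)
            msk = inside[r0 - (i - reach): r1 - (i - reach),
                         c0 - (j - reach): c1 - (j - reach)]
            win = values[r0:r1, c0:c1][msk]
            out[i, j] = win.sum() if stat == "sum" else win.mean()
    return out


class TestFocalStat:
    def test_constant_raster_mean_is_constant(self, small_grid):
        r = FeatureRaster(small_grid, "c", np.full(small_grid.shape, 3.7))
        out = focal_stat(r, 450, "mean")
        assert np.allclose(out.values, 3.7)

    def test_three_by_three_ones_sum_at_center(self):
        g = GridSpec(n_rows=3, n_cols=3, cell_size=50.0)
        r = FeatureRaster(g, "ones", np.ones((3, 3)))
        out = focal_stat(r, 50, "sum")
        assert out.values[1, 1] == 5

    @pytest.mark.parametrize("radius", [250, 450, 1000])
    def test_matches_brute_force_oracle(self, radius, rng):
        g = GridSpec(n_rows=60, n_cols=60, cell_size=50.0)
        vals = rng.integers(0, 100, g.shape).astype(float)
        r = FeatureRaster(g, "x", vals)
        assert np.array_equal(focal_stat(r, radius, "sum").values,
                              brute_focal(vals, radius, 50, "sum"))
        assert np.array_equal(focal_stat(r, radius, "mean").values,
                              brute_focal(vals, radius, 50, "mean"))

    def test_missing_cells_excluded_and_all_missing_is_nan(self):
        g = GridSpec(n_rows=5, n_cols=5, cell_size=50.0)
        vals = np.ones((5, 5))
        vals[2, 2] = np.nan
        out = focal_stat(FeatureRaster(g, "x", vals), 50, "sum")
        assert out.values[2, 2] == 4  # center missing, 4 neighbors remain
        allnan = FeatureRaster(g, "x", np.full((5, 5), np.nan))
        assert np.isnan(focal_stat(allnan, 50, "mean").values).all()

    def test_focal_sum_monotone_in_radius_for_ones_mask(self):
        g = GridSpec(n_rows=30, n_cols=30, cell_size=50.0)
        r = FeatureRaster(g, "ones", np.ones(g.shape))
        prev = None
        for radius in (250, 500, 750, 1000, 1500):
            cur = focal_stat(r, radius, "sum").values
            if prev is not None:
                assert (cur >= prev).all()
            prev = cur

    def test_translation_equivariance_in_interior(self, rng):
        g = GridSpec(n_rows=40, n_cols=40, cell_size=50.0)
        vals = rng.normal(size=g.shape)
        radius, k = 250, 3
        reach = int(radius // 50)
        out = focal_stat(FeatureRaster(g, "x", vals), radius, "sum").values
        out_shift = focal_stat(
            FeatureRaster(g, "x", np.roll(vals, k, axis=0)), radius, "sum").values
        m = reach + k
        assert np.allclose(np.roll(out, k, axis=0)[m:-m, m:-m],
                           out_shift[m:-m, m:-m])

    def test_focal_at_points_agrees_with_full_raster(self, rng):
        g = GridSpec(n_rows=25, n_cols=25, cell_size=50.0)
        vals = rng.normal(size=g.shape)
        full = focal_stat(FeatureRaster(g, "x", vals), 450, "mean").values
        pts = [(330.0, 610.0), (25.0, 25.0), (1200.0, 90.0)]
        got = focal_at_points(vals, g, 450, pts, "mean")
        rows, cols = g.index_of([p[0] for p in pts], [p[1] for p in pts])
        assert np.allclose(got, full[rows, cols])


class TestNearestDistance:
    def test_query_on_feature_is_zero(self):
        assert nearest_distance([(10.0, 20.0)], (10.0, 20.0)) == 0.0

    def test_three_four_five_triangle(self):
        assert nearest_distance([(0, 0), (100, 0)], (30, 40)) == pytest.approx(50.0)

    def test_point_to_segment(self):
        line = LineString([(0, 0), (100, 0)])
        assert nearest_distance([line], (50, 30)) == pytest.approx(30.0)

    def test_random_points_match_all_pairs_minimum(self, rng):
        feats = [tuple(p) for p in rng.uniform(0, 1000, (50, 2))]
        for q in rng.uniform(0, 1000, (20, 2)):
            expected = min(np.hypot(q[0] - x, q[1] - y) for x, y in feats)
            assert nearest_distance(feats, tuple(q)) == pytest.approx(expected)

    def test_empty_feature_set_raises(self):
        with pytest.raises(ValueError):
            nearest_distance([], (0, 0))

    def test_raster_matches_pointwise(self, rng, small_grid):
        feats = [Point(123.0, 456.0), Point(700.0, 900.0)]
        rast = nearest_distance_raster(feats, small_grid, "Airport")
        X, Y = small_grid.cell_centers()
        i, j = 7, 13
        assert rast.values[i, j] == pytest.approx(
            nearest_distance(feats, (X[i, j], Y[i, j])))
        assert rast.name == "Airport_nearest"


class TestExtractAt:
    def test_cell_center_and_edge_convention(self, small_grid):
        vals = np.arange(400, dtype=float).reshape(20, 20)
        r = FeatureRaster(small_grid, "x", vals)
        # center of cell (2, 3)
        assert extract_at(r, [(175.0, 125.0)])[0] == vals[2, 3]
        # a point on the shared edge x=150 belongs to the right-hand cell
        assert extract_at(r, [(150.0, 125.0)])[0] == vals[2, 3]

    def test_out_of_bounds_names_station(self, small_grid):
        r = FeatureRaster(small_grid, "x", np.zeros(small_grid.shape))
        with pytest.raises(ValueError, match="monitor-07"):
            extract_at(r, [(2000.0, 0.0)], labels=["monitor-07"])

    def test_matches_floor_index_arithmetic(self, small_grid, rng):
        vals = rng.normal(size=small_grid.shape)
        r = FeatureRaster(small_grid, "x", vals)
        pts = rng.uniform(0, 999.9, (10, 2))
        got = extract_at(r, pts)
        for (x, y), v in zip(pts, got):
            assert v == vals[int(y // 50), int(x // 50)]


class TestFeatureStack:
    def test_raster_count_and_names(self, rng):
        g = GridSpec(n_rows=30, n_cols=30, cell_size=50.0)
        codes = rng.integers(0, 3, g.shape).astype(float)
        lu = FeatureRaster(g, "landuse", codes)
        ndvi = FeatureRaster(g, "ndvi", rng.uniform(0, 0.5, g.shape))
        stack = build_feature_stack(
            landuse=lu, class_map={1: "Residential", 2: "Forest"},
            ndvi=ndvi, vectors={"Airport": [Point(500, 500)]},
            ladder=(250, 500, 750, 1000))
        # 2 classes x 4 radii + NDVI x 4 + 1 distance = 13
        assert len(stack) == 13
        assert "Residential_250m" in stack and "NDVI_1000m" in stack
        assert "Airport_nearest" in stack
        for name in stack:
            parsed = parse_feature_name(name)
            assert parsed["kind"] in ("buffered", "distance")
            assert np.isfinite(stack[name].values).all()

    def test_class_area_units(self, rng):
        g = GridSpec(n_rows=10, n_cols=10, cell_size=50.0)
        lu = FeatureRaster(g, "landuse", np.ones(g.shape))
        stack = build_feature_stack(landuse=lu, class_map={1: "Residential"},
                                    ladder=(50,))
        # plus-shaped kernel of 5 cells, all residential: 5 * 2500 m2 = 1.25 ha
        assert stack["Residential_50m"].values[5, 5] == pytest.approx(1.25)

    def test_ladder_validation(self):
        with pytest.raises(ValueError):
            BufferLadder((500, 250))
        with pytest.raises(ValueError):
            BufferLadder(())


def test_parse_feature_name_round_trip():
    assert parse_feature_name("Residential_4250m") == {
        "layer": "Residential", "kind": "buffered", "radius": 4250.0}
    assert parse_feature_name("Airport_nearest")["kind"] == "distance"
    assert parse_feature_name("temperature")["kind"] == "plain"
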