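import numpy as np
import pytest
from shapely.geometry import Polygon

from dogedge import (
    GridRaster,
    PointSet,
    PolygonSet,
    extract_values_at_points,
    mask_area_km2,
    rasterize_polygons,
)
from dogedge.geodata import (
    read_ascii_grid,
    read_geotiff,
    write_ascii_grid,
    write_geotiff,
)


def square(x0, y0, x1, y1):
    return Polygon([(x0, y0), (x1, y0), (x1, y1), (x0, y1)])


def ray_cast_inside(px, py, poly: Polygon) -> bool:
    """Independent even-odd point-in-polygon check (boundary counts inside)."""
    if poly.exterior.distance(__import__("shapely").geometry.Point(px, py)) == 0:
        return True
    coords = list(poly.exterior.coords)
    inside = False
    for (x1, y1), (x2, y2) in zip(coords[:-1], coords[1:]):
        if (y1 > py) != (y2 > py):
            x_int = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
            if px < x_int:
                inside = not inside
    return inside


class TestRasterizePolygons:
    def test_full_coverage(self, flat_dem):
        polys = PolygonSet([square(-10, -10, 200, 200)])
        mask = rasterize_polygons(polys, flat_dem)
        assert (mask.values == 1).all()

    def test_empty_polygon_list(self, flat_dem):
        mask = rasterize_polygons(PolygonSet([]), flat_dem)
        assert (mask.values == 0).all()

    def test_small_square_against_ray_casting(self):
        template = GridRaster(np.zeros((10, 10)), 0.0, 100.0, 10.0, "elevation_m")
        # covers the centers of rows 2-3, cols 4-5 exactly
        poly = square(42.0, 62.0, 58.0, 78.0)
        mask = rasterize_polygons(PolygonSet([poly]), template)
        assert mask.values.sum() == 4
        for r in range(10):
            for c in range(10):
                cx, cy = template.cell_center(r, c)
                assert mask.values[r, c] == float(ray_cast_inside(cx, cy, poly))

    def test_nonfinite_vertex_rejected(self):
        with pytest.raises(ValueError):
            PolygonSet([Polygon([(0, 0), (np.nan, 1), (1, 1), (1, 0)])])


class TestMaskArea:
    def test_ten_cells_at_100m(self):
        vals = np.zeros((5, 5))
        vals.ravel()[:10] = 1
        mask = GridRaster(vals, 0, 500, 100.0, "mask")
        assert mask_area_km2(mask) == pytest.approx(0.1)

    def test_all_zero(self):
        assert mask_area_km2(GridRaster(np.zeros((3, 3)), 0, 300, 100.0, "mask")) == 0.0

    def test_random_mask_against_double_loop(self):
        rng = np.random.default_rng(7)
        vals = rng.integers(0, 2, size=(50, 50)).astype(float)
        vals[rng.random((50, 50)) < 0.1] = np.nan
        mask = GridRaster(vals, 0, 50 * 25.0, 25.0, "mask")
        count = 0
        for r in range(50):
            for c in range(50):
                if vals[r, c] == 1:
                    count += 1
        assert mask_area_km2(mask) == pytest.approx(count * 25.0**2 / 1e6)

    def test_kind_contract(self, flat_dem):
        with pytest.raises(TypeError):
            mask_area_km2(flat_dem)


class TestExtractValues:
    def test_point_at_cell_center(self):
        vals = np.arange(25.0).reshape(5, 5)
        ras = GridRaster(vals, 0, 150, 30.0, "elevation_m")
        for r, c in [(0, 0), (2, 3), (4, 4)]:
            cx, cy = ras.cell_center(r, c)
            got = extract_values_at_points(ras, PointSet([(cx, cy)]))
            assert got[0] == vals[r, c]

    def test_empty_pointset(self, flat_dem):
        assert extract_values_at_points(flat_dem, PointSet([])).size == 0

    def test_random_points_against_nearest_center_scan(self):
        rng = np.random.default_rng(11)
        vals = rng.random((8, 9))
        ras = GridRaster(vals, 10.0, 500.0, 40.0, "elevation_m")
        pts = np.column_stack([
            rng.uniform(10, 10 + 9 * 40, 20),
            rng.uniform(500 - 8 * 40, 500, 20),
        ])
        got = extract_values_at_points(ras, PointSet(pts))
        for k, (px, py) in enumerate(pts):
            best = min(
                ((r, c) for r in range(8) for c in range(9)),
                key=lambda rc: (px - ras.cell_center(*rc)[0]) ** 2
                + (py - ras.cell_center(*rc)[1]) ** 2,
            )
            assert got[k] == vals[best]

    def test_outside_extent_reports_indices(self, flat_dem):
        pts = PointSet([(75.0, 75.0), (1e6, 0.0)])
        with pytest.raises(ValueError, match=r"\[1\]"):
            extract_values_at_points(flat_dem, pts)

    def test_nodata_propagates(self):
        vals = np.zeros((2, 2))
        vals[0, 0] = np.nan
        ras = GridRaster(vals, 0, 200, 100.0, "elevation_m")
        got = extract_values_at_points(ras, PointSet([ras.cell_center(0, 0)]))
        assert np.isnan(got[0])

    def test_permutation_equivariance(self, flat_dem):
        rng = np.random.default_rng(3)
        ras = flat_dem.like(rng.random((5, 5)), "elevation_m")
        pts = np.column_stack([rng.uniform(0, 150, 15), rng.uniform(0, 150, 15)])
        perm = rng.permutation(15)
        a = extract_values_at_points(ras, PointSet(pts))
        b = extract_values_at_points(ras, PointSet(pts[perm]))
        assert np.array_equal(a[perm], b)


def test_area_error_shrinks_with_resolution():
    """Rasterized area of a 3 km square converges to the true 9 km²."""
    poly = PolygonSet([square(155.0, 155.0, 3155.0, 3155.0)])
    errors = []
    for cs in (100.0, 50.0, 25.0):
        n = int(4000 / cs)
        template = GridRaster(np.zeros((n, n)), 0.0, 4000.0, cs, "elevation_m")
        errors.append(abs(mask_area_km2(rasterize_polygons(poly, template)) - 9.0))
    assert errors[0] >= errors[1] >= errors[2]


@pytest.mark.parametrize("fmt", ["ascii", "geotiff"])
@pytest.mark.parametrize("kind", ["elevation_m", "mask"])
def test_raster_roundtrip(tmp_path, fmt, kind):
    rng = np.random.default_rng(5)
    if kind == "mask":
        vals = rng.integers(0, 2, (7, 6)).astype(float)
    else:
        vals = rng.normal(1000, 300, (7, 6))
    vals[0, 1] = np.nan
    ras = GridRaster(vals, 12345.5, 98765.25, 30.0, kind)
    path = tmp_path / ("r.asc" if fmt == "ascii" else "r.tif")
    if fmt == "ascii":
        write_ascii_grid(ras, path)
        back = read_ascii_grid(path, kind)
    else:
        write_geotiff(ras, path)
        back = read_geotiff(path)
    assert back.origin_x == ras.origin_x
    assert back.origin_y == ras.origin_y
    assert back.cell_size == ras.cell_size
    assert back.kind == kind
    assert np.array_equal(np.isnan(back.values), np.isnan(ras.values))
    assert np.allclose(back.values[~np.isnan(vals)], vals[~np.isnan(vals)], rtol=0, atol=0)


def test_alignment_required_for_combination():
    from dogedge import AlignmentError, ZoneConfig, effective_habitat

    a = GridRaster(np.zeros((4, 4)), 0, 400, 100.0, "mask")
    b = GridRaster(np.zeros((4, 4)), 50, 400, 100.0, "mask")
    with pytest.raises(AlignmentError):
        a.require_aligned(b)


def test_invalid_rasters_rejected():
    with pytest.raises(ValueError):
        GridRaster(np.array([[0.0, 2.0]]), 0, 100, 100.0, "mask")
    with pytest.raises(ValueError):
        GridRaster(np.array([[-1.0]]), 0, 100, 100.0, "distance_m")
    with pytest.raises(ValueError):
        GridRaster(np.zeros((2, 2)), 0, 100, -5.0)
    with pytest.raises(ValueError):
        GridRaster(np.array([[np.inf]]), 0, 100, 100.0)
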