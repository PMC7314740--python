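"""Core raster/vector data model, area accounting and file I/O.

All geometry lives in a projected planar coordinate system with units of
meters.  Rasters follow the dominant geospatial convention: row 0 is the
northernmost row, ``(origin_x, origin_y)`` is the *outer* corner of cell
(0, 0) (i.e. the north-west corner of the grid), and the center of cell
``(r, c)`` is at ``(origin_x + (c + 0.5) * cell_size,
origin_y - (r + 0.5) * cell_size)``.

Nodata is represented internally by ``NaN``; mask rasters contain only
``{0, 1, NaN}``.  Rasters must share identical georeferencing to be
combined — there is no implicit resampling.

Supported file formats: single-band GeoTIFF (georeferencing carried in the
standard ModelPixelScale / ModelTiepoint tags, nodata in the GDAL_NODATA
tag) and Esri ASCII Grid for plain-text fixtures; GeoJSON for polygons and
points; CSV (columns ``x,y``) for bare point sets.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np
import shapely
from shapely.geometry import Point, Polygon, mapping, shape

__all__ = [
    "RASTER_KINDS",
    "GridRaster",
    "PointSet",
    "PolygonSet",
    "AlignmentError",
    "rasterize_polygons",
    "mask_area_km2",
    "extract_values_at_points",
    "read_ascii_grid",
    "write_ascii_grid",
    "read_geotiff",
    "write_geotiff",
    "read_points_csv",
    "write_points_csv",
    "read_geojson_points",
    "write_geojson_points",
    "read_geojson_polygons",
    "write_geojson_polygons",
]

RASTER_KINDS = ("elevation_m", "density_per_km2", "distance_m", "mask")

#: nodata sentinel used when writing integer/text formats
ASCII_NODATA = -9999.0


class AlignmentError(ValueError):
    """Two rasters do not share identical georeferencing."""


@dataclass
class GridRaster:
    """A georeferenced square-cell raster.

    Parameters
    ----------
    values:
        ``(n_rows, n_cols)`` float array.  ``NaN`` marks nodata.
    origin_x, origin_y:
        Coordinates (m) of the outer (north-west) corner of cell (0, 0).
    cell_size:
        Edge length of a cell in meters (> 0).
    kind:
        One of :data:`RASTER_KINDS`; drives validation (masks must be
        {0, 1, NaN}; distance rasters must be non-negative).
    """

    values: np.ndarray
    origin_x: float
    origin_y: float
    cell_size: float
    kind: str = "elevation_m"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] < 1 or self.values.shape[1] < 1:
            raise ValueError("values must be a 2-D array with at least one cell")
        if not (self.cell_size > 0):
            raise ValueError(f"cell_size must be > 0, got {self.cell_size}")
        if not (np.isfinite(self.origin_x) and np.isfinite(self.origin_y)):
            raise ValueError("raster origin must be finite")
        if self.kind not in RASTER_KINDS:
            raise ValueError(f"kind must be one of {RASTER_KINDS}, got {self.kind!r}")
        finite = self.values[np.isfinite(self.values)]
        if np.isinf(self.values).any():
            raise ValueError("raster values must be finite or NaN (nodata)")
        if self.kind == "mask" and finite.size and not np.isin(finite, (0.0, 1.0)).all():
            raise ValueError("mask rasters may contain only {0, 1, nodata}")
        if self.kind == "distance_m" and finite.size and (finite < 0).any():
            raise ValueError("distance rasters may not contain negative values")

    # -- geometry ---------------------------------------------------------

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the raster's outer edges."""
        return (
            self.origin_x,
            self.origin_y - self.n_rows * self.cell_size,
            self.origin_x + self.n_cols * self.cell_size,
            self.origin_y,
        )

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        return (
            self.origin_x + (col + 0.5) * self.cell_size,
            self.origin_y - (row + 0.5) * self.cell_size,
        )

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Arrays ``(X, Y)`` of all cell-center coordinates, shape (n_rows, n_cols)."""
        cols = self.origin_x + (np.arange(self.n_cols) + 0.5) * self.cell_size
        rows = self.origin_y - (np.arange(self.n_rows) + 0.5) * self.cell_size
        return np.meshgrid(cols, rows)

    def aligned_with(self, other: "GridRaster") -> bool:
        return (
            self.values.shape == other.values.shape
            and self.origin_x == other.origin_x
            and self.origin_y == other.origin_y
            and self.cell_size == other.cell_size
        )

    def require_aligned(self, other: "GridRaster") -> None:
        if not self.aligned_with(other):
            raise AlignmentError(
                "rasters do not share identical georeferencing "
                f"({self.values.shape}@({self.origin_x},{self.origin_y})/{self.cell_size} vs "
                f"{other.values.shape}@({other.origin_x},{other.origin_y})/{other.cell_size}); "
                "resample explicitly before combining"
            )

    def like(self, values: np.ndarray, kind: str) -> "GridRaster":
        """New raster with this georeferencing and the given values/kind."""
        return GridRaster(values, self.origin_x, self.origin_y, self.cell_size, kind)

    def copy(self) -> "GridRaster":
        return self.like(self.values.copy(), self.kind)


@dataclass
class PointSet:
    """Plain (x, y) locations in projected meters with a role tag."""

    points: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.size == 0:
            pts = pts.reshape(0, 2)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError("points must be an (n, 2) array of x, y coordinates")
        if not np.isfinite(pts).all():
            raise ValueError("point coordinates must be finite")
        self.points = pts

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class PolygonSet:
    """Simple polygons (holes allowed) with optional per-polygon names."""

    polygons: list[Polygon]
    names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for i, poly in enumerate(self.polygons):
            if not isinstance(poly, Polygon):
                raise TypeError(f"polygon {i} is not a shapely Polygon")
            coords = np.asarray(poly.exterior.coords)
            if not np.isfinite(coords).all():
                raise ValueError(f"polygon {i} has non-finite vertices")
            if not poly.is_valid:
                raise ValueError(f"polygon {i} is invalid (self-intersecting ring?)")
            if poly.area <= 0:
                raise ValueError(f"polygon {i} has zero area")
        if not self.names:
            self.names = [f"polygon_{i}" for i in range(len(self.polygons))]
        if len(self.names) != len(self.polygons):
            raise ValueError("names must match polygons in length")

    def __len__(self) -> int:
        return len(self.polygons)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def rasterize_polygons(polys: PolygonSet, template: GridRaster) -> GridRaster:
    """Burn polygons onto the template grid by the cell-center rule.

    A cell is 1 iff its center lies inside (or exactly on the boundary of)
    any polygon.  The output is aligned exactly with ``template``.
    """
    out = np.zeros((template.n_rows, template.n_cols))
    if len(polys) > 0:
        X, Y = template.cell_centers()
        geom = shapely.union_all(polys.polygons)
        # intersects == covered-by for points: boundary counts as inside
        inside = shapely.intersects_xy(geom, X.ravel(), Y.ravel())
        out = inside.reshape(out.shape).astype(float)
    return template.like(out, "mask")


def mask_area_km2(mask: GridRaster) -> float:
    """Total area (km²) of cells equal to 1; nodata cells contribute nothing."""
    if mask.kind != "mask":
        raise TypeError(f"expected a mask raster, got kind={mask.kind!r}")
    ones = np.nansum(mask.values == 1.0)
    return float(ones) * mask.cell_size**2 / 1e6


def extract_values_at_points(raster: GridRaster, pts: PointSet) -> np.ndarray:
    """Raster value at the cell whose center is nearest each point.

    Values come back in point order; a point falling on a nodata cell yields
    NaN.  Points outside the raster extent raise a ``ValueError`` listing the
    offending indices.
    """
    if len(pts) == 0:
        return np.empty(0)
    x = pts.points[:, 0]
    y = pts.points[:, 1]
    xmin, ymin, xmax, ymax = raster.bounds
    outside = (x < xmin) | (x > xmax) | (y < ymin) | (y > ymax)
    if outside.any():
        bad = np.nonzero(outside)[0].tolist()
        raise ValueError(f"points outside raster extent at indices {bad}")
    # nearest cell center == containing cell; points exactly on an interior
    # edge snap deterministically to the higher col / row index via floor
    col = np.clip(np.floor((x - raster.origin_x) / raster.cell_size).astype(int), 0, raster.n_cols - 1)
    row = np.clip(np.floor((raster.origin_y - y) / raster.cell_size).astype(int), 0, raster.n_rows - 1)
    return raster.values[row, col]


# ---------------------------------------------------------------------------
# Raster I/O
# ---------------------------------------------------------------------------


def write_ascii_grid(raster: GridRaster, path: str | Path) -> None:
    """Write an Esri ASCII Grid (text) file; nodata becomes -9999."""
    vals = np.where(np.isnan(raster.values), ASCII_NODATA, raster.values)
    yll = raster.origin_y - raster.n_rows * raster.cell_size
    header = (
        f"ncols {raster.n_cols}\n"
        f"nrows {raster.n_rows}\n"
        f"xllcorner {raster.origin_x!r}\n"
        f"yllcorner {yll!r}\n"
        f"cellsize {raster.cell_size!r}\n"
        f"NODATA_value {ASCII_NODATA!r}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        for row in vals:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


def read_ascii_grid(path: str | Path, kind: str = "elevation_m") -> GridRaster:
    """Read an Esri ASCII Grid file written by any conforming tool."""
    with open(path) as fh:
        header: dict[str, float] = {}
        pos = fh.tell()
        for _ in range(6):
            pos = fh.tell()
            line = fh.readline()
            parts = line.split()
            if len(parts) == 2 and parts[0].lower() in (
                "ncols", "nrows", "xllcorner", "yllcorner", "xllcenter",
                "yllcenter", "cellsize", "nodata_value",
            ):
                header[parts[0].lower()] = float(parts[1])
            else:
                fh.seek(pos)
                break
        data = np.loadtxt(fh)
    n_rows, n_cols = int(header["nrows"]), int(header["ncols"])
    data = np.asarray(data, dtype=float).reshape(n_rows, n_cols)
    cs = header["cellsize"]
    if "xllcorner" in header:
        origin_x = header["xllcorner"]
        origin_y = header["yllcorner"] + n_rows * cs
    else:  # cell-center registered variant
        origin_x = header["xllcenter"] - cs / 2
        origin_y = header["yllcenter"] - cs / 2 + n_rows * cs
    nodata = header.get("nodata_value", ASCII_NODATA)
    data = np.where(data == nodata, np.nan, data)
    return GridRaster(data, origin_x, origin_y, cs, kind)


# GeoTIFF tag ids (GeoTIFF 1.1 / GDAL conventions)
_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113


def write_geotiff(raster: GridRaster, path: str | Path) -> None:
    """Write a single-band GeoTIFF (float64; uint8 for masks).

    Georeferencing is stored in the standard ModelPixelScale and
    ModelTiepoint tags; nodata in the GDAL_NODATA ASCII tag.
    """
    import tifffile

    if raster.kind == "mask":
        nodata_val = 255
        data = np.where(np.isnan(raster.values), nodata_val, raster.values).astype(np.uint8)
    else:
        nodata_val = ASCII_NODATA
        data = np.where(np.isnan(raster.values), nodata_val, raster.values).astype(np.float64)
    extratags = [
        (_TAG_PIXEL_SCALE, "d", 3, (raster.cell_size, raster.cell_size, 0.0)),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, raster.origin_x, raster.origin_y, 0.0)),
        (_TAG_GDAL_NODATA, "s", 0, str(nodata_val)),
    ]
    tifffile.imwrite(path, data, extratags=extratags,
                     metadata={"dogedge_kind": raster.kind})


def read_geotiff(path: str | Path, kind: str | None = None) -> GridRaster:
    """Read a single-band GeoTIFF written by :func:`write_geotiff` (or GDAL)."""
    import tifffile

    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        data = page.asarray().astype(float)
        scale = page.tags[_TAG_PIXEL_SCALE].value
        tie = page.tags[_TAG_TIEPOINT].value
        nodata_tag = page.tags.get(_TAG_GDAL_NODATA)
        if kind is None:
            kind = "elevation_m"
            meta = tif.shaped_metadata or ()
            for m in meta:
                if "dogedge_kind" in m:
                    kind = m["dogedge_kind"]
    if abs(scale[0] - scale[1]) > 1e-12 * max(scale[0], scale[1]):
        raise ValueError("only square-cell GeoTIFFs are supported")
    # tiepoint maps raster point (i, j) -> model (x, y); we require (0, 0)
    i, j = tie[0], tie[1]
    origin_x = tie[3] - i * scale[0]
    origin_y = tie[4] + j * scale[1]
    if nodata_tag is not None:
        data = np.where(data == float(nodata_tag.value), np.nan, data)
    return GridRaster(data, origin_x, origin_y, float(scale[0]), kind)


# ---------------------------------------------------------------------------
# Vector I/O
# ---------------------------------------------------------------------------


def write_points_csv(pts: PointSet, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["x", "y"])
        for x, y in pts.points:
            writer.writerow([repr(float(x)), repr(float(y))])


def read_points_csv(path: str | Path, label: str = "") -> PointSet:
    import pandas as pd

    df = pd.read_csv(path)
    return PointSet(df[["x", "y"]].to_numpy(dtype=float), label=label)


def write_geojson_points(pts: PointSet, path: str | Path) -> None:
    features = [
        {"type": "Feature", "properties": {"label": pts.label},
         "geometry": mapping(Point(x, y))}
        for x, y in pts.points
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def read_geojson_points(path: str | Path, label: str = "") -> PointSet:
    with open(path) as fh:
        gj = json.load(fh)
    coords = []
    lbl = label
    for feat in gj.get("features", []):
        geom = shape(feat["geometry"])
        if geom.geom_type != "Point":
            raise ValueError(f"expected Point geometries, got {geom.geom_type}")
        coords.append((geom.x, geom.y))
        lbl = lbl or feat.get("properties", {}).get("label", "")
    return PointSet(np.array(coords).reshape(-1, 2), label=lbl)


def write_geojson_polygons(polys: PolygonSet, path: str | Path) -> None:
    features = [
        {"type": "Feature", "properties": {"name": name}, "geometry": mapping(poly)}
        for poly, name in zip(polys.polygons, polys.names)
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def read_geojson_polygons(path: str | Path) -> PolygonSet:
    with open(path) as fh:
        gj = json.load(fh)
    polygons: list[Polygon] = []
    names: list[str] = []
    for i, feat in enumerate(gj.get("features", [])):
        geom = shape(feat["geometry"])
        if geom.geom_type == "Polygon":
            polygons.append(geom)
            names.append(feat.get("properties", {}).get("name", f"polygon_{i}"))
        elif geom.geom_type == "MultiPolygon":
            for j, part in enumerate(geom.geoms):
                polygons.append(part)
                names.append(feat.get("properties", {}).get("name", f"polygon_{i}") + f"_{j}")
        else:
            raise ValueError(f"expected Polygon geometries, got {geom.geom_type}")
    return PolygonSet(polygons, names)
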