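"""Housing-density surfaces and the populated-area mask.

A "populated area" is any cell whose housing density exceeds a threshold
(default 6.25 houses/km²).  Density is a circular moving-window count over
cell centers; the default window radius of 564.19 m gives a window of
exactly 1 km², so the threshold reads directly as "more than 6 houses
within 1 km² of the cell center".

Note the threshold is a *strict* inequality: a cell at exactly the
threshold density is not populated.  Using ``>=`` instead changes which
boundary cells seed the distance computation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .geodata import GridRaster, PointSet

__all__ = ["DensityConfig", "housing_density_surface", "populated_mask"]

#: radius (m) of a circle with area exactly 1 km²
RADIUS_1KM2_M = 1000.0 / math.sqrt(math.pi)


@dataclass(frozen=True)
class DensityConfig:
    """Moving-window housing-density parameters.

    window_radius_m : circular window radius in meters (> 0); the default
        564.19... m encloses exactly 1 km².
    threshold_per_km2 : density above which (strictly) a cell counts as a
        populated area; default 6.25 houses/km².
    """

    window_radius_m: float = RADIUS_1KM2_M
    threshold_per_km2: float = 6.25

    def __post_init__(self) -> None:
        if not (self.window_radius_m > 0):
            raise ValueError("window_radius_m must be > 0")
        if self.threshold_per_km2 < 0:
            raise ValueError("threshold_per_km2 must be >= 0")

    @property
    def window_area_km2(self) -> float:
        return math.pi * self.window_radius_m**2 / 1e6


def housing_density_surface(
    residences: PointSet, template: GridRaster, cfg: DensityConfig = DensityConfig()
) -> GridRaster:
    """Houses per km² within ``cfg.window_radius_m`` of each cell center.

    Residences outside the template but within one window radius of an edge
    cell's center still count toward that cell, so the surface has no
    artificial edge under-count.
    """
    X, Y = template.cell_centers()
    counts = np.zeros(X.size)
    if len(residences) > 0:
        tree = cKDTree(residences.points)
        centers = np.column_stack([X.ravel(), Y.ravel()])
        counts = tree.query_ball_point(
            centers, r=cfg.window_radius_m, return_length=True
        ).astype(float)
    density = counts.reshape(X.shape) / cfg.window_area_km2
    return template.like(density, "density_per_km2")


def populated_mask(density: GridRaster, cfg: DensityConfig = DensityConfig()) -> GridRaster:
    """Binary populated-area mask: density strictly greater than threshold."""
    if density.kind != "density_per_km2":
        raise TypeError(f"expected a density raster, got kind={density.kind!r}")
    vals = density.values
    out = np.where(np.isnan(vals), np.nan, (vals > cfg.threshold_per_km2).astype(float))
    return density.like(out, "mask")
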