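"""Distance-threshold zones and effective-habitat accounting.

Two thresholds matter: the human-impact distance (1,920 m, the edge effect
of residences alone) and the dog foray distance (10,900 m, the maximum
path-distance observed for free-roaming dogs).  The "dog zone" is all
terrain within the foray distance of a populated area; its complement over
passable terrain is the "dog-free zone".  Effective habitat is baseline
habitat minus the habitat lying inside a zone.

Convention: a cell is *inside* a zone when its distance is <= the
threshold, so effective habitat requires distance strictly greater.  Cells
whose distance is nodata (enclaves walled off by DEM barriers) cannot be
reached by an animal travelling over the surface either, so they count as
outside every zone; their area is reported via a logged warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .geodata import GridRaster, mask_area_km2
from .pathdist import PathDistanceSurface

__all__ = [
    "ZoneConfig",
    "EffectiveHabitatReport",
    "zone_mask",
    "effective_habitat",
    "dog_free_percent",
    "percent_reduction",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ZoneConfig:
    """Edge-effect distance thresholds, meters."""

    human_impact_m: float = 1920.0
    foray_m: float = 10900.0

    def __post_init__(self) -> None:
        if not (0 <= self.human_impact_m <= self.foray_m):
            raise ValueError("require 0 <= human_impact_m <= foray_m")


@dataclass(frozen=True)
class EffectiveHabitatReport:
    """Baseline vs effective habitat areas (km²) and the dog-impact reduction."""

    baseline_km2: float
    effective_I_km2: float   # beyond the human-impact distance
    effective_II_km2: float  # beyond the dog foray distance
    reduction_II_pct: float

    def __post_init__(self) -> None:
        if not (0 <= self.effective_II_km2 <= self.effective_I_km2 <= self.baseline_km2 + 1e-9):
            raise ValueError("effective areas must nest within baseline")


def zone_mask(surface: PathDistanceSurface, d: float) -> GridRaster:
    """Mask of cells within path-distance ``d`` of any source (the zone).

    The complementary dog-free mask is the negation over finite cells.
    """
    if d < 0:
        raise ValueError(f"zone distance must be >= 0, got {d}")
    vals = surface.raster.values
    out = np.where(np.isnan(vals), np.nan, (vals <= d).astype(float))
    return surface.raster.like(out, "mask")


def percent_reduction(baseline_km2: float, effective_km2: float) -> float:
    """Percent of baseline habitat lost to the edge effect."""
    if baseline_km2 <= 0:
        raise ValueError("baseline area must be > 0")
    if effective_km2 > baseline_km2 + 1e-9:
        raise ValueError("effective area cannot exceed baseline")
    return 100.0 * (baseline_km2 - effective_km2) / baseline_km2


def effective_habitat(
    habitat: GridRaster, surface: PathDistanceSurface, cfg: ZoneConfig = ZoneConfig()
) -> EffectiveHabitatReport:
    """Baseline habitat area and the areas beyond each edge-effect threshold."""
    if habitat.kind != "mask":
        raise TypeError(f"expected a habitat mask, got kind={habitat.kind!r}")
    habitat.require_aligned(surface.raster)
    hab = habitat.values == 1.0
    dist = surface.raster.values
    unreachable = hab & np.isnan(dist) & np.isfinite(surface.dem.values)
    if unreachable.any():
        area = unreachable.sum() * habitat.cell_size**2 / 1e6
        logger.warning(
            "%.3f km2 of habitat is unreachable from any populated area "
            "(nodata distance); counted as beyond every zone", area
        )
    cell_km2 = habitat.cell_size**2 / 1e6
    baseline = float(hab.sum()) * cell_km2
    beyond = ~(dist <= cfg.human_impact_m)  # NaN compares False -> beyond
    eff1 = float((hab & beyond).sum()) * cell_km2
    beyond2 = ~(dist <= cfg.foray_m)
    eff2 = float((hab & beyond2).sum()) * cell_km2
    reduction = percent_reduction(baseline, eff2) if baseline > 0 else 0.0
    return EffectiveHabitatReport(
        baseline_km2=baseline,
        effective_I_km2=eff1,
        effective_II_km2=eff2,
        reduction_II_pct=reduction,
    )


def dog_free_percent(total_km2: float, edge_km2: float) -> tuple[float, float]:
    """Dog-free area and percent of a total, given the edge-affected area."""
    if total_km2 <= 0:
        raise ValueError("total area must be > 0")
    if not (0 <= edge_km2 <= total_km2):
        raise ValueError("edge area must lie in [0, total]")
    dog_free = total_km2 - edge_km2
    return dog_free, 100.0 * dog_free / total_km2
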