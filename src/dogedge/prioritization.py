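"""Reserve threat ranking and Jenks natural-breaks classification.

Reserves are ranked by the area of habitat inside the dog zone (habitat
within the foray path-distance of a populated area) and classified into
low / moderate / high threat tiers.  The default tier boundaries are 50
and 165 km²; fresh boundaries can be re-derived from any value list with
:func:`jenks_breaks`, which implements Fisher's exact dynamic program for
the optimal contiguous partition (not the common heuristic reseeding
variant), so the within-class sum of squared deviations is globally
minimal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .geodata import GridRaster, PolygonSet, rasterize_polygons
from .pathdist import PathDistanceSurface
from .zones import ZoneConfig

__all__ = [
    "ReserveThreat",
    "JenksResult",
    "dog_zone_habitat_by_reserve",
    "jenks_breaks",
    "classify_threat",
    "LOW_BREAK_KM2",
    "HIGH_BREAK_KM2",
]

logger = logging.getLogger(__name__)

LOW_BREAK_KM2 = 50.0
HIGH_BREAK_KM2 = 165.0


@dataclass(frozen=True)
class ReserveThreat:
    reserve_id: str
    dog_zone_habitat_km2: float
    category: str  # low | moderate | high


@dataclass(frozen=True)
class JenksResult:
    """Optimal k-class partition of 1-D values.

    breaks : k-1 ascending boundaries, each the midpoint between the
        adjacent sorted values that the optimal partition separates.
    gvf : goodness of variance fit, 1 - SSD_within / SSD_total in [0, 1].
    assignment : class index (0..k-1) per input value, in input order.
    """

    breaks: tuple[float, ...]
    gvf: float
    assignment: tuple[int, ...]


def dog_zone_habitat_by_reserve(
    reserves: PolygonSet,
    habitat: GridRaster,
    surface: PathDistanceSurface,
    cfg: ZoneConfig = ZoneConfig(),
) -> list[tuple[str, float]]:
    """Area (km²) of habitat inside the dog zone, per reserve polygon."""
    if len(reserves) == 0:
        raise ValueError("reserves must be non-empty")
    habitat.require_aligned(surface.raster)
    hab = habitat.values == 1.0
    in_zone = surface.raster.values <= cfg.foray_m  # NaN -> False
    cell_km2 = habitat.cell_size**2 / 1e6
    out: list[tuple[str, float]] = []
    for poly, name in zip(reserves.polygons, reserves.names):
        rmask = rasterize_polygons(PolygonSet([poly], [name]), habitat)
        inside = rmask.values == 1.0
        if not inside.any():
            logger.warning("reserve %s covers no raster cells; area reported as 0", name)
        area = float((inside & hab & in_zone).sum()) * cell_km2
        out.append((name, area))
    return out


def _prefix_stats(sorted_vals: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    s1 = np.concatenate([[0.0], np.cumsum(sorted_vals)])
    s2 = np.concatenate([[0.0], np.cumsum(sorted_vals**2)])
    return s1, s2


def _sse(s1: np.ndarray, s2: np.ndarray, i: int, j: int) -> float:
    """Within-class SSD of sorted values [i, j) using prefix sums."""
    n = j - i
    tot = s1[j] - s1[i]
    return max(0.0, (s2[j] - s2[i]) - tot * tot / n)


def jenks_breaks(values, k: int) -> JenksResult:
    """Globally optimal Jenks natural breaks (Fisher's dynamic program).

    Minimizes the total within-class sum of squared deviations over all
    partitions of the sorted values into ``k`` contiguous classes.  Ties
    between equally good partitions are broken toward the partition with
    the smallest first break, then recursively.
    """
    vals = np.asarray(values, dtype=float)
    n = vals.size
    if not (1 <= k <= n):
        raise ValueError(f"need 1 <= k <= n, got k={k}, n={n}")
    order = np.argsort(vals, kind="stable")
    sorted_vals = vals[order]
    s1, s2 = _prefix_stats(sorted_vals)

    # cost[j][c]: minimal SSD of the first j values in c classes
    cost = np.full((n + 1, k + 1), np.inf)
    split = np.zeros((n + 1, k + 1), dtype=int)
    cost[0, 0] = 0.0
    for c in range(1, k + 1):
        for j in range(c, n + 1):
            best, best_m = np.inf, c
            # last class covers sorted values [m, j); scan m ascending so
            # ties prefer the smaller split, keeping earlier breaks small
            for m in range(c - 1, j):
                cand = cost[m, c - 1] + _sse(s1, s2, m, j)
                if cand < best - 1e-12:
                    best, best_m = cand, m
            cost[j, c] = best
            split[j, c] = best_m

    # backtrack class boundaries (indices into sorted order)
    bounds = [n]
    j = n
    for c in range(k, 0, -1):
        j = split[j, c]
        bounds.append(j)
    bounds = bounds[::-1]  # [0, b1, ..., n]

    breaks = tuple(
        0.5 * (sorted_vals[b - 1] + sorted_vals[b]) for b in bounds[1:-1]
    )
    class_of_sorted = np.empty(n, dtype=int)
    for c in range(k):
        class_of_sorted[bounds[c]:bounds[c + 1]] = c
    assignment = np.empty(n, dtype=int)
    assignment[order] = class_of_sorted

    ssd_total = _sse(s1, s2, 0, n)
    gvf = 1.0 if ssd_total == 0 else 1.0 - cost[n, k] / ssd_total
    return JenksResult(
        breaks=breaks, gvf=float(min(max(gvf, 0.0), 1.0)), assignment=tuple(assignment)
    )


def classify_threat(
    dog_zone_habitat_km2: float,
    low_break: float = LOW_BREAK_KM2,
    high_break: float = HIGH_BREAK_KM2,
) -> str:
    """Threat tier for a reserve's dog-zone habitat area.

    low: area < low_break; moderate: low_break <= area < high_break;
    high: area >= high_break (the boundary value counts as high — the
    conservative choice for a threat ranking).
    """
    if dog_zone_habitat_km2 < 0:
        raise ValueError("area must be >= 0")
    if not (0 <= low_break <= high_break):
        raise ValueError("require 0 <= low_break <= high_break")
    if dog_zone_habitat_km2 < low_break:
        return "low"
    if dog_zone_habitat_km2 < high_break:
        return "moderate"
    return "high"
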