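"""Synthetic mountain landscapes for end-to-end pipeline runs.

No real inputs ship with this package (the study system's census
occurrences, digitized residences, DEM extract and range layer are all
restricted or third-party), so every stage is exercised on generated
landscapes that carry the same statistical structure:

* rugged terrain — a central massif with smooth random ridge texture and
  carved valley corridors draining to lowlands around the rim;
* residences clustered in villages on low-elevation valley floors, the
  way mountain settlements follow roads and rivers;
* a habitat mask defined by an elevation band (mirroring montane bamboo
  forest below the rocky crests), which splits into a near-village apron
  and a remote interior separated by the non-habitat crest ring;
* reserve polygons tiling the habitat; and
* occurrence points drawn from habitat with a logistic avoidance response
  to path distance from populated areas (scenario ``many_dogs``:
  avoidance midpoint at the dog foray distance; ``few_dogs``: midpoint at
  the human-impact distance; ``null``: uniform use).

Every stage draws from its own seeded random stream, so changing one
config field never perturbs an unrelated stage, and fixed seeds give
bit-identical outputs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from shapely.geometry import Polygon

from .geodata import GridRaster, PointSet, PolygonSet
from .pathdist import PathDistanceSurface
from .use_availability import avoidance_weight

__all__ = [
    "LandscapeConfig",
    "OccurrenceConfig",
    "Landscape",
    "generate_terrain",
    "place_residences",
    "generate_habitat_and_reserves",
    "simulate_occurrences",
    "generate_landscape",
]

logger = logging.getLogger(__name__)

# per-stage stream tags so stages are statistically independent
_STREAM_TERRAIN = 11
_STREAM_VILLAGES = 23
_STREAM_RESERVES = 37
_STREAM_OCCURRENCES = 53


@dataclass(frozen=True)
class LandscapeConfig:
    """Parameters of the generated landscape.

    The defaults give a 36 km x 36 km landscape at 100 m resolution with
    2,000 m of relief — large enough that the 10.9 km foray threshold
    leaves a genuine remote interior behind the crest ring, small enough
    that the full pipeline runs in seconds.
    """

    seed: int = 0
    n_rows: int = 360
    n_cols: int = 360
    cell_size_m: float = 100.0
    relief_m: float = 2000.0
    n_valleys: int = 4
    n_villages: int = 12
    houses_per_village: tuple[int, int] = (20, 60)
    village_spread_m: float = 500.0
    habitat_band_m: tuple[float, float] = (150.0, 1350.0)
    n_reserves: int = 3

    def __post_init__(self) -> None:
        if min(self.n_rows, self.n_cols) < 1 or self.cell_size_m <= 0:
            raise ValueError("grid dimensions must be positive")
        if self.relief_m < 0:
            raise ValueError("relief_m must be >= 0")
        if min(self.n_valleys, self.n_villages, self.n_reserves) < 0:
            raise ValueError("counts must be >= 0")
        lo, hi = self.houses_per_village
        if not (0 <= lo <= hi):
            raise ValueError("houses_per_village must be an ascending range")
        if not (self.habitat_band_m[0] < self.habitat_band_m[1]):
            raise ValueError("habitat band must satisfy low < high")


@dataclass(frozen=True)
class OccurrenceConfig:
    """Occurrence simulation: scenario contrast of dog pressure.

    ``many_dogs`` places the avoidance midpoint at the dog foray distance
    (10,900 m); ``few_dogs`` at the human-impact distance (1,920 m);
    ``null`` uses habitat uniformly.  ``s_m`` is the logistic softness.
    """

    seed: int = 0
    n_occurrences: int = 46
    scenario: str = "many_dogs"
    theta_m: float | None = None
    s_m: float = 1000.0

    def __post_init__(self) -> None:
        if self.scenario not in ("many_dogs", "few_dogs", "null"):
            raise ValueError("scenario must be many_dogs, few_dogs or null")
        if self.s_m <= 0:
            raise ValueError("s_m must be > 0")
        if self.n_occurrences < 0:
            raise ValueError("n_occurrences must be >= 0")

    @property
    def effective_theta_m(self) -> float:
        if self.theta_m is not None:
            return self.theta_m
        return {"many_dogs": 10900.0, "few_dogs": 1920.0, "null": 0.0}[self.scenario]


@dataclass
class Landscape:
    """A complete generated landscape bundle."""

    dem: GridRaster
    residences: PointSet
    habitat: GridRaster
    reserves: PolygonSet
    config: LandscapeConfig


def _valley_lines(cfg: LandscapeConfig) -> list[tuple[float, float, float, float]]:
    """Valley center-lines in cell units, draining from mid-slope to the edge.

    Azimuths are evenly spaced with jitter so the valleys (and hence the
    settled corridors) surround the massif but leave remote inter-valley
    sectors.  Drawn from a dedicated substream so terrain texture and
    residence placement can share the same corridors.
    """
    rng = np.random.default_rng([cfg.seed, _STREAM_TERRAIN, 1])
    lines = []
    cr, cc = (cfg.n_rows - 1) / 2.0, (cfg.n_cols - 1) / 2.0
    rim = min(cr, cc)
    for i in range(cfg.n_valleys):
        azimuth = 2.0 * math.pi * (i + rng.uniform(-0.25, 0.25)) / cfg.n_valleys
        # from roughly half-way up the massif out past the grid edge
        r_in = rng.uniform(0.35, 0.55) * rim
        r_out = 1.5 * rim
        r0 = cr + r_in * math.cos(azimuth)
        c0 = cc + r_in * math.sin(azimuth)
        r1 = cr + r_out * math.cos(azimuth)
        c1 = cc + r_out * math.sin(azimuth)
        lines.append((r0, c0, r1, c1))
    return lines


def _dist_to_segment(rr: np.ndarray, cc: np.ndarray, seg: tuple[float, float, float, float]) -> np.ndarray:
    r0, c0, r1, c1 = seg
    vr, vc = r1 - r0, c1 - c0
    vv = vr * vr + vc * vc
    t = ((rr - r0) * vr + (cc - c0) * vc) / vv if vv > 0 else np.zeros_like(rr)
    t = np.clip(t, 0.0, 1.0)
    dr = rr - (r0 + t * vr)
    dc = cc - (c0 + t * vc)
    return np.sqrt(dr * dr + dc * dc)


def generate_terrain(cfg: LandscapeConfig) -> GridRaster:
    """Smooth pseudo-random topography with carved valley corridors.

    The surface is a settled lowland apron rising to a high crest ring
    with high interior valleys behind it, plus a sum of low-frequency
    random cosine waves, with ``n_valleys`` Gaussian-profile radial
    depressions draining from mid-slope out past the grid edge.  After
    carving, elevation is rescaled to span exactly ``[0, relief_m]``.
    """
    rng = np.random.default_rng([cfg.seed, _STREAM_TERRAIN])
    rr, cc = np.meshgrid(np.arange(cfg.n_rows, dtype=float),
                         np.arange(cfg.n_cols, dtype=float), indexing="ij")
    n = max(cfg.n_rows, cfg.n_cols)

    # dominant structure: a settled lowland apron rising to a high rocky
    # crest ring, with high interior valleys behind it — so a mid-elevation
    # habitat band splits into a near-village apron and a remote interior
    # separated by the (non-habitat) crest
    cr, ccen = (cfg.n_rows - 1) / 2.0, (cfg.n_cols - 1) / 2.0
    rim = min(cr, ccen)
    rho = np.sqrt((rr - cr) ** 2 + (cc - ccen) ** 2) / rim
    z = 0.35 * np.clip(1.0 - rho, 0.0, None) + 0.95 * np.exp(-(((rho - 0.42) / 0.16) ** 2))
    # low-frequency ridge-and-valley texture
    for _ in range(6):
        wavelength = rng.uniform(n / 8.0, n / 2.5)
        direction = rng.uniform(0.0, math.pi)
        phase = rng.uniform(0.0, 2.0 * math.pi)
        amp = rng.uniform(0.05, 0.16)
        k = 2.0 * math.pi / wavelength
        z += amp * np.cos(k * (rr * math.cos(direction) + cc * math.sin(direction)) + phase)
    # carved valleys draining radially outward
    width = max(n / 30.0, 2.0)
    for seg in _valley_lines(cfg):
        d = _dist_to_segment(rr, cc, seg)
        z -= 0.55 * np.exp(-((d / width) ** 2))

    if cfg.relief_m == 0:
        return GridRaster(np.zeros_like(z), 0.0, cfg.n_rows * cfg.cell_size_m,
                          cfg.cell_size_m, "elevation_m")
    z -= z.min()
    zmax = z.max()
    if zmax > 0:
        z *= cfg.relief_m / zmax
    return GridRaster(z, 0.0, cfg.n_rows * cfg.cell_size_m, cfg.cell_size_m, "elevation_m")


def place_residences(dem: GridRaster, cfg: LandscapeConfig) -> PointSet:
    """Village-clustered residences on low-elevation valley floors.

    Village centers are drawn uniformly from cells in the lowest elevation
    quartile (the valley bottoms); each village scatters its houses with an
    isotropic Gaussian of scale ``village_spread_m``.
    """
    rng = np.random.default_rng([cfg.seed, _STREAM_VILLAGES])
    if cfg.n_villages == 0:
        return PointSet(np.empty((0, 2)), label="residences")
    q25 = np.nanquantile(dem.values, 0.25)
    rows, cols = np.nonzero(dem.values <= q25)
    if rows.size == 0:
        rows, cols = np.nonzero(np.isfinite(dem.values))

    # villages ring the massif: one per azimuthal sector (jittered), drawn
    # from the low-elevation cells of the outer apron in that sector, which
    # are the valley mouths and river flats where roads run
    rr, cc = rows.astype(float), cols.astype(float)
    cr, ccen = (dem.n_rows - 1) / 2.0, (dem.n_cols - 1) / 2.0
    rim = min(cr, ccen)
    rho = np.sqrt((rr - cr) ** 2 + (cc - ccen) ** 2) / rim
    angle = np.arctan2(cc - ccen, rr - cr)  # (-pi, pi]
    outer = rho > 0.90

    pts: list[np.ndarray] = []
    lo, hi = cfg.houses_per_village
    half_sector = math.pi / cfg.n_villages
    for i in range(cfg.n_villages):
        az = -math.pi + 2.0 * math.pi * (i + 0.5 + rng.uniform(-0.3, 0.3)) / cfg.n_villages
        delta = np.abs(np.angle(np.exp(1j * (angle - az))))
        cand = np.nonzero(outer & (delta <= half_sector))[0]
        if cand.size == 0:
            cand = np.nonzero(outer)[0]
        if cand.size == 0:
            cand = np.arange(rows.size)
        idx = int(cand[rng.integers(0, cand.size)])
        cx, cy = dem.cell_center(rows[idx], cols[idx])
        n_houses = int(rng.integers(lo, hi + 1)) if hi > 0 else 0
        offsets = rng.normal(0.0, cfg.village_spread_m, size=(n_houses, 2))
        pts.append(np.array([cx, cy]) + offsets)
    coords = np.vstack(pts) if pts else np.empty((0, 2))
    return PointSet(coords, label="residences")


def generate_habitat_and_reserves(
    dem: GridRaster, cfg: LandscapeConfig
) -> tuple[GridRaster, PolygonSet]:
    """Elevation-band habitat mask and jittered rectangular reserves.

    Habitat is every cell whose elevation lies inside ``habitat_band_m``
    (montane forest sits in an elevation band above the settled valley
    floors).  Reserves are ``n_reserves`` disjoint jittered rectangles,
    one per vertical strip of the grid, drawn around the habitat cells in
    that strip.
    """
    rng = np.random.default_rng([cfg.seed, _STREAM_RESERVES])
    lo, hi = cfg.habitat_band_m
    hab = ((dem.values >= lo) & (dem.values <= hi)).astype(float)
    hab[np.isnan(dem.values)] = np.nan
    habitat = dem.like(hab, "mask")
    if np.nansum(hab) == 0:
        logger.warning("habitat band [%s, %s] m excludes every cell", lo, hi)

    polys: list[Polygon] = []
    names: list[str] = []
    if cfg.n_reserves > 0:
        strip_w = dem.n_cols / cfg.n_reserves
        cs = dem.cell_size
        for i in range(cfg.n_reserves):
            c_lo, c_hi = int(i * strip_w), int((i + 1) * strip_w)
            sub = hab[:, c_lo:c_hi] == 1.0
            rows_i, cols_i = np.nonzero(sub)
            if rows_i.size:
                r0, r1 = rows_i.min(), rows_i.max() + 1
                cc0, cc1 = c_lo + cols_i.min(), c_lo + cols_i.max() + 1
            else:
                logger.warning("reserve strip %d contains no habitat cells", i)
                r0, r1 = dem.n_rows // 4, 3 * dem.n_rows // 4
                cc0, cc1 = c_lo, c_hi
            # outward jitter on the north/south edges only; east/west edges
            # stay inside the strip so reserves remain disjoint
            jn = rng.uniform(0.0, 1.0)
            js = rng.uniform(0.0, 1.0)
            x0 = dem.origin_x + cc0 * cs
            x1 = dem.origin_x + cc1 * cs
            y1 = dem.origin_y - max(r0 - jn, 0) * cs
            y0 = dem.origin_y - min(r1 + js, dem.n_rows) * cs
            polys.append(Polygon([(x0, y0), (x1, y0), (x1, y1), (x0, y1)]))
            names.append(f"reserve_{i}")
    return habitat, PolygonSet(polys, names)


def simulate_occurrences(
    surface: PathDistanceSurface, habitat: GridRaster, cfg: OccurrenceConfig
) -> PointSet:
    """Occurrence points drawn from habitat with distance-dependent weight.

    Habitat cells with a finite path distance are sampled with replacement,
    with probability proportional to the logistic avoidance weight
    ``w(d) = 1 / (1 + exp(-(d - theta)/s))`` (uniform for the ``null``
    scenario); each point is jittered uniformly within its cell.
    """
    habitat.require_aligned(surface.raster)
    rows, cols = np.nonzero((habitat.values == 1.0) & np.isfinite(surface.raster.values))
    if rows.size == 0:
        raise ValueError("no habitat cells with finite path distance")
    rng = np.random.default_rng([cfg.seed, _STREAM_OCCURRENCES])
    if cfg.scenario == "null":
        weights = np.ones(rows.size)
    else:
        d = surface.raster.values[rows, cols]
        weights = avoidance_weight(d, cfg.effective_theta_m, cfg.s_m)
    total = weights.sum()
    if not (total > 0) or not np.isfinite(total):
        raise RuntimeError("all occurrence sampling weights are numerically zero")
    pick = rng.choice(rows.size, size=cfg.n_occurrences, replace=True, p=weights / total)
    jitter = rng.random((cfg.n_occurrences, 2))
    cs = habitat.cell_size
    x = habitat.origin_x + (cols[pick] + jitter[:, 0]) * cs
    y = habitat.origin_y - (rows[pick] + jitter[:, 1]) * cs
    return PointSet(np.column_stack([x, y]), label="occurrences")


def generate_landscape(cfg: LandscapeConfig) -> Landscape:
    """Generate terrain, residences, habitat and reserves in one call."""
    dem = generate_terrain(cfg)
    residences = place_residences(dem, cfg)
    habitat, reserves = generate_habitat_and_reserves(dem, cfg)
    return Landscape(dem=dem, residences=residences, habitat=habitat,
                     reserves=reserves, config=cfg)
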