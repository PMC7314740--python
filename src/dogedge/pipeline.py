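"""End-to-end orchestration: density -> populated mask -> path distance ->
zones -> effective habitat -> use/availability -> reserve prioritization.

A run is configured either from real inputs (file paths to a DEM raster,
residence points, habitat mask/polygons, reserve polygons and optional
occurrence points) or from a synthetic :class:`~dogedge.synthetic.LandscapeConfig`;
exactly one of the two must be active.  All distances are meters, all
areas km².

The run report is a plain dictionary (written as JSON plus a key/value
text file and CSV tables) containing every effective-habitat and
use-availability figure the analysis produces.  Reports carry no
timestamps, so identical configurations and seeds produce byte-identical
report files; stage timings go to the logger only.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import geodata
from .geodata import GridRaster, PointSet, PolygonSet, extract_values_at_points, mask_area_km2
from .populated import DensityConfig, housing_density_surface, populated_mask
from .pathdist import max_finite_distance, surface_path_distance
from .prioritization import classify_threat, dog_zone_habitat_by_reserve, jenks_breaks
from .use_availability import fit_avoidance, sample_available, summarize_shift
from .synthetic import LandscapeConfig, OccurrenceConfig, generate_landscape, simulate_occurrences
from .zones import ZoneConfig, effective_habitat, zone_mask

__all__ = ["RealInputs", "RunConfig", "run_pipeline", "load_run_config"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RealInputs:
    """File paths for a run on observed data (projected meters throughout)."""

    dem: str
    residences: str
    habitat: str            # raster mask (.asc/.tif) or polygon GeoJSON
    reserves: str | None = None
    occurrences: str | None = None


@dataclass
class RunConfig:
    """Everything one pipeline run needs.

    Exactly one of ``real`` and ``landscape`` must be set.  Defaults
    reproduce the reference parameterization: 6.25 houses/km², thresholds
    1,920 m and 10,900 m, 100 available locations, fixed threat breaks at
    50/165 km².
    """

    real: RealInputs | None = None
    landscape: LandscapeConfig | None = None
    occurrences: OccurrenceConfig | None = None
    density: DensityConfig = field(default_factory=DensityConfig)
    zones: ZoneConfig = field(default_factory=ZoneConfig)
    n_available: int = 100
    availability_seed: int = 0
    fit_avoidance_model: bool = False
    jenks_k: int | None = None  # None -> fixed 50/165 breaks
    out_dir: str | None = None
    write_geotiff: bool = False  # default ASCII grids; GeoTIFF on request

    def __post_init__(self) -> None:
        if (self.real is None) == (self.landscape is None):
            raise ValueError("exactly one of real inputs or a synthetic landscape must be set")


def _load_real(inputs: RealInputs) -> tuple[GridRaster, PointSet, GridRaster, PolygonSet | None, PointSet | None]:
    def _read_raster(path: str, kind: str) -> GridRaster:
        p = Path(path)
        if p.suffix.lower() in (".tif", ".tiff"):
            return geodata.read_geotiff(p, kind)
        return geodata.read_ascii_grid(p, kind)

    dem = _read_raster(inputs.dem, "elevation_m")
    if Path(inputs.residences).suffix.lower() == ".csv":
        residences = geodata.read_points_csv(inputs.residences, label="residences")
    else:
        residences = geodata.read_geojson_points(inputs.residences, label="residences")
    hab_path = Path(inputs.habitat)
    if hab_path.suffix.lower() in (".geojson", ".json"):
        habitat = geodata.rasterize_polygons(geodata.read_geojson_polygons(hab_path), dem)
    else:
        habitat = _read_raster(inputs.habitat, "mask")
    reserves = geodata.read_geojson_polygons(inputs.reserves) if inputs.reserves else None
    occurrences = None
    if inputs.occurrences:
        if Path(inputs.occurrences).suffix.lower() == ".csv":
            occurrences = geodata.read_points_csv(inputs.occurrences, label="occurrences")
        else:
            occurrences = geodata.read_geojson_points(inputs.occurrences, label="occurrences")
    return dem, residences, habitat, reserves, occurrences


def _stage(name: str, t0: float) -> float:
    t1 = time.perf_counter()
    logger.info("stage %-16s %6.2f s", name, t1 - t0)
    return t1


def run_pipeline(cfg: RunConfig) -> dict[str, Any]:
    """Run all stages and return (and optionally write) the run report."""
    t = time.perf_counter()
    if cfg.landscape is not None:
        land = generate_landscape(cfg.landscape)
        dem, residences, habitat, reserves = land.dem, land.residences, land.habitat, land.reserves
        occurrences = None
    else:
        dem, residences, habitat, reserves, occurrences = _load_real(cfg.real)
    habitat.require_aligned(dem)
    t = _stage("inputs", t)

    density = housing_density_surface(residences, dem, cfg.density)
    populated = populated_mask(density, cfg.density)
    if not (populated.values == 1.0).any():
        raise RuntimeError("populated-areas stage produced an empty mask; "
                           "no source cells for the path-distance stage")
    t = _stage("populated", t)

    surface = surface_path_distance(dem, populated)
    t = _stage("path_distance", t)

    report: dict[str, Any] = {
        "config": {
            "density_threshold_per_km2": cfg.density.threshold_per_km2,
            "density_window_radius_m": cfg.density.window_radius_m,
            "human_impact_m": cfg.zones.human_impact_m,
            "foray_m": cfg.zones.foray_m,
            "n_available": cfg.n_available,
            "availability_seed": cfg.availability_seed,
            "synthetic": cfg.landscape is not None,
        },
        "n_residences": len(residences),
        "max_path_distance_m": max_finite_distance(surface),
    }

    eh = effective_habitat(habitat, surface, cfg.zones)
    report["effective_habitat"] = dataclasses.asdict(eh)
    dog_zone = zone_mask(surface, cfg.zones.foray_m)
    dog_zone_km2 = mask_area_km2(dog_zone)
    finite_km2 = float(np.isfinite(surface.raster.values).sum()) * dem.cell_size**2 / 1e6
    report["zones"] = {
        "dog_zone_km2": dog_zone_km2,
        "dog_free_km2": finite_km2 - dog_zone_km2,
        "total_finite_km2": finite_km2,
    }
    # conservation identities are structural; fail loudly if they ever break
    assert abs(report["zones"]["dog_zone_km2"] + report["zones"]["dog_free_km2"]
               - finite_km2) < 1e-6
    assert eh.effective_II_km2 <= eh.effective_I_km2 + 1e-9 <= eh.baseline_km2 + 2e-9
    t = _stage("zones", t)

    if cfg.landscape is not None and cfg.occurrences is not None:
        occurrences = simulate_occurrences(surface, habitat, cfg.occurrences)
    use_avail = None
    if occurrences is not None and len(occurrences) > 0:
        avail = sample_available(habitat, cfg.n_available, cfg.availability_seed)
        used_d = extract_values_at_points(surface.raster, occurrences)
        avail_d = extract_values_at_points(surface.raster, avail)
        used_d = used_d[np.isfinite(used_d)]
        avail_d = avail_d[np.isfinite(avail_d)]
        ua = summarize_shift(used_d, avail_d, cfg.zones)
        use_avail = dataclasses.asdict(ua)
        if cfg.fit_avoidance_model:
            model = fit_avoidance(used_d, avail_d)
            use_avail["avoidance_theta_m"] = model.theta_m
            use_avail["avoidance_s_m"] = model.s_m
        report["use_availability"] = use_avail
    else:
        avail = None
    t = _stage("use_availability", t)

    ranking = None
    if reserves is not None and len(reserves) > 0:
        areas = dog_zone_habitat_by_reserve(reserves, habitat, surface, cfg.zones)
        if cfg.jenks_k:
            jr = jenks_breaks([a for _, a in areas], cfg.jenks_k)
            lows = list(jr.breaks) + [float("inf")] * 2
            low_b, high_b = lows[0], lows[1]
        else:
            low_b, high_b = 50.0, 165.0
        ranking = [
            {"reserve_id": rid, "dog_zone_habitat_km2": a,
             "category": classify_threat(a, low_b, high_b)}
            for rid, a in areas
        ]
        report["prioritization"] = {
            "low_break_km2": low_b, "high_break_km2": high_b,
            "mode": "jenks" if cfg.jenks_k else "fixed",
            "reserves": ranking,
        }
    t = _stage("prioritization", t)

    if cfg.out_dir:
        _write_outputs(Path(cfg.out_dir), cfg, report,
                       rasters={"dem": dem, "density": density, "populated": populated,
                                "path_distance": surface.raster, "habitat": habitat,
                                "dog_zone": dog_zone},
                       points={"residences": residences, "occurrences": occurrences,
                               "available": avail},
                       reserves=reserves, ranking=ranking)
        _stage("outputs", t)
    return report


def _write_outputs(out: Path, cfg: RunConfig, report: dict, rasters: dict,
                   points: dict, reserves: PolygonSet | None, ranking) -> None:
    out.mkdir(parents=True, exist_ok=True)
    for name, ras in rasters.items():
        if ras is None:
            continue
        if cfg.write_geotiff:
            geodata.write_geotiff(ras, out / f"{name}.tif")
        else:
            geodata.write_ascii_grid(ras, out / f"{name}.asc")
    for name, pts in points.items():
        if pts is not None:
            geodata.write_points_csv(pts, out / f"{name}.csv")
            geodata.write_geojson_points(pts, out / f"{name}.geojson")
    if reserves is not None:
        geodata.write_geojson_polygons(reserves, out / "reserves.geojson")
    if ranking is not None:
        pd.DataFrame(ranking).to_csv(out / "reserve_threat.csv", index=False)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    with open(out / "report.txt", "w") as fh:
        for line in _flatten("", report):
            fh.write(line + "\n")


def _flatten(prefix: str, obj) -> list[str]:
    lines: list[str] = []
    if isinstance(obj, dict):
        items = [(str(k), v) for k, v in sorted(obj.items())]
    elif isinstance(obj, list):
        items = [(str(i), v) for i, v in enumerate(obj)]
    else:
        return [f"{prefix.rstrip('.')} = {obj}"]
    for key, val in items:
        if isinstance(val, (dict, list)):
            lines.extend(_flatten(f"{prefix}{key}.", val))
        else:
            lines.append(f"{prefix}{key} = {val}")
    return lines


def load_run_config(path: str | Path) -> RunConfig:
    """Build a :class:`RunConfig` from a YAML file.

    Sections mirror the dataclasses: ``inputs`` (real file paths) or
    ``landscape`` (synthetic), plus optional ``occurrences``, ``density``,
    ``zones`` and top-level keys ``n_available``, ``availability_seed``,
    ``fit_avoidance_model``, ``jenks_k``, ``out_dir``, ``write_geotiff``.
    An empty override block reproduces the reference parameterization.
    """
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    kwargs: dict[str, Any] = {}
    if "inputs" in raw:
        kwargs["real"] = RealInputs(**raw["inputs"])
    if "landscape" in raw:
        land = dict(raw["landscape"] or {})
        for key in ("houses_per_village", "habitat_band_m"):
            if key in land:
                land[key] = tuple(land[key])
        kwargs["landscape"] = LandscapeConfig(**land)
    if "occurrences" in raw:
        kwargs["occurrences"] = OccurrenceConfig(**(raw["occurrences"] or {}))
    if "density" in raw:
        kwargs["density"] = DensityConfig(**(raw["density"] or {}))
    if "zones" in raw:
        kwargs["zones"] = ZoneConfig(**(raw["zones"] or {}))
    for key in ("n_available", "availability_seed", "fit_avoidance_model",
                "jenks_k", "out_dir", "write_geotiff"):
        if key in raw:
            kwargs[key] = raw[key]
    return RunConfig(**kwargs)
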