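"""Use-versus-availability analysis of occurrence distances.

The question: are occurrence locations farther (in path distance) from
populated areas than random locations drawn from the available habitat
would be?  The headline statistics are the two distance means, the shift
between them, and that shift expressed in availability standard deviations
— a shift of ~2 SD with most occurrences beyond the dog foray distance is
the signature of avoidance.

An optional logistic avoidance model formalizes the comparison: habitat
use is weighted by w(d) = 1 / (1 + exp(-(d - theta)/s)), a soft step that
switches on at the avoidance midpoint theta with softness s.  The fit is
an extension beyond the headline summary statistics and is reported
separately.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .geodata import GridRaster, PointSet
from .zones import ZoneConfig

__all__ = [
    "UseAvailabilityResult",
    "AvoidanceModel",
    "FitError",
    "sample_available",
    "summarize_shift",
    "fit_avoidance",
    "dog_density",
    "avoidance_weight",
]


class FitError(RuntimeError):
    """The avoidance-model fit could not be carried out on these inputs."""


@dataclass(frozen=True)
class UseAvailabilityResult:
    """Summary of used vs available path-distance distributions (km)."""

    n_used: int
    n_available: int
    mean_used_km: float
    mean_avail_km: float
    sd_avail_km: float
    shift_km: float
    shift_sd: float | None  # None when availability has zero variance
    frac_used_beyond_foray: float


@dataclass(frozen=True)
class AvoidanceModel:
    """Logistic avoidance response: midpoint theta_m, softness s_m (meters)."""

    theta_m: float
    s_m: float

    def __post_init__(self) -> None:
        if not (self.s_m > 0):
            raise ValueError("softness s_m must be > 0")

    def weight(self, d_m: np.ndarray | float) -> np.ndarray | float:
        return avoidance_weight(d_m, self.theta_m, self.s_m)


def avoidance_weight(d_m, theta_m: float, s_m: float):
    """w(d) = 1 / (1 + exp(-(d - theta)/s)), computed stably."""
    x = (np.asarray(d_m, dtype=float) - theta_m) / s_m
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out if out.shape else float(out)


def sample_available(habitat: GridRaster, n: int, seed: int) -> PointSet:
    """Uniform random locations within the habitat mask.

    A habitat cell is chosen uniformly among one-cells, then the point is
    placed uniformly within that cell, so the sample is uniform over the
    union of habitat cells.  Reproducible for a fixed seed.
    """
    if habitat.kind != "mask":
        raise TypeError(f"expected a habitat mask, got kind={habitat.kind!r}")
    if n < 0:
        raise ValueError("n must be >= 0")
    if n == 0:
        return PointSet(np.empty((0, 2)), label="available")
    rows, cols = np.nonzero(habitat.values == 1.0)
    if rows.size == 0:
        raise ValueError("habitat mask has no one-cells; cannot sample")
    rng = np.random.default_rng(seed)
    pick = rng.integers(0, rows.size, size=n)
    jitter = rng.random((n, 2))  # offsets within the cell, [0, 1)
    cs = habitat.cell_size
    x = habitat.origin_x + (cols[pick] + jitter[:, 0]) * cs
    y = habitat.origin_y - (rows[pick] + jitter[:, 1]) * cs
    return PointSet(np.column_stack([x, y]), label="available")


def summarize_shift(
    used_d: np.ndarray, avail_d: np.ndarray, cfg: ZoneConfig = ZoneConfig()
) -> UseAvailabilityResult:
    """Compare used vs available path-distance distributions.

    Inputs are distances in meters; the summary reports kilometers.  The
    shift in SD units divides by the *availability* sample SD (n-1
    denominator); it is None when that SD is zero.
    """
    used = np.asarray(used_d, dtype=float)
    avail = np.asarray(avail_d, dtype=float)
    if used.size == 0 or avail.size == 0:
        raise ValueError("used and available distance lists must be non-empty")
    mean_used = float(np.mean(used)) / 1000.0
    mean_avail = float(np.mean(avail)) / 1000.0
    sd_avail = float(np.std(avail, ddof=1)) / 1000.0 if avail.size > 1 else 0.0
    shift = mean_used - mean_avail
    shift_sd = shift / sd_avail if sd_avail > 0 else None
    frac_beyond = float(np.mean(used > cfg.foray_m))
    return UseAvailabilityResult(
        n_used=used.size,
        n_available=avail.size,
        mean_used_km=mean_used,
        mean_avail_km=mean_avail,
        sd_avail_km=sd_avail,
        shift_km=shift,
        shift_sd=shift_sd,
        frac_used_beyond_foray=frac_beyond,
    )


def _neg_loglik(theta: float, log_s: float, used, bin_idx, bin_centers, avail_dens) -> float:
    s = math.exp(log_s)
    w_used = avoidance_weight(used, theta, s)
    w_bins = avoidance_weight(bin_centers, theta, s)
    z = float(np.sum(w_bins * avail_dens))
    if z <= 0:
        return np.inf
    tiny = 1e-300
    ll = np.sum(np.log(w_used * avail_dens[bin_idx] + tiny)) - used.size * math.log(z)
    return -float(ll)


def fit_avoidance(
    used_d: np.ndarray, avail_d: np.ndarray, n_bins: int = 20
) -> AvoidanceModel:
    """Maximum-likelihood logistic avoidance fit.

    The likelihood of a used distance d is proportional to w(d) * a(d)
    where a is the empirical availability density over ``n_bins``
    equal-width bins spanning the pooled distance range.  A fixed coarse
    grid over (theta, s) is scanned first and the best point refined with
    Nelder-Mead, so the fit is deterministic for given inputs.
    """
    used = np.asarray(used_d, dtype=float)
    avail = np.asarray(avail_d, dtype=float)
    if used.size < 10 or avail.size < 10:
        raise FitError("need at least 10 used and 10 available distances")
    if n_bins < 4:
        raise ValueError("n_bins must be >= 4")
    pooled = np.concatenate([used, avail])
    lo, hi = float(pooled.min()), float(pooled.max())
    span = hi - lo
    if span <= 0:
        raise FitError("all distances identical; avoidance is unidentifiable")

    edges = np.linspace(lo, hi, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    counts, _ = np.histogram(avail, bins=edges)
    avail_dens = counts / counts.sum()
    bin_idx = np.clip(np.searchsorted(edges, used, side="right") - 1, 0, n_bins - 1)

    # coarse deterministic grid: theta spans below the data (flat-weight
    # limit) through the top of the range; s from sub-bin to beyond-range
    theta_grid = np.linspace(lo - 0.5 * span, hi, 49)
    s_grid = np.geomspace(span / 200.0, 2.0 * span, 25)
    best = (np.inf, 0.0, 0.0)
    for th in theta_grid:
        for s in s_grid:
            nll = _neg_loglik(th, math.log(s), used, bin_idx, centers, avail_dens)
            if nll < best[0]:
                best = (nll, th, s)
    if not np.isfinite(best[0]):
        raise FitError("likelihood degenerate over the whole search grid")

    res = optimize.minimize(
        lambda p: _neg_loglik(p[0], p[1], used, bin_idx, centers, avail_dens),
        x0=[best[1], math.log(best[2])],
        method="Nelder-Mead",
        options={"xatol": 1.0, "fatol": 1e-9, "maxiter": 2000},
    )
    theta, log_s = (res.x if res.fun <= best[0] else (best[1], math.log(best[2])))
    return AvoidanceModel(theta_m=float(theta), s_m=float(math.exp(log_s)))


def dog_density(n_free_roaming: int, area_km2: float) -> float:
    """Free-roaming dogs per km² (full precision; round only when reporting)."""
    if area_km2 <= 0:
        raise ValueError("area_km2 must be > 0")
    if n_free_roaming < 0:
        raise ValueError("dog count must be >= 0")
    return n_free_roaming / area_km2
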