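"""Use-versus-availability contrast between dog-pressure scenarios.

On one shared landscape, occurrences are simulated under a strong
avoidance response (midpoint at the 10.9 km foray distance, the
"many dogs" case) and a weak one (midpoint at the 1.92 km human-impact
distance, "few dogs"), then compared against 100 random available
locations.  The headline statistic is the shift of the used distance
mean in availability standard deviations.
"""

from dogedge import (
    LandscapeConfig,
    OccurrenceConfig,
    extract_values_at_points,
    fit_avoidance,
    generate_landscape,
    housing_density_surface,
    populated_mask,
    sample_available,
    simulate_occurrences,
    summarize_shift,
    surface_path_distance,
)

land = generate_landscape(LandscapeConfig(seed=0))
populated = populated_mask(housing_density_surface(land.residences, land.dem))
surface = surface_path_distance(land.dem, populated)

avail_pts = sample_available(land.habitat, 100, seed=1)
avail = extract_values_at_points(surface.raster, avail_pts)

for scenario in ("many_dogs", "few_dogs"):
    occ = simulate_occurrences(surface, land.habitat,
                               OccurrenceConfig(seed=0, scenario=scenario))
    used = extract_values_at_points(surface.raster, occ)
    res = summarize_shift(used, avail)
    print(f"{scenario:10s}: avail {res.mean_avail_km:4.1f} +/- {res.sd_avail_km:.1f} km | "
          f"used {res.mean_used_km:4.1f} km | shift {res.shift_km:4.1f} km "
          f"({res.shift_sd:+.1f} SD) | {100 * res.frac_used_beyond_foray:.0f}% beyond 10.9 km")

occ = simulate_occurrences(surface, land.habitat,
                           OccurrenceConfig(seed=0, n_occurrences=500,
                                            scenario="many_dogs"))
used = extract_values_at_points(surface.raster, occ)
avail_big = extract_values_at_points(
    surface.raster, sample_available(land.habitat, 2000, seed=2))
model = fit_avoidance(used, avail_big)
print(f"\nfitted avoidance midpoint: {model.theta_m:.0f} m "
      f"(generating value 10,900 m), softness {model.s_m:.0f} m")
print("A shift of ~2 SD with most occurrences beyond the foray distance is "
      "the avoidance signature; the weak scenario stays within 1 SD.")
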