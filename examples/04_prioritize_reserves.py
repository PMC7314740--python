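"""Reserve threat ranking with Jenks natural breaks.

Computes per-reserve dog-zone habitat on a synthetic landscape, classifies
each reserve against the fixed 50/165 km2 tier boundaries, and shows how
fresh boundaries would be re-derived from a value list with the exact
Jenks (Fisher) dynamic program.
"""

from dogedge import (
    LandscapeConfig,
    classify_threat,
    dog_zone_habitat_by_reserve,
    generate_landscape,
    housing_density_surface,
    jenks_breaks,
    populated_mask,
    surface_path_distance,
)

land = generate_landscape(LandscapeConfig(seed=0, n_reserves=5))
populated = populated_mask(housing_density_surface(land.residences, land.dem))
surface = surface_path_distance(land.dem, populated)

areas = dog_zone_habitat_by_reserve(land.reserves, land.habitat, surface)
print("reserve          dog-zone habitat   tier (fixed 50/165 km2 breaks)")
for rid, km2 in areas:
    print(f"{rid:15s}  {km2:10.1f} km2      {classify_threat(km2)}")

values = [km2 for _, km2 in areas]
res = jenks_breaks(values, k=3)
print(f"\nre-derived Jenks breaks for k=3: "
      f"{', '.join(f'{b:.1f}' for b in res.breaks)} km2 (GVF {res.gvf:.3f})")
print("GVF near 1 means the three tiers explain nearly all variance in "
      "dog-zone habitat area across reserves.")
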