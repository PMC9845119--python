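"""From a label scene to per-tree carbon and a per-hectare grid.

Runs the full chain on one synthetic 100 m x 100 m tile: separate crowns,
extract per-crown geometry, assign land-cover classes, apply the
class-specific allometric equations, and aggregate density, canopy cover
and carbon onto the hectare grid.
"""

from crownmap import (
    SceneConfig,
    aggregate_hectares,
    apply_carbon,
    assign_class,
    expand_crowns,
    extract_crowns,
    make_landcover,
    make_scene,
    separate_crowns,
)

mask, _ = make_scene(
    SceneConfig(seed=7, grid_shape=(400, 400), pixel_size=0.25, n_crowns=200, clump_fraction=0.4)
)
scene = separate_crowns(mask)
records = extract_crowns(scene)  # drops crowns below 0.25 m^2

layer = make_landcover((0.0, -100.0, 100.0, 0.0), n_polygons=5, seed=8)
records = assign_class(records, layer, default_class="savanna_shrubland")
records = apply_carbon(records, E=0.5)  # E: environmental stress for the forest equation

cover = expand_crowns(records, scene, expansion=0.27)  # undo the 27% prediction shrinkage
grid = aggregate_hectares(records, cover, (0.0, 0.0), (1, 1))

print(f"trees retained (>= 0.25 m^2): {len(records)}")
print(f"tree density:                 {grid.density[0, 0]:.0f} trees/ha")
print(f"canopy cover:                 {grid.cover_pct[0, 0]:.1f} %")
print(f"carbon density:               {grid.carbon_mgc_ha[0, 0]:.2f} MgC/ha")
biggest = max(records, key=lambda r: r.agc_kg)
print(
    f"largest tree: CD {biggest.cd_m:.1f} m -> DBH {biggest.dbh_cm:.1f} cm -> "
    f"AGC {biggest.agc_kg:.0f} kg ({biggest.landcover})"
)

# Density counts crown centroids per hectare cell; cover is the dissolved
# area of the expanded crowns; carbon sums the per-tree estimates, which
# depend on each tree's land-cover class through the equation routing.
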