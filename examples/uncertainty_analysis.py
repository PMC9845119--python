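"""Quantify the uncertainty of the carbon estimates.

Shows the three evaluation tools on synthetic data: plot-level comparison
of predicted against field carbon, the area-weighted national uncertainty
built from per-class biases, and the half-sample regression ensemble that
isolates the contribution of the CD -> DBH conversion.
"""

import numpy as np
from shapely.geometry import box

from crownmap import (
    AllometryTableConfig,
    SceneConfig,
    apply_carbon,
    assign_class,
    ensemble_uncertainty,
    extract_crowns,
    make_allometry_table,
    make_landcover,
    make_scene,
    national_uncertainty,
    plot_level_eval,
    separate_crowns,
)
from crownmap.allometry import default_dispatch

mask, _ = make_scene(SceneConfig(seed=3, grid_shape=(400, 400), pixel_size=0.25, n_crowns=200))
scene = separate_crowns(mask)
records = extract_crowns(scene)
records = assign_class(records, make_landcover((0, -100, 100, 0), 5, seed=4),
                       default_class="farmland")
records = apply_carbon(records, E=0.5)

# plot-level evaluation against noisy synthetic "field" totals
rng = np.random.default_rng(5)
plots, field = {}, {}
for i in range(16):
    x0, y0 = 25.0 * (i % 4), -25.0 * (i // 4)
    plots[f"p{i}"] = box(x0, y0 - 25, x0 + 25, y0)
pairs, _ = plot_level_eval(records, plots, {p: 1.0 for p in plots})
for p, pred in zip(pairs["plot_id"], pairs["y_pred"]):
    field[p] = max(float(pred), 1.0) * float(np.exp(rng.normal(0, 0.2)))
pairs, stats = plot_level_eval(records, plots, field)
print(f"plot-level rRMSE: {stats['rrmse_pct']:.1f} %   "
      f"mean relative bias: {stats['bias_relative_pct']:+.1f} %   "
      f"summed-stock bias: {stats['bias_summed']:.3f}")

# area-weighted national uncertainty from per-class biases
report = national_uncertainty(
    per_stratum_bias={"farmland": 5.9, "savanna_shrubland": 18.9, "natural_forest": 26.0},
    area_weights={"farmland": 0.55, "savanna_shrubland": 0.35, "natural_forest": 0.10},
)
print(f"area-weighted national uncertainty: {report.national_uncertainty_pct:.1f} %")

# half-sample ensemble: spread of hectare carbon under regression resampling
table = make_allometry_table(AllometryTableConfig(seed=6, n_trees=2000, noise_lognormal_sd=0.3))
ens = ensemble_uncertainty(table[["cd_m", "dbh_cm"]], records, default_dispatch(E=0.5),
                           seeds=(1, 2, 3, 4))
for cls, val in ens.items():
    if cls != "n_runs_used":
        print(f"ensemble rRMSE [{cls}]: {val:.2f} %")

# The ensemble refits the CD->DBH line on four random halves of the field
# table; the sd/mean of each hectare's carbon across those fits measures
# how much the regression's sampling variability moves the final map.
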