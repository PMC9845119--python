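"""Bias metrics and uncertainty propagation for the carbon estimates.

Two bias definitions are used when comparing predictions against field
plots: the mean relative error in percent, bias = (1/N) sum (obs - pred) /
obs * 100, and the magnitude of the summed error, |sum(obs - pred)| /
|sum obs|, which measures stock-level (rather than plot-level) agreement.
Class biases are combined into a single national figure by weighting with
the relative area of each class. The contribution of the CD -> DBH
regression is quantified by an ensemble: refit the regression on several
random half-samples of the field table, re-predict every tree's carbon
with each fit, aggregate per hectare and take the relative spread (sd /
mean) across fits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Point
from shapely.geometry.base import BaseGeometry

from .allometry import (
    EquationChain,
    agb_from_dbh,
    agc_from_agb,
    dbh_from_cd,
    fit_log_ma_baskerville,
    fit_major_axis,
)
from .geometry import TreeRecord

__all__ = [
    "BiasReport",
    "bias_relative",
    "bias_summed",
    "national_uncertainty",
    "ensemble_uncertainty",
    "plot_level_eval",
]


def _pairs(y_obs, y_pred) -> tuple[np.ndarray, np.ndarray]:
    obs = np.asarray(y_obs, dtype=float)
    pred = np.asarray(y_pred, dtype=float)
    if obs.shape != pred.shape:
        raise ValueError(f"mismatched pair shapes {obs.shape} vs {pred.shape}")
    if not (np.isfinite(obs).all() and np.isfinite(pred).all()):
        raise ValueError("observed and predicted values must be finite")
    return obs, pred


def bias_relative(y_obs, y_pred) -> float:
    """Mean relative systematic error in percent: (1/N) sum (obs-pred)/obs * 100."""
    obs, pred = _pairs(y_obs, y_pred)
    if np.any(obs == 0):
        raise ValueError("relative bias is undefined when any observed value is 0")
    return float(np.mean((obs - pred) / obs) * 100.0)


def bias_summed(y_obs, y_pred) -> float:
    """Stock-level error as a fraction: |sum(obs - pred)| / |sum obs|."""
    obs, pred = _pairs(y_obs, y_pred)
    denom = obs.sum()
    if denom == 0:
        raise ValueError("summed bias is undefined when observed values sum to 0")
    return float(abs((obs - pred).sum()) / abs(denom))


@dataclass(frozen=True)
class BiasReport:
    """Per-class bias (%) plus the area-weighted national figure."""

    per_stratum_bias: dict[str, float]
    area_weights: dict[str, float]
    national_uncertainty_pct: float


def national_uncertainty(
    per_stratum_bias: Mapping[str, float],
    area_weights: Mapping[str, float],
) -> BiasReport:
    """Combine class biases into one national uncertainty percentage.

    The weights are each class's fraction of the total area and must sum
    to 1; bias magnitudes are used so that over- and under-estimation in
    different classes cannot cancel.
    """
    missing = set(area_weights) ^ set(per_stratum_bias)
    if missing:
        raise ValueError(f"strata present on one side only: {sorted(missing)}")
    weights = np.array([area_weights[k] for k in sorted(area_weights)], dtype=float)
    if np.any(weights < 0):
        raise ValueError("area weights must be >= 0")
    if abs(weights.sum() - 1.0) > 1e-9:
        raise ValueError(f"area weights must sum to 1, got {weights.sum()!r}")
    total = sum(area_weights[k] * abs(per_stratum_bias[k]) for k in area_weights)
    return BiasReport(
        per_stratum_bias=dict(per_stratum_bias),
        area_weights=dict(area_weights),
        national_uncertainty_pct=float(total),
    )


def ensemble_uncertainty(
    cd_dbh_table: pd.DataFrame,
    records: Sequence[TreeRecord],
    dispatch: Mapping[str, EquationChain],
    k_runs: int = 4,
    subsample: float = 0.5,
    seeds: Sequence[int] = (1, 2, 3, 4),
    form: str = "linear_ma",
    grid_origin: tuple[float, float] = (0.0, 0.0),
    cell_size: float = 100.0,
) -> dict[str, float]:
    """Per-class relative RMSE of hectare carbon across half-sample refits.

    Fits ``k_runs`` CD -> DBH models, each on a seeded random half of the
    field table, predicts every tree's carbon under each fit (keeping the
    class-specific biomass equation fixed), sums carbon per hectare cell,
    and computes sd/mean across the runs per cell; the per-class value is
    the mean over that class's cells, in percent. Returns a dict keyed by
    class, plus ``n_runs_used``. Degenerate fits are dropped and logged in
    ``n_runs_used``.
    """
    if len(cd_dbh_table) < 6:
        raise ValueError("field table too small for half-sampling (need n >= 6)")
    if len(seeds) != k_runs:
        raise ValueError(f"need {k_runs} seeds, got {len(seeds)}")
    cd = cd_dbh_table["cd_m"].to_numpy(dtype=float)
    dbh = cd_dbh_table["dbh_cm"].to_numpy(dtype=float)
    fit = fit_major_axis if form == "linear_ma" else fit_log_ma_baskerville
    n = cd.size
    n_sub = max(3, int(round(n * subsample)))
    models = []
    for seed in seeds:
        rng = np.random.default_rng(seed)
        idx = rng.choice(n, size=n_sub, replace=False)
        try:
            models.append(fit(cd[idx], dbh[idx]))
        except ValueError:
            continue  # degenerate half-sample; reported via n_runs_used
    if len(models) < 2:
        raise ValueError("fewer than two non-degenerate ensemble fits; cannot form a spread")

    x0, y0 = grid_origin
    cells: dict[tuple[str, int, int], np.ndarray] = {}
    for rec in records:
        if rec.landcover is None:
            raise ValueError(f"tree {rec.tree_id} has no land-cover class")
        chain = dispatch[rec.landcover]
        x, y = rec.centroid_xy
        key = (
            rec.landcover,
            math.floor((y0 - y) / cell_size),
            math.floor((x - x0) / cell_size),
        )
        agc = np.empty(len(models))
        for i, model in enumerate(models):
            d = float(dbh_from_cd(rec.cd_m, model))
            agb = float(agb_from_dbh(d, chain.agb_equation)) if d > 0 else 0.0
            agc[i] = agc_from_agb(agb)
        cells[key] = cells.get(key, 0.0) + agc

    per_class: dict[str, list[float]] = {}
    for (cls, _, _), totals in cells.items():
        mean = totals.mean()
        sd = totals.std(ddof=1)
        if mean == 0.0:
            rrmse = 0.0 if sd == 0.0 else float("nan")
        else:
            rrmse = sd / mean * 100.0
        if math.isfinite(rrmse):
            per_class.setdefault(cls, []).append(rrmse)
    out = {cls: float(np.mean(vals)) for cls, vals in sorted(per_class.items())}
    out["n_runs_used"] = float(len(models))
    return out


def plot_level_eval(
    records: Sequence[TreeRecord],
    plots: Mapping[str, BaseGeometry],
    field_values: Mapping[str, float],
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Compare summed predicted carbon against field totals per plot.

    Sums the predicted AGC of trees whose centroids fall inside each plot
    polygon (plots with no predicted tree keep a prediction of 0) and
    reports rRMSE = RMSE / mean(obs) in percent together with both bias
    definitions. Field values must use the same unit as the records' AGC.
    """
    missing = set(plots) - set(field_values)
    if missing:
        raise ValueError(f"field value missing for plots: {sorted(missing)}")
    rows = []
    for plot_id in plots:
        geom = plots[plot_id]
        pred = 0.0
        for rec in records:
            if rec.agc_kg is None:
                raise ValueError(f"tree {rec.tree_id} has no carbon estimate")
            if geom.covers(Point(*rec.centroid_xy)):
                pred += rec.agc_kg
        rows.append({"plot_id": plot_id, "y_obs": float(field_values[plot_id]), "y_pred": pred})
    pairs = pd.DataFrame(rows, columns=["plot_id", "y_obs", "y_pred"])
    obs = pairs["y_obs"].to_numpy()
    pred = pairs["y_pred"].to_numpy()
    rmse = float(np.sqrt(np.mean((obs - pred) ** 2)))
    stats = {
        "rmse": rmse,
        "rrmse_pct": rmse / float(np.mean(obs)) * 100.0 if np.mean(obs) != 0 else float("nan"),
        "bias_relative_pct": bias_relative(obs, pred) if np.all(obs != 0) else float("nan"),
        "bias_summed": bias_summed(obs, pred),
    }
    return pairs, stats
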