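"""Synthetic inputs with known ground truth.

Every downstream module is exercised on generated data: clumped
circular/elliptical crown scenes with true instance labels (standing in
for segmentation-model predictions), field-style CD/DBH/AGB tables drawn
from the calibrated allometric equations plus configurable noise, and
random rectangular land-cover layers. All generators are pure functions
of their configuration, seed included.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from shapely.geometry import box

from . import allometry
from .dcr import CentreSet, CrownMask, LabelScene
from .stratify import LandCoverFeature, LandCoverLayer

__all__ = [
    "SceneConfig",
    "AllometryTableConfig",
    "make_scene",
    "make_allometry_table",
    "make_landcover",
]


@dataclass(frozen=True)
class SceneConfig:
    """Layout of a synthetic crown scene.

    Crown radii (metres) are lognormal, by default lognormal(ln 1.0, 0.6),
    which keeps most crowns in the 0.25-3 m^2 range that dominates real
    scenes. ``clump_fraction`` is the fraction of crowns deliberately
    placed touching an earlier crown; the rest are placed with a clear
    gap so they stay separable. ``aspect_range`` > (1, 1) draws ellipses.
    """

    seed: int
    grid_shape: tuple[int, int] = (256, 256)
    pixel_size: float = 0.25
    n_crowns: int = 20
    radius_mu_log: float = 0.0  # ln(1.0 m)
    radius_sigma_log: float = 0.6
    clump_fraction: float = 0.0
    aspect_range: tuple[float, float] = (1.0, 1.0)
    max_tries: int = 500

    def __post_init__(self) -> None:
        if not 0.0 <= self.clump_fraction <= 1.0:
            raise ValueError("clump_fraction must be in [0, 1]")
        if self.n_crowns < 0 or self.pixel_size <= 0:
            raise ValueError("n_crowns must be >= 0 and pixel_size > 0")


def _disk_pixels(
    centre: tuple[float, float],
    radii_px: tuple[float, float],
    angle: float,
    shape: tuple[int, int],
) -> tuple[np.ndarray, np.ndarray]:
    """Pixels inside a rotated ellipse; a pixel belongs if its centre is inside."""
    r0, c0 = centre
    a, b = radii_px
    rmax = max(a, b)
    rlo = max(0, int(math.floor(r0 - rmax)))
    rhi = min(shape[0], int(math.ceil(r0 + rmax)) + 1)
    clo = max(0, int(math.floor(c0 - rmax)))
    chi = min(shape[1], int(math.ceil(c0 + rmax)) + 1)
    if rlo >= rhi or clo >= chi:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    rr, cc = np.mgrid[rlo:rhi, clo:chi]
    dr = rr - r0
    dc = cc - c0
    ca, sa = math.cos(angle), math.sin(angle)
    u = dr * ca + dc * sa
    v = -dr * sa + dc * ca
    inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    return rr[inside], cc[inside]


def make_scene(cfg: SceneConfig) -> tuple[CrownMask, LabelScene]:
    """Rasterize a random crown layout; returns the binary mask and the truth.

    Crowns are placed sequentially; later-placed crowns own contested
    pixels in the ground-truth labels. Non-clumped crowns are rejected
    until they keep at least a two-pixel gap to everything placed before,
    so with ``clump_fraction = 0`` all crowns are disjoint and separable.
    Raises if a crown cannot be placed within ``max_tries`` attempts.
    """
    rng = np.random.default_rng(cfg.seed)
    nrow, ncol = cfg.grid_shape
    truth = np.zeros((nrow, ncol), dtype=np.int32)
    placed: list[tuple[float, float, float]] = []  # (row, col, radius_px)
    centres: list[tuple[int, int]] = []
    for i in range(cfg.n_crowns):
        radius_m = float(rng.lognormal(cfg.radius_mu_log, cfg.radius_sigma_log))
        r_px = max(1.0, radius_m / cfg.pixel_size)
        aspect = float(rng.uniform(*cfg.aspect_range))
        angle = float(rng.uniform(0.0, math.pi))
        radii = (r_px, r_px / aspect)
        clump = bool(placed) and (rng.random() < cfg.clump_fraction)
        ok = False
        for _ in range(cfg.max_tries):
            if clump:
                ar, ac, arad = placed[int(rng.integers(len(placed)))]
                theta = rng.uniform(0.0, 2.0 * math.pi)
                dist = (arad + r_px) * rng.uniform(0.5, 0.95)  # guaranteed overlap/touch
                r0 = ar + dist * math.sin(theta)
                c0 = ac + dist * math.cos(theta)
                if not (0 <= r0 < nrow and 0 <= c0 < ncol):
                    continue
                ok = True
                break
            r0 = float(rng.uniform(r_px, nrow - r_px)) if nrow > 2 * r_px else float(rng.uniform(0, nrow))
            c0 = float(rng.uniform(r_px, ncol - r_px)) if ncol > 2 * r_px else float(rng.uniform(0, ncol))
            # demand a 2 px boundary gap to every earlier crown
            if all(math.hypot(r0 - pr, c0 - pc) >= r_px + prad + 2.0 for pr, pc, prad in placed):
                ok = True
                break
        if not ok:
            raise RuntimeError(
                f"could not place crown {i + 1}/{cfg.n_crowns} after {cfg.max_tries} tries; "
                f"achieved {len(placed)} crowns"
            )
        rr, cc = _disk_pixels((r0, c0), radii, angle, (nrow, ncol))
        if rr.size == 0:  # degenerate placement entirely off-grid
            rr = np.array([min(nrow - 1, max(0, int(round(r0))))])
            cc = np.array([min(ncol - 1, max(0, int(round(c0))))])
        truth[rr, cc] = i + 1  # later crown wins contested pixels
        placed.append((r0, c0, max(radii)))
        centres.append((int(round(r0)), int(round(c0))))
    mask = CrownMask(pixels=(truth > 0).astype(np.uint8), pixel_size=cfg.pixel_size)
    scene = LabelScene(
        labels=truth,
        centres=CentreSet(centres=tuple(centres), m=0),
        pixel_size=cfg.pixel_size,
        origin=mask.origin,
    )
    return mask, scene


@dataclass(frozen=True)
class AllometryTableConfig:
    """Field-table generator settings.

    CD is lognormal in metres; DBH comes from the configured generating
    model (the linear open-grown line by default, or the log-log forest
    model) and AGB from the configured power law. Noise is either additive
    Gaussian on DBH (``noise_dbh_sd``, cm; optionally also on CD via
    ``noise_cd_sd``) or median-preserving multiplicative lognormal
    (``noise_lognormal_sd``, log units). Noiseless truth columns are kept
    for recovery tests.
    """

    seed: int
    n_trees: int = 1000
    cd_mu_log: float = math.log(3.0)
    cd_sigma_log: float = 0.4
    dbh_model: allometry.AllometricModel = allometry.EQ_LINEAR_OPEN
    agb_equation: allometry.AGBEquation = allometry.AGB_SAVANNA
    noise_dbh_sd: float = 0.0
    noise_cd_sd: float = 0.0
    noise_lognormal_sd: float = 0.0
    noise_agb_lognormal_sd: float = 0.0

    def __post_init__(self) -> None:
        for name in ("noise_dbh_sd", "noise_cd_sd", "noise_lognormal_sd", "noise_agb_lognormal_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def make_allometry_table(cfg: AllometryTableConfig) -> pd.DataFrame:
    """Draw a synthetic CD/DBH/AGB field table from the calibrated equations."""
    rng = np.random.default_rng(cfg.seed)
    cd_true = rng.lognormal(cfg.cd_mu_log, cfg.cd_sigma_log, size=cfg.n_trees)
    dbh_true = np.asarray(allometry.dbh_from_cd(cd_true, cfg.dbh_model), dtype=float)
    agb_true = np.asarray(allometry.agb_from_dbh(dbh_true, cfg.agb_equation), dtype=float)
    cd = cd_true + (rng.normal(0.0, cfg.noise_cd_sd, cfg.n_trees) if cfg.noise_cd_sd else 0.0)
    dbh = dbh_true + (rng.normal(0.0, cfg.noise_dbh_sd, cfg.n_trees) if cfg.noise_dbh_sd else 0.0)
    if cfg.noise_lognormal_sd:
        dbh = dbh * np.exp(rng.normal(0.0, cfg.noise_lognormal_sd, cfg.n_trees))
    agb = agb_true.copy()
    if cfg.noise_agb_lognormal_sd:
        agb = agb * np.exp(rng.normal(0.0, cfg.noise_agb_lognormal_sd, cfg.n_trees))
    return pd.DataFrame(
        {
            "cd_true_m": cd_true,
            "dbh_true_cm": dbh_true,
            "agb_true_kg": agb_true,
            "cd_m": cd,
            "dbh_cm": dbh,
            "agb_kg": agb,
        }
    )


def make_landcover(
    grid_extent: tuple[float, float, float, float],
    n_polygons: int,
    classes: Sequence[str] = allometry.LANDCOVER_CLASSES,
    seed: int = 0,
    max_tries: int = 200,
) -> LandCoverLayer:
    """Random disjoint class rectangles tiling part of the extent.

    ``grid_extent`` is (xmin, ymin, xmax, ymax) in world coordinates. Each
    rectangle gets a class cycled-then-shuffled from ``classes``; overlap
    with earlier rectangles is rejected so assignments are unambiguous.
    """
    rng = np.random.default_rng(seed)
    xmin, ymin, xmax, ymax = grid_extent
    w = xmax - xmin
    h = ymax - ymin
    features: list[LandCoverFeature] = []
    rects = []
    for i in range(n_polygons):
        for _ in range(max_tries):
            rw = rng.uniform(0.15, 0.45) * w
            rh = rng.uniform(0.15, 0.45) * h
            rx = rng.uniform(xmin, xmax - rw)
            ry = rng.uniform(ymin, ymax - rh)
            rect = box(rx, ry, rx + rw, ry + rh)
            if all(not rect.intersects(other) for other in rects):
                rects.append(rect)
                cls = classes[int(rng.integers(len(classes)))]
                features.append(
                    LandCoverFeature(geometry=rect, landcover=cls, protected=bool(rng.random() < 0.2))
                )
                break
        # a rectangle that cannot be placed without overlap is simply skipped
    return LandCoverLayer(features=features)
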