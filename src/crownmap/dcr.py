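"""Detect-centre-and-relabel (DCR) separation of clumped tree crowns.

A binary crown mask produced by a segmentation model merges touching
crowns into single blobs. DCR splits them under the assumption that
crowns are roughly round: the Euclidean distance transform peaks near
crown centres, local maxima of the transform are taken as instance
centres, and every foreground pixel is assigned to the nearest centre
under a distance that penalises crossing background, so a pixel is never
attached to a centre across a canopy gap. A final pass fills artificial
holes left inside single crowns.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage.draw import line as bresenham_line

__all__ = [
    "CrownMask",
    "DistanceMap",
    "CentreSet",
    "LabelScene",
    "distance_transform",
    "detect_centres",
    "relabel",
    "fill_holes",
    "dcr",
]

_EIGHT = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class CrownMask:
    """Binary crown raster with georeferencing carried alongside.

    ``origin`` is the world coordinate of the top-left corner of pixel
    (0, 0) in a north-up frame: x grows with columns, y shrinks with rows.
    """

    pixels: np.ndarray
    pixel_size: float = 1.0
    origin: tuple[float, float] = (0.0, 0.0)
    crs_tag: str | None = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError(f"mask must be 2-D, got shape {px.shape}")
        bad = np.setdiff1d(np.unique(px), [0, 1])
        if bad.size:
            raise ValueError(f"mask must be binary; found values {bad.tolist()}")
        if not self.pixel_size > 0:
            raise ValueError(f"pixel_size must be > 0, got {self.pixel_size}")
        object.__setattr__(self, "pixels", px.astype(np.uint8, copy=False))


@dataclass(frozen=True)
class DistanceMap:
    """Euclidean distance (in pixels) to the nearest background pixel."""

    values: np.ndarray


@dataclass(frozen=True)
class CentreSet:
    """Instance centres in row-major order, one per distance-transform plateau."""

    centres: tuple[tuple[int, int], ...]
    m: int = 3

    def __len__(self) -> int:
        return len(self.centres)


@dataclass(frozen=True)
class LabelScene:
    """Integer instance raster (0 = background) plus its provenance."""

    labels: np.ndarray
    centres: CentreSet = field(default_factory=lambda: CentreSet(()))
    penalty_weight: float = 0.0
    pixel_size: float = 1.0
    origin: tuple[float, float] = (0.0, 0.0)
    crs_tag: str | None = None

    @property
    def n_instances(self) -> int:
        labels = self.labels
        return int(labels.max()) if labels.size else 0


def distance_transform(mask: CrownMask) -> DistanceMap:
    """Euclidean distance of each crown pixel to the nearest background pixel.

    The image border counts as background, so crowns truncated by a tile
    edge still get a finite distance ridge. Background pixels hold 0.
    """
    px = mask.pixels
    padded = np.pad(px, 1, mode="constant", constant_values=0)
    dt = ndimage.distance_transform_edt(padded)[1:-1, 1:-1]
    return DistanceMap(values=dt)


def detect_centres(dt: DistanceMap, m: int = 3) -> CentreSet:
    """Find instance centres as local maxima of the distance transform.

    A pixel is a candidate when its distance value survives an ``m`` x ``m``
    maximum filter unchanged; 8-connected candidate plateaus (flat ridges of
    equal distance) collapse to a single centre, the plateau pixel with the
    smallest row-major index. ``m`` controls the minimum separation between
    centres and should match the smallest crown to be split.
    """
    if m < 1 or m % 2 == 0:
        raise ValueError(f"max-filter size m must be odd and >= 1, got {m}")
    values = dt.values
    filtered = ndimage.maximum_filter(values, size=m, mode="constant", cval=0.0)
    candidates = (values > 0) & (values == filtered)
    plateau_labels, n_plateaus = ndimage.label(candidates, structure=_EIGHT)
    centres: list[tuple[int, int]] = []
    for lab in range(1, n_plateaus + 1):
        rows, cols = np.nonzero(plateau_labels == lab)
        flat = rows * values.shape[1] + cols
        k = int(np.argmin(flat))
        centres.append((int(rows[k]), int(cols[k])))
    centres.sort()  # row-major order
    return CentreSet(centres=tuple(centres), m=m)


def _background_count(start: tuple[int, int], end: tuple[int, int], fg: np.ndarray) -> int:
    """Background pixels on the Bresenham line from start to end, endpoints excluded."""
    rr, cc = bresenham_line(start[0], start[1], end[0], end[1])
    if rr.size <= 2:
        return 0
    return int(np.count_nonzero(~fg[rr[1:-1], cc[1:-1]]))


def relabel(mask: CrownMask, centres: CentreSet, penalty_weight: float | None = None) -> LabelScene:
    """Assign every crown pixel to its best centre.

    The distance from pixel x to centre c is ``|x - c| + lambda * B(x, c)``
    where B counts background pixels on the straight pixel line between
    them (endpoints excluded), so with a large penalty no pixel is claimed
    across a canopy gap. Ties go to the smallest centre index. The default
    penalty is the grid diagonal in pixels, which makes any assignment
    crossing even one background pixel worse than any gap-free one.
    """
    px = mask.pixels
    fg = px.astype(bool)
    if penalty_weight is None:
        penalty_weight = float(np.hypot(*px.shape))
    if penalty_weight < 0:
        raise ValueError(f"penalty_weight must be >= 0, got {penalty_weight}")
    if len(centres) == 0:
        if fg.any():
            raise ValueError(
                "no centres supplied for a non-empty mask; treat the scene as "
                "zero crowns explicitly or lower the max-filter size m"
            )
        return LabelScene(
            labels=np.zeros_like(px, dtype=np.int32),
            centres=centres,
            penalty_weight=penalty_weight,
            pixel_size=mask.pixel_size,
            origin=mask.origin,
            crs_tag=mask.crs_tag,
        )

    centre_arr = np.asarray(centres.centres, dtype=float)
    labels = np.zeros_like(px, dtype=np.int32)
    rows, cols = np.nonzero(fg)
    lam = float(penalty_weight)
    for r, c in zip(rows.tolist(), cols.tolist()):
        # integer squares are exact in floats, so this sqrt is reproducible bit-for-bit
        d_euc = np.sqrt((centre_arr[:, 0] - r) ** 2 + (centre_arr[:, 1] - c) ** 2)
        order = np.argsort(d_euc, kind="stable")
        best_idx = -1
        best_d = np.inf
        for k in order.tolist():
            de = d_euc[k]
            if de > best_d:
                break  # penalties are non-negative: nothing later can win
            if lam > 0:
                d = de + lam * _background_count(centres.centres[k], (r, c), fg)
            else:
                d = de
            if d < best_d or (d == best_d and k < best_idx):
                best_d = d
                best_idx = k
        labels[r, c] = best_idx + 1
    return LabelScene(
        labels=labels,
        centres=centres,
        penalty_weight=lam,
        pixel_size=mask.pixel_size,
        origin=mask.origin,
        crs_tag=mask.crs_tag,
    )


def fill_holes(scene: LabelScene) -> LabelScene:
    """Fill gaps enclosed inside a single crown.

    A background region is filled when it is not 4-connected to the image
    exterior and every labelled pixel touching it (8-neighbourhood) carries
    the same label. Gaps between two different crowns, and corridors open
    to the scene edge, are left alone.
    """
    labels = scene.labels.copy()
    background = labels == 0
    # 4-connected background components; the default ndimage structure is the cross
    comp, n_comp = ndimage.label(background)
    if n_comp == 0:
        return replace(scene, labels=labels)
    # components touching the border are connected to the exterior
    border = np.zeros_like(background)
    border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
    exterior_ids = np.unique(comp[border & background])
    exterior = np.isin(np.arange(n_comp + 1), exterior_ids)
    for cid in range(1, n_comp + 1):
        if exterior[cid]:
            continue
        region = comp == cid
        ring = ndimage.binary_dilation(region, structure=_EIGHT) & ~region
        neighbours = np.unique(labels[ring])
        neighbours = neighbours[neighbours > 0]
        if neighbours.size == 1:
            labels[region] = neighbours[0]
    return replace(scene, labels=labels)


def dcr(
    mask: CrownMask,
    m: int = 3,
    penalty_weight: float | None = None,
) -> LabelScene:
    """Full crown-separation pipeline on one tile.

    Runs distance transform -> centre detection -> penalised relabelling ->
    hole filling. Deterministic: identical inputs give bit-identical labels.
    An empty mask yields a scene with zero instances.
    """
    dt = distance_transform(mask)
    centres = detect_centres(dt, m=m)
    if len(centres) == 0 and not mask.pixels.any():
        lam = float(np.hypot(*mask.pixels.shape)) if penalty_weight is None else penalty_weight
        return LabelScene(
            labels=np.zeros_like(mask.pixels, dtype=np.int32),
            centres=centres,
            penalty_weight=lam,
            pixel_size=mask.pixel_size,
            origin=mask.origin,
            crs_tag=mask.crs_tag,
        )
    scene = relabel(mask, centres, penalty_weight)
    return fill_holes(scene)
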