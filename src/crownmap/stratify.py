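"""Land-cover stratification: route each tree to its allometric chain.

The study area is stratified into six broad classes (natural forest,
savannas and shrublands, Eucalyptus and non-Eucalyptus plantations,
farmland, urban/built-up), optionally split into protected and
non-protected areas. Each tree is assigned the class of the polygon or
raster cell containing its crown centroid.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import math

import numpy as np
from shapely.geometry import Point
from shapely.geometry.base import BaseGeometry

from .allometry import LANDCOVER_CLASSES, replace_record
from .geometry import TreeRecord

__all__ = ["LandCoverFeature", "LandCoverLayer", "assign_class", "OUTSIDE_LAYER_FLAG"]

OUTSIDE_LAYER_FLAG = "outside_landcover_layer"


@dataclass(frozen=True)
class LandCoverFeature:
    geometry: BaseGeometry
    landcover: str
    protected: bool | None = None


@dataclass
class LandCoverLayer:
    """Six-class stratification, as polygons or a categorical raster.

    Polygon layers keep file order, which also resolves boundary ties.
    Raster layers carry a value map from integer codes to class names
    (0 is reserved for nodata).
    """

    features: list[LandCoverFeature] | None = None
    raster: np.ndarray | None = None
    value_map: dict[int, str] | None = None
    pixel_size: float = 1.0
    origin: tuple[float, float] = (0.0, 0.0)
    crs_tag: str | None = None

    def __post_init__(self) -> None:
        if (self.features is None) == (self.raster is None):
            raise ValueError("provide exactly one of features (polygons) or raster")
        if self.features is not None:
            for feat in self.features:
                _check_class(feat.landcover)
        else:
            if self.value_map is None:
                raise ValueError("a categorical raster needs a value_map")
            for code, cls in self.value_map.items():
                if code == 0:
                    raise ValueError("raster code 0 is reserved for nodata/background")
                _check_class(cls)

    def class_at(self, x: float, y: float) -> str | None:
        """Class containing the point, or None when outside every feature."""
        if self.features is not None:
            pt = Point(x, y)
            for feat in self.features:  # first feature in file order wins on boundaries
                if feat.geometry.covers(pt):
                    return feat.landcover
            return None
        x0, y0 = self.origin
        col = math.floor((x - x0) / self.pixel_size)
        row = math.floor((y0 - y) / self.pixel_size)
        nrow, ncol = self.raster.shape
        if not (0 <= row < nrow and 0 <= col < ncol):
            return None
        code = int(self.raster[row, col])
        if code == 0:
            return None
        return self.value_map[code]


def _check_class(value: str) -> None:
    if value not in LANDCOVER_CLASSES:
        raise ValueError(
            f"unknown land-cover class {value!r}; expected one of {list(LANDCOVER_CLASSES)}"
        )


def assign_class(
    records: Sequence[TreeRecord],
    layer: LandCoverLayer,
    default_class: str,
    crs_tag: str | None = None,
) -> list[TreeRecord]:
    """Give every tree the land-cover class at its centroid.

    Trees outside every feature get ``default_class`` and an
    ``outside_landcover_layer`` flag. Coordinate frames must match when
    both sides declare one; no silent reprojection is attempted.
    """
    _check_class(default_class)
    if crs_tag is not None and layer.crs_tag is not None and crs_tag != layer.crs_tag:
        raise ValueError(
            f"coordinate frame mismatch: trees are in {crs_tag!r} but the layer is in "
            f"{layer.crs_tag!r}; reproject one side explicitly"
        )
    out: list[TreeRecord] = []
    for rec in records:
        cls = layer.class_at(*rec.centroid_xy)
        flags = list(rec.flags)
        if cls is None:
            cls = default_class
            if OUTSIDE_LAYER_FLAG not in flags:
                flags.append(OUTSIDE_LAYER_FLAG)
        out.append(replace_record(rec, landcover=cls, flags=flags))
    return out
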