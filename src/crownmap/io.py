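"""File formats: georeferenced TIFF rasters, GeoJSON vectors, CSV tables.

Rasters are written as single-band TIFFs carrying the two standard
GeoTIFF georeferencing tags (ModelPixelScale and ModelTiepoint) plus the
coordinate-frame tag in the image description, enough for any GIS to
place the grid. Vector layers are plain GeoJSON. Fitted allometric
models round-trip through a plain-text key=value file whose floats are
written with ``repr`` and therefore restore bit-exactly.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry

from .allometry import AllometricModel
from .dcr import CentreSet, CrownMask, LabelScene
from .geometry import HectareGrid, TreeRecord, frame_to_records, records_to_frame
from .stratify import LandCoverFeature, LandCoverLayer

__all__ = [
    "write_raster",
    "read_mask",
    "write_labels",
    "read_labels",
    "write_grid",
    "write_centres_csv",
    "write_tree_csv",
    "read_tree_csv",
    "write_geojson",
    "read_landcover_geojson",
    "write_landcover_geojson",
    "save_model",
    "load_model",
]

_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922


def write_raster(
    path: str | Path,
    data: np.ndarray,
    pixel_size: float,
    origin: tuple[float, float],
    crs_tag: str | None = None,
) -> None:
    """Write a single-band raster with GeoTIFF placement tags."""
    x0, y0 = origin
    desc = json.dumps({"crs": crs_tag}, sort_keys=True)
    extratags = [
        (_TAG_PIXEL_SCALE, "d", 3, (float(pixel_size), float(pixel_size), 0.0)),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, float(x0), float(y0), 0.0)),
    ]
    tifffile.imwrite(path, data, description=desc, extratags=extratags)


def _read_raster(path: str | Path) -> tuple[np.ndarray, float, tuple[float, float], str | None]:
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        data = page.asarray()
        pixel_size = 1.0
        origin = (0.0, 0.0)
        crs = None
        if _TAG_PIXEL_SCALE in page.tags:
            pixel_size = float(page.tags[_TAG_PIXEL_SCALE].value[0])
        if _TAG_TIEPOINT in page.tags:
            tp = page.tags[_TAG_TIEPOINT].value
            origin = (float(tp[3]), float(tp[4]))
        if 270 in page.tags:  # ImageDescription
            try:
                crs = json.loads(page.tags[270].value).get("crs")
            except (ValueError, AttributeError):
                crs = None
    return data, pixel_size, origin, crs


def read_mask(path: str | Path) -> CrownMask:
    """Read a binary crown mask; values above 1 are coerced to 1 with a warning."""
    data, pixel_size, origin, crs = _read_raster(path)
    if data.max(initial=0) > 1:
        warnings.warn(f"{path}: values > 1 coerced to 1", stacklevel=2)
        data = (data > 0).astype(np.uint8)
    if data.min(initial=0) < 0:
        raise ValueError(f"{path}: negative values cannot form a binary mask")
    return CrownMask(pixels=data.astype(np.uint8), pixel_size=pixel_size, origin=origin, crs_tag=crs)


def write_labels(path: str | Path, scene: LabelScene) -> None:
    write_raster(path, scene.labels.astype(np.int32), scene.pixel_size, scene.origin, scene.crs_tag)


def read_labels(path: str | Path) -> LabelScene:
    data, pixel_size, origin, crs = _read_raster(path)
    return LabelScene(
        labels=data.astype(np.int32),
        centres=CentreSet(()),
        pixel_size=pixel_size,
        origin=origin,
        crs_tag=crs,
    )


def write_grid(path: str | Path, grid: HectareGrid, crs_tag: str | None = None) -> None:
    """Hectare grid as a 3-band raster: density, cover %, carbon MgC/ha."""
    stack = np.stack([grid.density, grid.cover_pct, grid.carbon_mgc_ha]).astype(np.float64)
    x0, y0 = grid.origin
    desc = json.dumps(
        {"crs": crs_tag, "bands": ["density_trees_ha", "cover_pct", "carbon_mgc_ha"]},
        sort_keys=True,
    )
    extratags = [
        (_TAG_PIXEL_SCALE, "d", 3, (grid.cell_size, grid.cell_size, 0.0)),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, float(x0), float(y0), 0.0)),
    ]
    tifffile.imwrite(
        path, stack, description=desc, extratags=extratags,
        photometric="minisblack", planarconfig="separate",
    )


def write_centres_csv(path: str | Path, scene: LabelScene) -> None:
    rows = []
    ps = scene.pixel_size
    x0, y0 = scene.origin
    for i, (r, c) in enumerate(scene.centres.centres, start=1):
        rows.append(
            {
                "label": i,
                "row": r,
                "col": c,
                "x_world": x0 + (c + 0.5) * ps,
                "y_world": y0 - (r + 0.5) * ps,
            }
        )
    pd.DataFrame(rows, columns=["label", "row", "col", "x_world", "y_world"]).to_csv(
        path, index=False
    )


def write_tree_csv(path: str | Path, records: Sequence[TreeRecord]) -> None:
    records_to_frame(records).to_csv(path, index=False)


def read_tree_csv(path: str | Path) -> list[TreeRecord]:
    return frame_to_records(pd.read_csv(path))


def write_geojson(path: str | Path, geometry: BaseGeometry | list[BaseGeometry], properties=None) -> None:
    geoms = geometry if isinstance(geometry, list) else [geometry]
    props = properties or [{} for _ in geoms]
    fc = {
        "type": "FeatureCollection",
        "features": [
            {"type": "Feature", "geometry": mapping(g), "properties": p}
            for g, p in zip(geoms, props)
        ],
    }
    Path(path).write_text(json.dumps(fc, sort_keys=True))


def read_geojson_geometries(path: str | Path) -> list[BaseGeometry]:
    fc = json.loads(Path(path).read_text())
    return [shape(feat["geometry"]) for feat in fc["features"]]


def write_landcover_geojson(path: str | Path, layer: LandCoverLayer) -> None:
    if layer.features is None:
        raise ValueError("only polygon land-cover layers can be written as GeoJSON")
    geoms = [f.geometry for f in layer.features]
    props = [{"class": f.landcover, "protected": f.protected} for f in layer.features]
    write_geojson(path, geoms, props)


def read_landcover_geojson(path: str | Path, crs_tag: str | None = None) -> LandCoverLayer:
    fc = json.loads(Path(path).read_text())
    features = []
    for feat in fc["features"]:
        props = feat.get("properties") or {}
        features.append(
            LandCoverFeature(
                geometry=shape(feat["geometry"]),
                landcover=props["class"],
                protected=props.get("protected"),
            )
        )
    return LandCoverLayer(features=features, crs_tag=crs_tag)


def save_model(path: str | Path, model: AllometricModel) -> None:
    lines = [
        f"form={model.form}",
        f"intercept={model.intercept!r}",
        f"slope={model.slope!r}",
        f"sigma={model.sigma!r}",
        f"cd_multiplier={model.cd_multiplier!r}",
        f"seeds={','.join(str(s) for s in model.seeds)}",
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def load_model(path: str | Path) -> AllometricModel:
    kv = {}
    for line in Path(path).read_text().splitlines():
        if line.strip():
            key, _, value = line.partition("=")
            kv[key.strip()] = value.strip()
    return AllometricModel(
        form=kv["form"],
        intercept=float(kv["intercept"]),
        slope=float(kv["slope"]),
        sigma=float(kv["sigma"]),
        cd_multiplier=float(kv["cd_multiplier"]),
        seeds=tuple(int(s) for s in kv["seeds"].split(",") if s),
    )
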