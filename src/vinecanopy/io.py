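"""File formats: GeoTIFF rasters, GeoJSON vectors, CSV tables, JSON sidecars.

Rasters are written as float32 GeoTIFF with the standard georeferencing tags
(ModelPixelScale, ModelTiepoint) plus a JSON ImageDescription carrying band
names, the CRS label and the exact transform, so grids round-trip without a
full GeoTIFF CRS machinery. Vectors are GeoJSON FeatureCollections with a
``crs`` member. A raster/vector CRS mismatch raises — nothing is silently
reprojected.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from shapely.geometry import mapping, shape

from .geo import CrsMismatchError, GridTransform
from .synthetic_scene import MultispectralScene
from .vigour_mapping import NdviGrid

__all__ = [
    "write_raster",
    "read_raster",
    "scene_to_file",
    "scene_from_file",
    "ndvi_to_file",
    "ndvi_from_file",
    "write_vectors",
    "read_vectors",
    "write_table",
    "read_table",
    "write_sidecar",
    "ensure_same_crs",
]

_MODEL_PIXEL_SCALE = 33550
_MODEL_TIEPOINT = 33922


def ensure_same_crs(crs_a: str, crs_b: str) -> None:
    if crs_a != crs_b:
        raise CrsMismatchError(
            f"CRS mismatch: {crs_a!r} vs {crs_b!r}; reproject inputs explicitly"
        )


# ---------------------------------------------------------------------------
# rasters


def write_raster(
    path: str | Path,
    bands: dict[str, np.ndarray],
    transform: GridTransform,
    crs: str,
) -> None:
    names = list(bands)
    stack = np.stack([bands[b].astype(np.float32) for b in names])
    meta = {
        "bands": names,
        "origin_x": transform.origin_x,
        "origin_y": transform.origin_y,
        "pixel_size": transform.pixel_size,
        "crs": crs,
    }
    ps = float(transform.pixel_size)
    tifffile.imwrite(
        path,
        stack,
        description=json.dumps(meta),
        extratags=[
            (_MODEL_PIXEL_SCALE, "d", 3, (ps, ps, 0.0)),
            (
                _MODEL_TIEPOINT,
                "d",
                6,
                (0.0, 0.0, 0.0, float(transform.origin_x), float(transform.origin_y), 0.0),
            ),
        ],
    )


def read_raster(path: str | Path) -> tuple[dict[str, np.ndarray], GridTransform, str]:
    with tifffile.TiffFile(path) as tif:
        stack = tif.asarray()
        desc = tif.pages[0].tags.get("ImageDescription")
        if desc is None:
            raise ValueError(f"{path}: no metadata description; not written by this package")
        meta = json.loads(desc.value)
    if stack.ndim == 2:
        stack = stack[None]
    names = meta["bands"]
    if len(names) != stack.shape[0]:
        raise ValueError(f"{path}: band-name count does not match raster planes")
    transform = GridTransform(meta["origin_x"], meta["origin_y"], meta["pixel_size"])
    bands = {n: stack[i].astype(np.float64) for i, n in enumerate(names)}
    return bands, transform, meta["crs"]


def scene_to_file(scene: MultispectralScene, path: str | Path) -> None:
    write_raster(path, scene.bands, scene.transform, scene.crs)


def scene_from_file(path: str | Path) -> MultispectralScene:
    """Read a band stack; the 4-band vs 5-band dialect is detected from the
    band names carried in the file metadata."""
    bands, transform, crs = read_raster(path)
    band_set = "UAV5" if "RE" in bands else "SAT4"
    return MultispectralScene(bands=bands, transform=transform, crs=crs, band_set=band_set)


def ndvi_to_file(grid: NdviGrid, path: str | Path) -> None:
    write_raster(path, {"NDVI": grid.values}, grid.transform, grid.crs)


def ndvi_from_file(path: str | Path) -> NdviGrid:
    bands, transform, crs = read_raster(path)
    if "NDVI" not in bands:
        raise ValueError(f"{path}: not an NDVI raster")
    return NdviGrid(values=bands["NDVI"], transform=transform, crs=crs)


# ---------------------------------------------------------------------------
# vectors


def write_vectors(path: str | Path, geometries, properties=None, crs: str = "EPSG:25831") -> None:
    """GeoJSON FeatureCollection from shapely geometries and parallel property dicts."""
    properties = properties or [{} for _ in geometries]
    features = [
        {"type": "Feature", "geometry": mapping(geom), "properties": props}
        for geom, props in zip(geometries, properties)
    ]
    doc = {
        "type": "FeatureCollection",
        "crs": {"type": "name", "properties": {"name": crs}},
        "features": features,
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def read_vectors(path: str | Path):
    """(geometries, properties, crs_label) from a GeoJSON FeatureCollection."""
    doc = json.loads(Path(path).read_text())
    crs = doc.get("crs", {}).get("properties", {}).get("name", "")
    geoms = [shape(f["geometry"]) for f in doc["features"]]
    props = [f.get("properties", {}) for f in doc["features"]]
    return geoms, props, crs


# ---------------------------------------------------------------------------
# tables

#: decimal places per database column at the CSV boundary (full precision inside)
_ROUNDING = {
    "NDVI_D": 4, "NDVI_S": 4, "NDVI_D_x_Prj_area_D": 4,
    "Prj_area_D": 4, "H_M": 3, "W_M": 3, "LWA_M": 2, "TRV_M": 2,
    "height_true": 4, "width_true": 4, "vigour_true": 4, "x": 3, "y": 3,
    "slope": 6, "intercept": 6, "r_squared": 4, "ks_p": 6,
}


def write_table(frame: pd.DataFrame, path: str | Path) -> None:
    out = frame.copy()
    for col, nd in _ROUNDING.items():
        if col in out.columns:
            out[col] = out[col].round(nd)
    out.to_csv(path, index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_sidecar(artefact_path: str | Path, metadata: dict) -> Path:
    """Write ``<artefact>.meta.json`` next to an artefact; returns its path."""
    side = Path(str(artefact_path) + ".meta.json")
    side.write_text(json.dumps(metadata, indent=1, sort_keys=True))
    return side
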