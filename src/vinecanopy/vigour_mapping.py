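"""NDVI vigour-map workflow.

Fine-resolution (UAV-scale) path: NDVI -> threshold canopy mask -> masked NDVI
-> inverse-distance-weighting interpolation from canopy-pixel anchors -> a
continuous NDVI surface -> quintile three-class map (low / medium / high).

Coarse (satellite-scale) path: at 3 m the rows cannot be segmented from the
background, so the raw NDVI grid is classified directly, optionally clipped to
the plot boundary first.

Class rule: value < P20 -> low, value > P80 -> high, otherwise medium (values
exactly at P20 or P80 are medium). Missing cells stay missing; masked-out
cells are 0 — a distinct, finite state.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import shapely
from scipy.spatial import cKDTree
from shapely.geometry import Polygon
from skimage.filters import threshold_otsu

from .geo import GridTransform, ensure_aligned
from .synthetic_scene import BAND_SETS, MultispectralScene

__all__ = [
    "NdviGrid",
    "CanopyMask",
    "VigourMap",
    "LOW", "MEDIUM", "HIGH", "NODATA",
    "CLASS_NAMES",
    "BandNotFoundError",
    "EmptyInputError",
    "compute_ndvi",
    "segment_canopy",
    "mask_ndvi",
    "anchors_from_masked",
    "idw_interpolate",
    "classify_quintiles",
    "satellite_vigour",
]

logger = logging.getLogger(__name__)

LOW, MEDIUM, HIGH, NODATA = 0, 1, 2, -1
CLASS_NAMES = {LOW: "low", MEDIUM: "medium", HIGH: "high", NODATA: "nodata"}


class BandNotFoundError(KeyError):
    pass


class EmptyInputError(ValueError):
    pass


@dataclass
class NdviGrid:
    """2-D NDVI surface; NaN marks missing cells."""

    values: np.ndarray
    transform: GridTransform
    crs: str = "EPSG:25831"

    def __post_init__(self) -> None:
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() < -1.0 - 1e-12 or finite.max() > 1.0 + 1e-12):
            raise ValueError("NDVI values must lie in [-1, 1]")

    @property
    def finite_values(self) -> np.ndarray:
        return self.values[np.isfinite(self.values)]


@dataclass
class CanopyMask:
    """Binary canopy/background grid aligned to its NDVI grid."""

    values: np.ndarray  # uint8 {0, 1}
    threshold_used: float
    method: str  # "manual" | "otsu"
    transform: GridTransform

    def __post_init__(self) -> None:
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("mask must be binary")


@dataclass
class VigourMap:
    """Continuous NDVI surface plus its three-class zoning and the quintile cuts."""

    continuous: NdviGrid
    classes: np.ndarray  # int8 {LOW, MEDIUM, HIGH, NODATA}
    thresholds: tuple[float, float, float, float]  # (P20, P40, P60, P80)

    def class_name_grid(self) -> np.ndarray:
        names = np.full(self.classes.shape, "nodata", dtype=object)
        for code, name in CLASS_NAMES.items():
            names[self.classes == code] = name
        return names


def compute_ndvi(scene: MultispectralScene) -> NdviGrid:
    """Per-pixel (NIR - R)/(NIR + R); cells with NIR + R = 0 become missing."""
    for band in ("NIR", "R"):
        if band not in scene.bands:
            raise BandNotFoundError(
                f"band {band!r} not present in {scene.band_set} scene "
                f"(bands: {sorted(scene.bands)}; dialects: {sorted(BAND_SETS)})"
            )
    nir = scene.bands["NIR"].astype(np.float64)
    red = scene.bands["R"].astype(np.float64)
    denom = nir + red
    with np.errstate(divide="ignore", invalid="ignore"):
        ndvi = np.where(denom > 0, (nir - red) / denom, np.nan)
    return NdviGrid(values=ndvi, transform=scene.transform, crs=scene.crs)


def segment_canopy(ndvi: NdviGrid, threshold: float | str = "auto") -> CanopyMask:
    """Binary canopy mask: 1 where NDVI > threshold.

    ``threshold="auto"`` splits the bimodal NDVI histogram with Otsu's method;
    a scalar reproduces a manually chosen cut.
    """
    finite = ndvi.finite_values
    if finite.size == 0:
        raise EmptyInputError("NDVI grid has no finite cells")
    if threshold == "auto":
        thr, method = float(threshold_otsu(finite)), "otsu"
    else:
        thr, method = float(threshold), "manual"
    mask = np.zeros(ndvi.values.shape, dtype=np.uint8)
    mask[np.isfinite(ndvi.values) & (ndvi.values > thr)] = 1
    return CanopyMask(values=mask, threshold_used=thr, method=method,
                      transform=ndvi.transform)


def mask_ndvi(ndvi: NdviGrid, mask: CanopyMask) -> NdviGrid:
    """Canopy pixels keep their NDVI; background pixels become 0 (not missing)."""
    ensure_aligned(ndvi, mask)
    out = np.where(mask.values == 1, ndvi.values, 0.0)
    return NdviGrid(values=out, transform=ndvi.transform, crs=ndvi.crs)


def anchors_from_masked(ndvi: NdviGrid, mask: CanopyMask) -> np.ndarray:
    """(n, 3) array of canopy-pixel centre coordinates and NDVI values."""
    ensure_aligned(ndvi, mask)
    rows, cols = np.nonzero((mask.values == 1) & np.isfinite(ndvi.values))
    xs, ys = ndvi.transform.cell_centres(ndvi.values.shape)
    return np.column_stack([xs[cols], ys[rows], ndvi.values[rows, cols]])


def idw_interpolate(
    anchors: np.ndarray,
    transform: GridTransform,
    shape: tuple[int, int],
    power: float = 2.0,
    k: int = 12,
    crs: str = "EPSG:25831",
) -> NdviGrid:
    """Inverse-distance-weighted interpolation onto a full grid.

    Value at a cell is sum(w_i v_i) / sum(w_i) with w_i = d_i^(-power) over the
    k nearest anchors; a cell whose centre coincides with an anchor returns the
    anchor value exactly (the interpolant is exact at the data).
    """
    anchors = np.asarray(anchors, dtype=np.float64)
    if anchors.ndim != 2 or anchors.shape[1] != 3 or anchors.shape[0] == 0:
        raise EmptyInputError("anchors must be a non-empty (n, 3) array of x, y, value")
    if power <= 0:
        raise ValueError("power must be > 0")
    pts, vals = anchors[:, :2], anchors[:, 2]
    k_eff = min(k, len(pts))
    tree = cKDTree(pts)
    gx, gy = transform.centre_mesh(shape)
    query = np.column_stack([gx.ravel(), gy.ravel()])
    dist, idx = tree.query(query, k=k_eff)
    if k_eff == 1:
        dist, idx = dist[:, None], idx[:, None]
    exact = dist[:, 0] < 1e-12
    with np.errstate(divide="ignore"):
        w = dist ** (-power)
    out = np.empty(len(query))
    ok = ~exact
    out[ok] = (w[ok] * vals[idx[ok]]).sum(axis=1) / w[ok].sum(axis=1)
    out[exact] = vals[idx[exact, 0]]
    return NdviGrid(values=out.reshape(shape), transform=transform, crs=crs)


def _classify(values: np.ndarray, thresholds) -> np.ndarray:
    p20, _, _, p80 = thresholds
    classes = np.full(values.shape, NODATA, dtype=np.int8)
    finite = np.isfinite(values)
    classes[finite] = MEDIUM
    classes[finite & (values < p20)] = LOW
    classes[finite & (values > p80)] = HIGH
    return classes


def classify_quintiles(continuous: NdviGrid) -> VigourMap:
    """Quintile three-class zoning of a continuous NDVI surface.

    Empirical 20/40/60/80th percentiles (linear interpolation) over the finite
    cells define the cuts; below P20 is low, above P80 high, the closed middle
    band medium. A constant grid degenerates to all-medium (warning logged).
    """
    finite = continuous.finite_values
    if finite.size < 5:
        raise EmptyInputError("need at least 5 finite cells for quintiles")
    thresholds = tuple(float(t) for t in np.percentile(finite, [20, 40, 60, 80]))
    if thresholds[0] == thresholds[3]:
        logger.warning("constant NDVI grid: degenerate quintiles, all cells medium")
    return VigourMap(
        continuous=continuous,
        classes=_classify(continuous.values, thresholds),
        thresholds=thresholds,
    )


def satellite_vigour(ndvi: NdviGrid, plot_boundary: Polygon | None = None) -> VigourMap:
    """Three-class vigour map straight from raw (unsegmented) NDVI.

    At 3 m resolution canopy/background segmentation is impossible, so the
    quintile rule is applied to the raw grid; if a plot boundary is given,
    cells whose centres fall outside it are set missing before the percentiles
    are taken.
    """
    values = ndvi.values
    if plot_boundary is not None:
        gx, gy = ndvi.transform.centre_mesh(values.shape)
        inside = shapely.contains_xy(plot_boundary, gx.ravel(), gy.ravel())
        values = np.where(inside.reshape(values.shape), values, np.nan)
        ndvi = NdviGrid(values=values, transform=ndvi.transform, crs=ndvi.crs)
    return classify_quintiles(ndvi)
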