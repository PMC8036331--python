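"""Systematic uniform random (SUR) sampling and per-vine feature extraction.

SUR sampling selects every m_r-th row after a random starting row in
{1..m_r}, and within each selected row every m_v-th vine after a random
starting vine in {1..m_v} — sampling locations spread uniformly over the plot
with a known selection probability.

Feature extraction assigns each sampled vine a rectangular polygon (1.2 m
along the row, one full row spacing across it) and reads, from the fine grid:
the mean canopy NDVI inside the polygon (NDVI_D), the pixel-counted projected
canopy area (Prj_area_D) and the majority vigour class (C_vigour_D); from the
coarse grid: the overlap-area-weighted NDVI (NDVI_S) and the class of the
dominant pixel (C_vigour_S). Vines whose polygon centroid lies within 3 m of
the plot border are flagged as edge points.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Polygon, box

from .canopy_metrics import lwa, trv
from .geo import ensure_aligned
from .synthetic_scene import FieldSpec, VineTruth
from .vigour_mapping import (
    CLASS_NAMES,
    HIGH,
    LOW,
    MEDIUM,
    CanopyMask,
    NdviGrid,
    VigourMap,
)

__all__ = [
    "SamplingDesign",
    "UavFeatures",
    "SatFeatures",
    "RECORD_COLUMNS",
    "JoinError",
    "sur_sample",
    "vine_polygon",
    "extract_uav_features",
    "extract_sat_features",
    "classify_edge",
    "assemble_records",
]

#: Canonical database column set (one column per database variable; ASCII-safe
#: spellings of the published field names).
RECORD_COLUMNS = [
    "Plot", "Variety", "Year", "BBCH", "Vine",
    "NDVI_D", "C_vigour_D", "Prj_area_D", "NDVI_D_x_Prj_area_D",
    "H_M", "W_M", "LWA_M", "TRV_M",
    "NDVI_S", "C_vigour_S", "Edge_pnt",
]


class JoinError(ValueError):
    """Manual / UAV / satellite tables do not join one-to-one."""


@dataclass(frozen=True)
class SamplingDesign:
    """Periods, random starts, and the resulting selection."""

    row_period: int
    vine_period: int
    start_row: int
    start_vine: int
    selected: tuple[str, ...]

    def __post_init__(self) -> None:
        if not 1 <= self.start_row <= self.row_period:
            raise ValueError("start_row must lie in 1..row_period")
        if not 1 <= self.start_vine <= self.vine_period:
            raise ValueError("start_vine must lie in 1..vine_period")
        if len(set(self.selected)) != len(self.selected):
            raise ValueError("selected vine ids must be unique")


def sur_sample(
    layout: list[VineTruth],
    row_period: int,
    vine_period: int,
    seed: int | None = None,
    start_row: int | None = None,
    start_vine: int | None = None,
) -> SamplingDesign:
    """Two-stage SUR selection over a layout ordered by (row, along-row position).

    Random starts are drawn uniformly on {1..period} from ``seed`` unless given
    explicitly (as when reproducing a published design). If a period exceeds
    the available units, only the start unit is selected and a warning is
    issued.
    """
    if row_period < 1 or vine_period < 1:
        raise ValueError("periods must be >= 1")
    if not layout:
        raise ValueError("layout must be non-empty")
    rng = np.random.default_rng(seed)
    if start_row is None:
        start_row = int(rng.integers(1, row_period + 1))
    if start_vine is None:
        start_vine = int(rng.integers(1, vine_period + 1))

    ordered = sorted(layout, key=lambda v: (v.row_index, v.along_row_position))
    rows: dict[int, list[VineTruth]] = {}
    for vine in ordered:
        rows.setdefault(vine.row_index, []).append(vine)
    row_keys = sorted(rows)
    if row_period > len(row_keys):
        warnings.warn(
            f"row_period {row_period} exceeds the {len(row_keys)} rows; "
            "only the start row is selected",
            stacklevel=2,
        )
    selected_rows = row_keys[start_row - 1 :: row_period]

    selected: list[str] = []
    warned_vine = False
    for rk in selected_rows:
        vines = rows[rk]
        if vine_period > len(vines) and not warned_vine:
            warnings.warn(
                f"vine_period {vine_period} exceeds the row population; "
                "only the start vine is selected",
                stacklevel=2,
            )
            warned_vine = True
        selected.extend(v.vine_id for v in vines[start_vine - 1 :: vine_period])

    return SamplingDesign(
        row_period=row_period,
        vine_period=vine_period,
        start_row=start_row,
        start_vine=start_vine,
        selected=tuple(selected),
    )


def vine_polygon(vine: VineTruth, field_spec: FieldSpec) -> Polygon:
    """Sampling rectangle: 1.2 m along the row, one row spacing across it,
    centred on the vine and oriented with the row azimuth."""
    along, across = field_spec.axes
    half_l, half_w = 1.2 / 2.0, field_spec.row_spacing / 2.0
    c = np.array([vine.x, vine.y])
    corners = [
        c + half_l * along + half_w * across,
        c + half_l * along - half_w * across,
        c - half_l * along - half_w * across,
        c - half_l * along + half_w * across,
    ]
    return Polygon([tuple(p) for p in corners])


@dataclass(frozen=True)
class UavFeatures:
    ndvi_d: float  # NaN when missing
    prj_area_d: float
    c_vigour_d: str
    missing: bool


@dataclass(frozen=True)
class SatFeatures:
    ndvi_s: float
    c_vigour_s: str
    missing: bool


def _majority_class(class_codes: np.ndarray) -> str:
    """Majority vigour class; any tie for the maximum count resolves to medium."""
    counts = {c: int((class_codes == c).sum()) for c in (LOW, MEDIUM, HIGH)}
    best = max(counts.values())
    winners = [c for c, n in counts.items() if n == best]
    return CLASS_NAMES[winners[0]] if len(winners) == 1 else CLASS_NAMES[MEDIUM]


def extract_uav_features(
    polygon: Polygon, ndvi: NdviGrid, mask: CanopyMask, vmap: VigourMap
) -> UavFeatures:
    """Canopy-pixel features inside one sampling polygon on the fine grid.

    Canopy cells are mask-1 cells whose centres fall inside the polygon.
    NDVI_D is their mean NDVI; Prj_area_D their count times the pixel area
    (the polygonised canopy contour's area); the class is the majority class
    of those cells in the vigour map. No canopy cells -> missing record with
    zero projected area.
    """
    ensure_aligned(ndvi, mask)
    if vmap.classes.shape != ndvi.values.shape:
        raise ValueError("vigour map not aligned with NDVI grid")
    t = ndvi.transform
    nrow, ncol = ndvi.values.shape
    xmin, ymin, xmax, ymax = polygon.bounds
    r0, c0 = t.index_of(xmin, ymax)
    r1, c1 = t.index_of(xmax, ymin)
    r0, c0 = max(r0, 0), max(c0, 0)
    r1, c1 = min(r1 + 1, nrow - 1), min(c1 + 1, ncol - 1)
    if r1 < r0 or c1 < c0:
        return UavFeatures(np.nan, 0.0, CLASS_NAMES[MEDIUM], True)
    xs, ys = t.cell_centres((nrow, ncol))
    gx, gy = np.meshgrid(xs[c0 : c1 + 1], ys[r0 : r1 + 1])
    inside = shapely.contains_xy(polygon, gx.ravel(), gy.ravel()).reshape(gx.shape)
    sub_mask = mask.values[r0 : r1 + 1, c0 : c1 + 1] == 1
    canopy = inside & sub_mask
    if not canopy.any():
        return UavFeatures(np.nan, 0.0, CLASS_NAMES[MEDIUM], True)
    sub_ndvi = ndvi.values[r0 : r1 + 1, c0 : c1 + 1][canopy]
    sub_classes = vmap.classes[r0 : r1 + 1, c0 : c1 + 1][canopy]
    area = float(canopy.sum()) * t.pixel_size**2
    return UavFeatures(
        ndvi_d=float(np.nanmean(sub_ndvi)),
        prj_area_d=area,
        c_vigour_d=_majority_class(sub_classes),
        missing=False,
    )


def extract_sat_features(
    polygon: Polygon, ndvi_s: NdviGrid, vmap_s: VigourMap
) -> SatFeatures:
    """Coarse-grid features: exact overlap-area-weighted NDVI over the 3 m
    pixels intersecting the polygon; class of the largest-overlap pixel."""
    if vmap_s.classes.shape != ndvi_s.values.shape:
        raise ValueError("vigour map not aligned with NDVI grid")
    t = ndvi_s.transform
    nrow, ncol = ndvi_s.values.shape
    xmin, ymin, xmax, ymax = polygon.bounds
    r0, c0 = t.index_of(xmin, ymax)
    r1, c1 = t.index_of(xmax, ymin)
    r0, c0 = max(r0, 0), max(c0, 0)
    r1, c1 = min(r1, nrow - 1), min(c1, ncol - 1)
    weights, values, classes = [], [], []
    for r in range(r0, r1 + 1):
        for c in range(c0, c1 + 1):
            if not np.isfinite(ndvi_s.values[r, c]):
                continue
            pb = box(*t.pixel_bounds(r, c))
            overlap = polygon.intersection(pb).area
            if overlap > 0:
                weights.append(overlap)
                values.append(ndvi_s.values[r, c])
                classes.append(vmap_s.classes[r, c])
    if not weights:
        return SatFeatures(np.nan, CLASS_NAMES[MEDIUM], True)
    w = np.asarray(weights)
    v = np.asarray(values)
    dominant = int(np.argmax(w))
    code = int(classes[dominant])
    return SatFeatures(
        ndvi_s=float((w * v).sum() / w.sum()),
        c_vigour_s=CLASS_NAMES.get(code, CLASS_NAMES[MEDIUM]),
        missing=False,
    )


def classify_edge(polygon: Polygon, plot_boundary: Polygon, buffer: float = 3.0) -> bool:
    """True iff the polygon centroid lies within ``buffer`` metres of the plot
    border ring (edge points: coarse pixels there mix in adjacent land cover)."""
    return polygon.centroid.distance(plot_boundary.exterior) < buffer


def assemble_records(
    manual: pd.DataFrame,
    uav: pd.DataFrame,
    sat: pd.DataFrame,
    plot_id: str,
    variety: str,
    year: int,
    row_spacing: float,
) -> pd.DataFrame:
    """Join manual means with UAV and satellite features into the database table.

    ``manual`` needs columns (vine_id, stage, H_M, W_M); ``uav`` (vine_id,
    stage, NDVI_D, Prj_area_D, C_vigour_D); ``sat`` (vine_id, stage, NDVI_S,
    C_vigour_S, Edge_pnt). Join keys must match one-to-one; orphans on either
    side raise :class:`JoinError` listing the offending keys. LWA_M/TRV_M are
    derived from the manual means and the plot's row spacing, and the
    composite predictor NDVI_D_x_Prj_area_D from the UAV features.
    """
    keys = ["vine_id", "stage"]
    for name, frame, cols in (
        ("manual", manual, ["H_M", "W_M"]),
        ("uav", uav, ["NDVI_D", "Prj_area_D", "C_vigour_D"]),
        ("sat", sat, ["NDVI_S", "C_vigour_S", "Edge_pnt"]),
    ):
        missing_cols = [c for c in keys + cols if c not in frame.columns]
        if missing_cols:
            raise JoinError(f"{name} table lacks columns {missing_cols}")
        if frame.duplicated(subset=keys).any():
            raise JoinError(f"{name} table has duplicate (vine_id, stage) keys")

    merged = manual.merge(uav, on=keys, how="outer", indicator=True)
    orphans = merged.loc[merged["_merge"] != "both", keys]
    if len(orphans):
        raise JoinError(f"manual/uav join mismatch for keys: {orphans.values.tolist()}")
    merged = merged.drop(columns="_merge").merge(sat, on=keys, how="outer", indicator=True)
    orphans = merged.loc[merged["_merge"] != "both", keys]
    if len(orphans):
        raise JoinError(f"uav/sat join mismatch for keys: {orphans.values.tolist()}")
    merged = merged.drop(columns="_merge")

    out = pd.DataFrame(
        {
            "Plot": plot_id,
            "Variety": variety,
            "Year": year,
            "BBCH": merged["stage"],
            "Vine": merged["vine_id"],
            "NDVI_D": merged["NDVI_D"],
            "C_vigour_D": merged["C_vigour_D"],
            "Prj_area_D": merged["Prj_area_D"],
            "NDVI_D_x_Prj_area_D": merged["NDVI_D"] * merged["Prj_area_D"],
            "H_M": merged["H_M"],
            "W_M": merged["W_M"],
            "LWA_M": [lwa(h, row_spacing) for h in merged["H_M"]],
            "TRV_M": [trv(h, w, row_spacing) for h, w in zip(merged["H_M"], merged["W_M"])],
            "NDVI_S": merged["NDVI_S"],
            "C_vigour_S": merged["C_vigour_S"],
            "Edge_pnt": merged["Edge_pnt"].astype(bool),
        },
        columns=RECORD_COLUMNS,
    )
    return out.sort_values(["BBCH", "Vine"], kind="stable").reset_index(drop=True)
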