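import math

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import box

from vinecanopy.geo import GridTransform
from vinecanopy.sampling_extraction import (
    JoinError,
    assemble_records,
    classify_edge,
    extract_sat_features,
    extract_uav_features,
    sur_sample,
    vine_polygon,
)
from vinecanopy.synthetic_scene import (
    FieldSpec,
    VigourFieldParams,
    assign_truth,
    generate_layout,
)
from vinecanopy.vigour_mapping import CanopyMask, NdviGrid, VigourMap, classify_quintiles


def sur_oracle(layout, m_r, m_v, s_r, s_v):
    """Enumeration oracle: walk rows and vines explicitly."""
    rows = {}
    for v in sorted(layout, key=lambda v: (v.row_index, v.along_row_position)):
        rows.setdefault(v.row_index, []).append(v.vine_id)
    keys = sorted(rows)
    picked = []
    for ri, rk in enumerate(keys, start=1):
        if ri < s_r or (ri - s_r) % m_r:
            continue
        for vi, vid in enumerate(rows[rk], start=1):
            if vi >= s_v and (vi - s_v) % m_v == 0:
                picked.append(vid)
    return picked


# ---------------------------------------------------------------------------
# SUR sampling


def test_sur_census(plot_a_field):
    layout = generate_layout(plot_a_field)
    design = sur_sample(layout, 1, 1, start_row=1, start_vine=1)
    assert len(design.selected) == len(layout)


def test_sur_matches_enumeration_example(plot_a_field):
    """10x10 grid, periods (5, 3), starts (2, 1): rows {2, 7}, vines
    {1, 4, 7, 10} in each — 8 vines, identical to direct enumeration."""
    layout = generate_layout(plot_a_field)
    design = sur_sample(layout, 5, 3, start_row=2, start_vine=1)
    assert len(design.selected) == 8
    assert set(design.selected) == set(sur_oracle(layout, 5, 3, 2, 1))
    assert {vid.split("-")[1] for vid in design.selected} == {"r02", "r07"}


def test_sur_random_layouts_match_oracle(plot_a_field):
    layout = generate_layout(plot_a_field)
    rng = np.random.default_rng(17)
    for _ in range(50):
        m_r, m_v = int(rng.integers(1, 8)), int(rng.integers(1, 8))
        s_r, s_v = int(rng.integers(1, m_r + 1)), int(rng.integers(1, m_v + 1))
        design = sur_sample(layout, m_r, m_v, start_row=s_r, start_vine=s_v)
        assert list(design.selected) == sur_oracle(layout, m_r, m_v, s_r, s_v)


def test_sur_seeded_starts_in_range(plot_a_field):
    layout = generate_layout(plot_a_field)
    design = sur_sample(layout, row_period=5, vine_period=30, seed=4)
    assert 1 <= design.start_row <= 5
    assert 1 <= design.start_vine <= 30


def test_sur_period_exceeding_population_warns(plot_a_field):
    layout = generate_layout(plot_a_field)  # 10 rows x 10 vines
    with pytest.warns(UserWarning):
        design = sur_sample(layout, 50, 1, start_row=3, start_vine=1)
    assert {vid.split("-")[1] for vid in design.selected} == {"r03"}


# ---------------------------------------------------------------------------
# polygons and edge flags


def test_vine_polygon_geometry(plot_a_field):
    layout = generate_layout(plot_a_field)
    poly = vine_polygon(layout[0], plot_a_field)
    assert poly.area == pytest.approx(1.2 * 2.2)
    assert poly.contains(__import__("shapely").points(layout[0].x, layout[0].y))


def test_vine_polygon_rotation_preserves_area():
    field = FieldSpec(
        boundary=box(0, 0, 30, 30), row_spacing=2.2, vine_spacing=1.2, row_azimuth=37.0
    )
    layout = generate_layout(field)
    poly = vine_polygon(layout[5], field)
    assert poly.area == pytest.approx(1.2 * 2.2, rel=1e-9)


def test_classify_edge_cases():
    plot = box(0, 0, 100, 100)
    on_border = box(-0.6, 49.4, 0.6, 50.6)  # centroid on the boundary ring
    centre = box(49.4, 49.4, 50.6, 50.6)
    near = box(1.0, 49.4, 2.2, 50.6)  # centroid 1.6 m from the border
    assert classify_edge(on_border, plot)
    assert not classify_edge(centre, plot)
    assert classify_edge(near, plot)


def test_classify_edge_matches_analytic_distance():
    """For a square plot the ring distance is min(x, y, L-x, L-y)."""
    plot = box(0, 0, 60, 40)
    rng = np.random.default_rng(8)
    for _ in range(100):
        cx, cy = rng.uniform(0.7, 59.3), rng.uniform(0.7, 39.3)
        poly = box(cx - 0.6, cy - 0.5, cx + 0.6, cy + 0.5)
        analytic = min(cx, cy, 60 - cx, 40 - cy)
        assert classify_edge(poly, plot, buffer=3.0) == (analytic < 3.0)


# ---------------------------------------------------------------------------
# UAV feature extraction

T = GridTransform(0.0, 4.0, 1.0)


def make_vmap(ndvi: NdviGrid) -> VigourMap:
    return classify_quintiles(ndvi)


def test_uav_features_hand_computed_toy_grid():
    """4x4 grid, hand-set mask and NDVI; polygon covers the left 2 columns."""
    values = np.arange(16, dtype=float).reshape(4, 4) / 20.0
    ndvi = NdviGrid(values=values, transform=T)
    mask_vals = np.zeros((4, 4), np.uint8)
    mask_vals[1:3, 0:2] = 1  # rows 1-2, cols 0-1
    mask = CanopyMask(mask_vals, 0.1, "manual", T)
    vmap = make_vmap(ndvi)
    poly = box(0.0, 0.0, 2.0, 4.0)

    feats = extract_uav_features(poly, ndvi, mask, vmap)
    # canopy cells: (1,0)=4/20, (1,1)=5/20, (2,0)=8/20, (2,1)=9/20
    assert feats.ndvi_d == pytest.approx((4 + 5 + 8 + 9) / 4 / 20.0)
    assert feats.prj_area_d == pytest.approx(4.0)  # 4 cells x 1 m^2
    assert not feats.missing


def test_uav_features_constant_canopy_returns_constant():
    values = np.full((4, 4), 0.7)
    values[0, 0] = 0.2  # make quintiles non-degenerate outside the polygon
    ndvi = NdviGrid(values=values, transform=T)
    mask = CanopyMask(np.ones((4, 4), np.uint8), 0.1, "manual", T)
    feats = extract_uav_features(box(1, 0, 4, 3), ndvi, mask, make_vmap(ndvi))
    assert feats.ndvi_d == pytest.approx(0.7)


def test_uav_features_empty_mask_is_missing():
    ndvi = NdviGrid(values=np.full((4, 4), 0.5), transform=T)
    mask = CanopyMask(np.zeros((4, 4), np.uint8), 0.9, "manual", T)
    feats = extract_uav_features(box(0, 0, 4, 4), ndvi, mask, make_vmap(ndvi))
    assert feats.missing and feats.prj_area_d == 0.0 and math.isnan(feats.ndvi_d)


def test_uav_projected_area_bounded_by_polygon():
    ndvi = NdviGrid(values=np.full((4, 4), 0.5), transform=T)
    mask = CanopyMask(np.ones((4, 4), np.uint8), 0.1, "manual", T)
    poly = box(0.0, 0.0, 2.0, 4.0)
    feats = extract_uav_features(poly, ndvi, mask, make_vmap(ndvi))
    assert feats.prj_area_d <= poly.area + 1e-9


# ---------------------------------------------------------------------------
# satellite feature extraction


def sat_overlap_oracle(poly_bounds, ndvi: NdviGrid):
    """Axis-aligned rectangle-intersection areas, computed analytically."""
    x1, y1, x2, y2 = poly_bounds
    t = ndvi.transform
    total_w, total_wv = 0.0, 0.0
    best, best_w = None, -1.0
    for r in range(ndvi.values.shape[0]):
        for c in range(ndvi.values.shape[1]):
            px1, py1, px2, py2 = t.pixel_bounds(r, c)
            w = max(0.0, min(x2, px2) - max(x1, px1)) * max(0.0, min(y2, py2) - max(y1, py1))
            if w > 0:
                total_w += w
                total_wv += w * ndvi.values[r, c]
                if w > best_w:
                    best, best_w = (r, c), w
    return total_wv / total_w, best


def test_sat_features_single_pixel():
    t3 = GridTransform(0.0, 6.0, 3.0)
    values = np.array([[0.2, 0.3], [0.4, 0.5]])
    ndvi = NdviGrid(values=values, transform=t3)
    vmap = VigourMap(continuous=ndvi, classes=np.ones((2, 2), np.int8),
                     thresholds=(0.2, 0.3, 0.4, 0.5))
    feats = extract_sat_features(box(0.5, 3.5, 2.5, 5.5), ndvi, vmap)
    assert feats.ndvi_s == pytest.approx(0.2)


def test_sat_features_even_split():
    t3 = GridTransform(0.0, 3.0, 3.0)
    ndvi = NdviGrid(values=np.array([[0.2, 0.4]]), transform=t3)
    vmap = VigourMap(continuous=ndvi, classes=np.ones((1, 2), np.int8),
                     thresholds=(0, 0, 0, 1))
    feats = extract_sat_features(box(2.0, 1.0, 4.0, 2.0), ndvi, vmap)
    assert feats.ndvi_s == pytest.approx(0.3)


def test_sat_features_match_exact_intersection_oracle():
    t3 = GridTransform(0.0, 12.0, 3.0)
    rng = np.random.default_rng(23)
    values = rng.uniform(0.1, 0.6, size=(4, 4))
    ndvi = NdviGrid(values=values, transform=t3)
    classes = rng.integers(0, 3, size=(4, 4)).astype(np.int8)
    vmap = VigourMap(continuous=ndvi, classes=classes, thresholds=(0.1, 0.2, 0.3, 0.4))
    for _ in range(25):
        cx, cy = rng.uniform(1.5, 10.5), rng.uniform(1.5, 10.5)
        bounds = (cx - 1.1, cy - 0.6, cx + 1.1, cy + 0.6)
        feats = extract_sat_features(box(*bounds), ndvi, vmap)
        oracle_val, oracle_px = sat_overlap_oracle(bounds, ndvi)
        assert feats.ndvi_s == pytest.approx(oracle_val, abs=1e-10)


def test_sat_features_outside_raster_missing():
    t3 = GridTransform(0.0, 3.0, 3.0)
    ndvi = NdviGrid(values=np.array([[np.nan]]), transform=t3)
    vmap = VigourMap(continuous=ndvi, classes=np.full((1, 1), -1, np.int8),
                     thresholds=(0, 0, 0, 0))
    feats = extract_sat_features(box(0, 0, 3, 3), ndvi, vmap)
    assert feats.missing


# ---------------------------------------------------------------------------
# record assembly


def _tables():
    manual = pd.DataFrame(
        {"vine_id": ["v1", "v2"], "stage": ["BBCH75"] * 2,
         "H_M": [0.78, 0.9], "W_M": [0.33, 0.4]}
    )
    uav = pd.DataFrame(
        {"vine_id": ["v1", "v2"], "stage": ["BBCH75"] * 2,
         "NDVI_D": [0.72, 0.8], "Prj_area_D": [0.17, 0.0],
         "C_vigour_D": ["medium", "high"]}
    )
    sat = pd.DataFrame(
        {"vine_id": ["v1", "v2"], "stage": ["BBCH75"] * 2,
         "NDVI_S": [0.54, 0.5], "C_vigour_S": ["medium", "high"],
         "Edge_pnt": [False, True]}
    )
    return manual, uav, sat


def test_assemble_reproduces_worked_row():
    manual, uav, sat = _tables()
    records = assemble_records(manual, uav, sat, "A", "Chardonnay", 2019, 2.2)
    row = records.loc[records["Vine"] == "v1"].iloc[0]
    assert round(row["NDVI_D_x_Prj_area_D"], 2) == 0.12  # 0.72 x 0.17
    assert round(row["LWA_M"], 2) == 7090.91
    assert round(row["TRV_M"], 2) == 1170.00
    zero_area = records.loc[records["Vine"] == "v2"].iloc[0]
    assert zero_area["NDVI_D_x_Prj_area_D"] == 0.0


def test_assemble_reports_orphan_keys():
    manual, uav, sat = _tables()
    uav_extra = pd.concat(
        [uav, pd.DataFrame({"vine_id": ["v9"], "stage": ["BBCH75"], "NDVI_D": [0.5],
                            "Prj_area_D": [0.1], "C_vigour_D": ["low"]})],
        ignore_index=True,
    )
    with pytest.raises(JoinError, match="v9"):
        assemble_records(manual, uav_extra, sat, "A", "Chardonnay", 2019, 2.2)


def test_full_run_record_count(plot_a_field):
    """End to end the database holds one row per sampled vine per stage."""
    from vinecanopy.config import RunConfig
    from vinecanopy.pipeline import build_records

    cfg = RunConfig()
    cfg.stages = ("BBCH59", "BBCH75")
    cfg.analysis.make_plots = False
    records, _, design = build_records(cfg)
    assert len(records) == len(design.selected) * len(cfg.stages)
    # internal consistency of the derived columns
    np.testing.assert_allclose(
        records["NDVI_D_x_Prj_area_D"], records["NDVI_D"] * records["Prj_area_D"]
    )
    np.testing.assert_allclose(
        records["LWA_M"], 2 * records["H_M"] * 1e4 / 2.2, rtol=1e-12
    )
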