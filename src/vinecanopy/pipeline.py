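"""End-to-end orchestration: simulate -> map vigour -> extract -> analyse.

This module glues the library together for the CLI and for reproduction
scripts. Every step takes its seed from the named seeds in the run config, so
a full run is a pure function of the config.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import box

from . import io
from .canopy_metrics import ManualMeasurement, summarise_manual
from .config import RunConfig, config_hash
from .sampling_extraction import (
    SamplingDesign,
    assemble_records,
    classify_edge,
    extract_sat_features,
    extract_uav_features,
    sur_sample,
    vine_polygon,
)
from .stats_models import (
    RESPONSES,
    CorrelationMatrix,
    RegressionOutcome,
    ad_analysis,
    edge_sensitivity,
    outcomes_to_frame,
    spd_analysis,
    spearman_matrix,
)
from .synthetic_scene import (
    FieldSpec,
    MultispectralScene,
    SceneParams,
    VigourFieldParams,
    VineTruth,
    assign_truth,
    degrade_to_satellite,
    generate_layout,
    render_scene,
    truth_to_frame,
)
from .vigour_mapping import (
    CanopyMask,
    NdviGrid,
    VigourMap,
    anchors_from_masked,
    classify_quintiles,
    compute_ndvi,
    idw_interpolate,
    mask_ndvi,
    satellite_vigour,
    segment_canopy,
)

__all__ = [
    "StageProducts",
    "AnalysisResults",
    "build_field",
    "build_scene_params",
    "build_vigour_params",
    "simulate_stage",
    "simulate_manual",
    "build_records",
    "analyse_records",
    "run_all",
    "UAV_PREDICTOR",
    "SAT_PREDICTOR",
    "UAV_VARIABLES",
    "SAT_VARIABLES",
]

UAV_PREDICTOR = "NDVI_D_x_Prj_area_D"
SAT_PREDICTOR = "NDVI_S"
UAV_VARIABLES = ["NDVI_D", "Prj_area_D", UAV_PREDICTOR, *RESPONSES]
SAT_VARIABLES = [SAT_PREDICTOR, *RESPONSES]


@dataclass
class StageProducts:
    """Everything derived from one plot at one growth stage."""

    stage: str
    truths: list[VineTruth]
    scene: MultispectralScene
    ndvi: NdviGrid
    mask: CanopyMask
    vmap: VigourMap
    sat_scene: MultispectralScene
    ndvi_s: NdviGrid
    vmap_s: VigourMap


@dataclass
class AnalysisResults:
    spearman_uav: CorrelationMatrix
    spearman_sat_with_edges: CorrelationMatrix
    spearman_sat_without_edges: CorrelationMatrix
    uav_spd: list[RegressionOutcome]
    uav_ad: list[RegressionOutcome]
    sat_spd: list[RegressionOutcome]
    sat_ad: list[RegressionOutcome]


def build_field(cfg: RunConfig) -> FieldSpec:
    f = cfg.field
    boundary = box(f.origin_x, f.origin_y, f.origin_x + f.width_m, f.origin_y + f.length_m)
    return FieldSpec(
        boundary=boundary,
        row_spacing=f.row_spacing,
        vine_spacing=f.vine_spacing,
        row_azimuth=f.row_azimuth,
        plot_id=f.plot_id,
        variety=f.variety,
    )


def build_scene_params(cfg: RunConfig) -> SceneParams:
    s = cfg.scene
    return SceneParams(
        gsd=s.gsd,
        noise_sd=s.noise_sd,
        weed_patch_density=s.weed_patch_density,
        shadow_offset=s.shadow_offset,
        margin=s.margin,
    )


def build_vigour_params(cfg: RunConfig) -> VigourFieldParams:
    v = cfg.vigour
    return VigourFieldParams(
        base=v.base,
        trend=(v.trend_x, v.trend_y),
        n_bumps=v.n_bumps,
        bump_amplitude=v.bump_amplitude,
        bump_length_scale=v.bump_length_scale,
        noise_sd=v.noise_sd,
        h_min=v.h_min,
        h_max=v.h_max,
        w_min=v.w_min,
        w_max=v.w_max,
    )


def simulate_stage(
    cfg: RunConfig, field_spec: FieldSpec, layout: list[VineTruth], stage: str,
    stage_idx: int,
) -> StageProducts:
    """Render one stage and run both vigour-mapping paths on it."""
    truths = assign_truth(layout, stage, build_vigour_params(cfg), seed=cfg.seeds.vigour)
    scene = render_scene(
        truths, field_spec, build_scene_params(cfg), seed=cfg.seeds.scene + stage_idx
    )
    ndvi = compute_ndvi(scene)
    mask = segment_canopy(ndvi, threshold=cfg.mapping.threshold)
    masked = mask_ndvi(ndvi, mask)
    anchors = anchors_from_masked(masked, mask)
    continuous = idw_interpolate(
        anchors,
        ndvi.transform,
        ndvi.values.shape,
        power=cfg.mapping.idw_power,
        k=cfg.mapping.idw_neighbours,
        crs=ndvi.crs,
    )
    vmap = classify_quintiles(continuous)

    sat_scene = degrade_to_satellite(scene, target_gsd=cfg.scene.satellite_gsd)
    ndvi_s = compute_ndvi(sat_scene)
    vmap_s = satellite_vigour(ndvi_s, plot_boundary=field_spec.boundary)
    return StageProducts(
        stage=stage, truths=truths, scene=scene, ndvi=ndvi, mask=mask, vmap=vmap,
        sat_scene=sat_scene, ndvi_s=ndvi_s, vmap_s=vmap_s,
    )


def simulate_manual(
    truths: list[VineTruth], selected: tuple[str, ...], stage: str, noise_sd: float,
    rng: np.random.Generator,
) -> list[ManualMeasurement]:
    """Emulate two surveyors measuring each sampled vine three times with a tape."""
    by_id = {t.vine_id: t for t in truths}
    out = []
    for vid in selected:
        t = by_id[vid]
        h_obs = np.clip(rng.normal(t.height_true, noise_sd, size=6), 0.0, None)
        w_obs = np.clip(rng.normal(t.width_true, noise_sd, size=6), 0.0, None)
        out.append(
            ManualMeasurement(
                vine_id=vid, stage=stage,
                height_obs=tuple(float(v) for v in h_obs),
                width_obs=tuple(float(v) for v in w_obs),
            )
        )
    return out


def build_records(cfg: RunConfig):
    """Simulate the full study for one plot: returns (records, products, design).

    ``records`` is the per-vine database (one row per sampled vine per stage);
    ``products`` maps stage -> StageProducts.
    """
    field_spec = build_field(cfg)
    layout = generate_layout(field_spec)
    if not layout:
        raise ValueError("field too small: layout is empty")
    design: SamplingDesign = sur_sample(
        layout, cfg.sampling.row_period, cfg.sampling.vine_period, seed=cfg.seeds.sampling
    )
    meas_rng = np.random.default_rng(cfg.seeds.measurement)

    products: dict[str, StageProducts] = {}
    all_records: list[pd.DataFrame] = []
    layout_by_id = {v.vine_id: v for v in layout}
    for stage_idx, stage in enumerate(cfg.stages):
        sp = simulate_stage(cfg, field_spec, layout, stage, stage_idx)
        products[stage] = sp
        truths_by_id = {t.vine_id: t for t in sp.truths}

        manual = summarise_manual(
            simulate_manual(
                sp.truths, design.selected, stage, cfg.analysis.measurement_noise_sd,
                meas_rng,
            ),
            cfg.field.row_spacing,
        )

        uav_rows, sat_rows = [], []
        for vid in design.selected:
            poly = vine_polygon(layout_by_id[vid], field_spec)
            uf = extract_uav_features(poly, sp.ndvi, sp.mask, sp.vmap)
            sf = extract_sat_features(poly, sp.ndvi_s, sp.vmap_s)
            edge = classify_edge(poly, field_spec.boundary, buffer=cfg.sampling.edge_buffer)
            uav_rows.append(
                {"vine_id": vid, "stage": stage, "NDVI_D": uf.ndvi_d,
                 "Prj_area_D": uf.prj_area_d, "C_vigour_D": uf.c_vigour_d}
            )
            sat_rows.append(
                {"vine_id": vid, "stage": stage, "NDVI_S": sf.ndvi_s,
                 "C_vigour_S": sf.c_vigour_s, "Edge_pnt": edge}
            )
        records = assemble_records(
            manual,
            pd.DataFrame(uav_rows),
            pd.DataFrame(sat_rows),
            plot_id=cfg.field.plot_id,
            variety=cfg.field.variety,
            year=cfg.analysis.year,
            row_spacing=cfg.field.row_spacing,
        )
        all_records.append(records)

    return pd.concat(all_records, ignore_index=True), products, design


def ndvi_amplitudes(
    products: dict[str, StageProducts], boundary=None
) -> pd.DataFrame:
    """Max-minus-min NDVI over vine-covering pixels, per stage and platform.

    Fine grid: pixels inside the painted canopy footprint. Coarse grid: pixels
    that cover canopy *and* whose centre lies inside the plot boundary — a
    coarse pixel centred outside the plot is adjacent land cover, not a
    vine-covering pixel, even when a sliver of canopy falls into it.
    """
    import shapely as _shp

    rows = []
    for stage, sp in products.items():
        fine = sp.ndvi.values[(sp.scene.canopy_truth) & np.isfinite(sp.ndvi.values)]
        cover = sp.sat_scene.canopy_truth
        keep = (cover > 0) & np.isfinite(sp.ndvi_s.values)
        if boundary is not None:
            gx, gy = sp.ndvi_s.transform.centre_mesh(sp.ndvi_s.values.shape)
            inside = _shp.contains_xy(boundary, gx.ravel(), gy.ravel())
            keep &= inside.reshape(sp.ndvi_s.values.shape)
        coarse = sp.ndvi_s.values[keep]
        rows.append(
            {
                "stage": stage,
                "uav_amplitude": float(np.ptp(fine)) if fine.size else np.nan,
                "sat_amplitude": float(np.ptp(coarse)) if coarse.size else np.nan,
            }
        )
    return pd.DataFrame(rows)


def analyse_records(records: pd.DataFrame, cfg: RunConfig) -> AnalysisResults:
    """Correlation screening plus SPD and AD gated regressions, both platforms."""
    spearman_uav = spearman_matrix(records, UAV_VARIABLES)
    with_edges, without_edges = edge_sensitivity(records, SAT_VARIABLES)

    alpha = cfg.analysis.alpha
    uav_spd = spd_analysis(records, UAV_PREDICTOR, alpha=alpha)
    uav_ad = ad_analysis(records, UAV_PREDICTOR, class_col="C_vigour_D", alpha=alpha)

    sat_records = records
    if cfg.analysis.satellite_reject_edges:
        sat_records = records.loc[~records["Edge_pnt"].astype(bool)]
    sat_spd = spd_analysis(sat_records, SAT_PREDICTOR, alpha=alpha)
    sat_ad = ad_analysis(sat_records, SAT_PREDICTOR, class_col="C_vigour_S", alpha=alpha)
    return AnalysisResults(
        spearman_uav=spearman_uav,
        spearman_sat_with_edges=with_edges,
        spearman_sat_without_edges=without_edges,
        uav_spd=uav_spd,
        uav_ad=uav_ad,
        sat_spd=sat_spd,
        sat_ad=sat_ad,
    )


# ---------------------------------------------------------------------------
# artefact writing


def _sidecar_meta(cfg: RunConfig) -> dict:
    from . import __version__

    return {
        "config_hash": config_hash(cfg),
        "seeds": cfg.to_dict()["seeds"],
        "package": f"vinecanopy {__version__}",
    }


def _write_vigour_rasters(outdir: Path, products: dict[str, StageProducts],
                          cfg: RunConfig) -> list[Path]:
    meta = _sidecar_meta(cfg)
    written = []
    for stage, sp in products.items():
        for label, grid, vmap in (
            (f"vigour_uav_{stage}.tif", sp.vmap.continuous, sp.vmap),
            (f"vigour_sat_{stage}.tif", sp.vmap_s.continuous, sp.vmap_s),
        ):
            path = outdir / label
            io.write_raster(
                path,
                {"NDVI": grid.values, "CLASS": vmap.classes.astype(np.float32)},
                grid.transform,
                grid.crs,
            )
            io.write_sidecar(
                path,
                {
                    **meta,
                    "quintile_thresholds": list(vmap.thresholds),
                    "class_codes": {"low": 0, "medium": 1, "high": 2, "nodata": -1},
                    "class_colours": {"low": "red", "medium": "yellow", "high": "green"},
                    "segmentation": {
                        "threshold": sp.mask.threshold_used, "method": sp.mask.method,
                    },
                },
            )
            written.append(path)
    return written


def _write_report(outdir: Path, results: AnalysisResults, amplitudes: pd.DataFrame,
                  n_records: int) -> Path:
    lines = [
        "Vineyard canopy characterisation report",
        "=======================================",
        f"records: {n_records}",
        "",
        "NDVI amplitude (max - min over vine-covering pixels) per stage:",
        amplitudes.to_string(index=False),
        "",
        "Spearman rho, UAV variables:",
        results.spearman_uav.to_frame().round(3).to_string(),
        "",
        "Spearman rho, satellite NDVI vs manual parameters:",
        "  considering edge points:",
        results.spearman_sat_with_edges.to_frame().round(3).to_string(),
        "  rejecting edge points:",
        results.spearman_sat_without_edges.to_frame().round(3).to_string(),
        "",
        "Gated Ln-Ln regressions:",
    ]
    frames = [
        outcomes_to_frame(results.uav_spd, "UAV"),
        outcomes_to_frame(results.uav_ad, "UAV"),
        outcomes_to_frame(results.sat_spd, "satellite"),
        outcomes_to_frame(results.sat_ad, "satellite"),
    ]
    lines.append(pd.concat(frames, ignore_index=True).round(4).to_string(index=False))
    path = outdir / "report.txt"
    path.write_text("\n".join(lines) + "\n")
    return path


def _write_plots(outdir: Path, records: pd.DataFrame, results: AnalysisResults,
                 cfg: RunConfig) -> None:
    from .plots import plot_regression_grid

    sat_records = records
    if cfg.analysis.satellite_reject_edges:
        sat_records = records.loc[~records["Edge_pnt"].astype(bool)]
    plot_regression_grid(records, results.uav_spd, outdir / "fig_uav_spd.png")
    plot_regression_grid(records, results.uav_ad, outdir / "fig_uav_ad.png")
    plot_regression_grid(sat_records, results.sat_spd, outdir / "fig_sat_spd.png")
    plot_regression_grid(sat_records, results.sat_ad, outdir / "fig_sat_ad.png")


def run_all(cfg: RunConfig, outdir: str | Path) -> dict[str, Path]:
    """Full pipeline; writes all artefacts with metadata sidecars, returns paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = _sidecar_meta(cfg)

    records, products, design = build_records(cfg)
    results = analyse_records(records, cfg)
    amplitudes = ndvi_amplitudes(products, boundary=build_field(cfg).boundary)

    paths: dict[str, Path] = {}

    records_path = outdir / "vine_records.csv"
    io.write_table(records, records_path)
    io.write_sidecar(records_path, {**meta, "sampling_design": {
        "row_period": design.row_period, "vine_period": design.vine_period,
        "start_row": design.start_row, "start_vine": design.start_vine,
        "n_selected": len(design.selected)}})
    paths["records"] = records_path

    truth_frames = [
        truth_to_frame(sp.truths, cfg.field.plot_id) for sp in products.values()
    ]
    truth_path = outdir / "vine_truth.csv"
    io.write_table(pd.concat(truth_frames, ignore_index=True), truth_path)
    paths["truth"] = truth_path

    for p in _write_vigour_rasters(outdir, products, cfg):
        paths[p.stem] = p

    corr_tables = {
        "spearman_uav.csv": results.spearman_uav,
        "spearman_sat_with_edges.csv": results.spearman_sat_with_edges,
        "spearman_sat_without_edges.csv": results.spearman_sat_without_edges,
    }
    for name, matrix in corr_tables.items():
        path = outdir / name
        matrix.to_frame().round(6).to_csv(path)
        paths[name] = path

    reg_path = outdir / "regressions.csv"
    reg_frame = pd.concat(
        [
            outcomes_to_frame(results.uav_spd, "UAV"),
            outcomes_to_frame(results.uav_ad, "UAV"),
            outcomes_to_frame(results.sat_spd, "satellite"),
            outcomes_to_frame(results.sat_ad, "satellite"),
        ],
        ignore_index=True,
    )
    io.write_table(reg_frame, reg_path)
    io.write_sidecar(reg_path, meta)
    paths["regressions"] = reg_path

    paths["report"] = _write_report(outdir, results, amplitudes, len(records))

    if cfg.analysis.make_plots:
        _write_plots(outdir, records, results, cfg)

    return paths
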