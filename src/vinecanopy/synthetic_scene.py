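"""Synthetic vineyard scenes: layouts, per-vine ground truth, multispectral rasters.

The generator emulates the data the analysis assumes: row-structured vineyards
(hedgerow training, rows a fixed spacing apart, vines a fixed step along each
row), a spatially smooth vigour field driving canopy size and canopy spectra,
soil/weed/shadow background, a fine-resolution (UAV-scale, ~6.5 cm) band stack
and a coarse (satellite-scale, 3 m) stack derived from it by area-weighted
pixel mixing.

Vigour is a latent scalar in [0, 1] per vine: a linear spatial trend plus a few
Gaussian bumps plus iid noise, clamped. Canopy height and width are affine in
vigour and scaled by growth stage (BBCH 59 baseline; BBCH 75 and 81 are 1.5x
the baseline, with no further growth between 75 and 81 — canopies are hedged
and topped after fruit set, which plateaus the envelope dimensions).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import shapely
import shapely.affinity
from shapely.geometry import Polygon

from .geo import GridTransform

__all__ = [
    "BAND_SETS",
    "STAGES",
    "STAGE_SCALE",
    "FieldSpec",
    "VineTruth",
    "VigourFieldParams",
    "SceneParams",
    "MultispectralScene",
    "gsd_from_sensor",
    "generate_layout",
    "assign_truth",
    "vine_canopy_polygon",
    "rasterize_canopy",
    "render_scene",
    "degrade_to_satellite",
    "truth_to_frame",
    "frame_to_truth",
]

#: Band name order for the two sensor dialects.
BAND_SETS: dict[str, tuple[str, ...]] = {
    "UAV5": ("R", "G", "B", "RE", "NIR"),
    "SAT4": ("B", "G", "R", "NIR"),
}

STAGES = ("BBCH59", "BBCH75", "BBCH81")

#: Canopy dimension multiplier per growth stage (plateau after BBCH75).
STAGE_SCALE = {"BBCH59": 1.0, "BBCH75": 1.5, "BBCH81": 1.5}


class InvalidParameterError(ValueError):
    pass


class DegenerateRasterError(ValueError):
    pass


def gsd_from_sensor(
    altitude_m: float, focal_length_m: float, pixel_pitch_m: float
) -> float:
    """Ground sample distance (m per pixel) of a nadir frame camera.

    GSD = flight altitude x detector pixel pitch / focal length. A 95 m flight
    with a 5.5 mm lens and 3.75 um pixels yields ~0.0648 m (6.48 cm).
    """
    if min(altitude_m, focal_length_m, pixel_pitch_m) <= 0:
        raise InvalidParameterError("altitude, focal length and pixel pitch must be > 0")
    return altitude_m * pixel_pitch_m / focal_length_m


@dataclass(frozen=True)
class FieldSpec:
    """One vineyard plot: boundary polygon plus planting geometry.

    ``row_azimuth`` is the direction the rows run, in degrees clockwise from
    north (0 = rows run south->north).
    """

    boundary: Polygon
    row_spacing: float
    vine_spacing: float
    row_azimuth: float = 0.0
    plot_id: str = "A"
    variety: str = "Chardonnay"

    def __post_init__(self) -> None:
        if self.row_spacing <= 0 or self.vine_spacing <= 0:
            raise InvalidParameterError("row/vine spacing must be > 0")
        if not self.boundary.is_valid or self.boundary.area <= 0:
            raise InvalidParameterError("boundary must be a simple polygon with area > 0")

    @property
    def axes(self) -> tuple[np.ndarray, np.ndarray]:
        """(along-row, across-row) unit vectors in the x/y plane."""
        theta = math.radians(self.row_azimuth)
        along = np.array([math.sin(theta), math.cos(theta)])
        across = np.array([math.cos(theta), -math.sin(theta)])
        return along, across


@dataclass
class VineTruth:
    """Ground truth for one vine (positions first; stage/size after assignment)."""

    vine_id: str
    row_index: int
    along_row_position: float
    x: float
    y: float
    stage: str | None = None
    height_true: float | None = None
    width_true: float | None = None
    vigour_true: float | None = None

    @property
    def centre(self) -> tuple[float, float]:
        return (self.x, self.y)


@dataclass(frozen=True)
class VigourFieldParams:
    """Latent vigour field: linear trend + Gaussian bumps + iid noise, clamped to [0, 1].

    Defaults give plots with distinct low/medium/high zones over a few tens of
    metres, and canopy envelopes typical of double-cordon vines at the start of
    flowering (heights 0.5-0.85 m, widths 0.20-0.40 m before stage scaling).
    """

    base: float = 0.5
    trend: tuple[float, float] = (0.006, 0.002)  # d(vigour)/dx, d(vigour)/dy per metre
    n_bumps: int = 3
    bump_amplitude: float = 0.25
    bump_length_scale: float = 8.0  # metres
    noise_sd: float = 0.05
    h_min: float = 0.5
    h_max: float = 0.85
    w_min: float = 0.20
    w_max: float = 0.40

    def __post_init__(self) -> None:
        if self.h_min > self.h_max or self.w_min > self.w_max:
            raise InvalidParameterError("h_min/w_min must not exceed h_max/w_max")
        if self.noise_sd < 0 or self.bump_length_scale <= 0:
            raise InvalidParameterError("noise_sd >= 0 and bump_length_scale > 0 required")


# Affine reflectance-vs-vigour canopy model and background constants per band.
# Chosen so noiseless canopy NDVI spans ~0.70 (vigour 0) to ~0.89 (vigour 1),
# soil NDVI ~0.2, weeds ~0.45 — the separability the threshold step relies on.
_DEFAULT_CANOPY = {
    "R": (0.08, -0.04),
    "G": (0.10, -0.03),
    "B": (0.05, -0.02),
    "RE": (0.25, 0.05),
    "NIR": (0.45, 0.25),
}
_DEFAULT_SOIL = {"R": 0.20, "G": 0.18, "B": 0.15, "RE": 0.25, "NIR": 0.30}
_DEFAULT_WEED = {"R": 0.12, "G": 0.13, "B": 0.09, "RE": 0.25, "NIR": 0.32}


@dataclass(frozen=True)
class SceneParams:
    """Rendering parameters for one multispectral raster."""

    gsd: float = 0.0648
    band_set: str = "UAV5"
    canopy_reflectance: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_CANOPY)
    )
    soil_reflectance: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_SOIL))
    weed_reflectance: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_WEED))
    weed_patch_density: float = 20.0  # patches per hectare
    shadow_offset: float = 0.15  # gap between canopy edge and shadow strip, metres
    shadow_width: float = 0.30  # strip width, metres
    shadow_factor: float = 0.4  # multiplicative darkening
    noise_sd: float = 0.01  # reflectance noise, per band
    margin: float = 5.0  # bare-soil apron around the plot boundary, metres

    def __post_init__(self) -> None:
        if self.gsd <= 0:
            raise InvalidParameterError("gsd must be > 0")
        if self.band_set not in BAND_SETS:
            raise InvalidParameterError(f"unknown band set {self.band_set!r}")
        for b in BAND_SETS[self.band_set]:
            if b not in self.canopy_reflectance or b not in self.soil_reflectance:
                raise InvalidParameterError(f"no reflectance model for band {b!r}")
        for v in (0.0, 1.0):
            for b, (icpt, slope) in self.canopy_reflectance.items():
                refl = icpt + slope * v
                if not 0.0 <= refl <= 1.0:
                    raise InvalidParameterError(f"canopy reflectance out of [0,1] for {b}")
        if not all(0.0 <= r <= 1.0 for r in self.soil_reflectance.values()):
            raise InvalidParameterError("soil reflectance out of [0,1]")
        # separability precondition: noiseless canopy NDVI > soil NDVI
        soil = _ndvi_of(self.soil_reflectance["NIR"], self.soil_reflectance["R"])
        for v in (0.0, 1.0):
            nir = _affine(self.canopy_reflectance["NIR"], v)
            red = _affine(self.canopy_reflectance["R"], v)
            if _ndvi_of(nir, red) <= soil:
                raise InvalidParameterError("canopy NDVI must exceed soil NDVI")


def _affine(coeffs: tuple[float, float], v: float) -> float:
    return coeffs[0] + coeffs[1] * v


def _ndvi_of(nir: float, red: float) -> float:
    return (nir - red) / (nir + red)


@dataclass
class MultispectralScene:
    """A georeferenced stack of surface-reflectance bands.

    ``canopy_truth`` (optional) is the renderer's painted canopy footprint — a
    boolean grid kept for validation; it is not part of the raster contract and
    is not serialised to GeoTIFF.
    """

    bands: dict[str, np.ndarray]
    transform: GridTransform
    crs: str = "EPSG:25831"
    band_set: str = "UAV5"
    canopy_truth: np.ndarray | None = None

    def __post_init__(self) -> None:
        shapes = {b.shape for b in self.bands.values()}
        if len(shapes) != 1:
            raise ValueError("all bands must share one shape")
        for name, arr in self.bands.items():
            if arr.min() < 0.0 or arr.max() > 1.0:
                raise ValueError(f"band {name!r} has reflectance outside [0, 1]")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.bands.values())).shape


# ---------------------------------------------------------------------------
# layout and truth


def generate_layout(field_spec: FieldSpec, seed: int = 0) -> list[VineTruth]:
    """Place vine centres on the row grid implied by the field geometry.

    Rows are parallel lines ``row_spacing`` apart oriented along
    ``row_azimuth``; vines sit every ``vine_spacing`` along each row. The grid
    is centred in the boundary's rotated bounding box and centres falling
    outside the boundary are dropped. A boundary too small to hold one full
    spacing cell in either direction yields an empty list.

    Deterministic; ``seed`` is accepted for interface uniformity (the grid
    itself involves no randomness).
    """
    along, across = field_spec.axes
    coords = shapely.get_coordinates(field_spec.boundary.exterior)
    u = coords @ across  # across-row coordinate
    v = coords @ along  # along-row coordinate
    uspan, vspan = u.max() - u.min(), v.max() - v.min()

    n_rows = int(math.floor(uspan / field_spec.row_spacing + 1e-9))
    n_vines = int(math.floor(vspan / field_spec.vine_spacing + 1e-9))
    if n_rows < 1 or n_vines < 1:
        return []

    u0 = u.min() + (uspan - (n_rows - 1) * field_spec.row_spacing) / 2.0
    v0 = v.min() + (vspan - (n_vines - 1) * field_spec.vine_spacing) / 2.0

    vines: list[VineTruth] = []
    for i in range(n_rows):
        ui = u0 + i * field_spec.row_spacing
        for j in range(n_vines):
            vj = v0 + j * field_spec.vine_spacing
            xy = ui * across + vj * along
            if not field_spec.boundary.contains(shapely.points(xy[0], xy[1])):
                continue
            vines.append(
                VineTruth(
                    vine_id=f"{field_spec.plot_id}-r{i + 1:02d}-v{j + 1:03d}",
                    row_index=i + 1,
                    along_row_position=vj - v0,
                    x=float(xy[0]),
                    y=float(xy[1]),
                )
            )
    return vines


def _vigour_surface(xy: np.ndarray, params: VigourFieldParams, rng: np.random.Generator,
                    bbox: tuple[float, float, float, float]) -> np.ndarray:
    """Evaluate the latent vigour field at (n, 2) points."""
    xmin, ymin, xmax, ymax = bbox
    cx, cy = (xmin + xmax) / 2.0, (ymin + ymax) / 2.0
    v = params.base + params.trend[0] * (xy[:, 0] - cx) + params.trend[1] * (xy[:, 1] - cy)
    for _ in range(params.n_bumps):
        centre = rng.uniform([xmin, ymin], [xmax, ymax])
        amp = rng.uniform(-params.bump_amplitude, params.bump_amplitude)
        d2 = ((xy - centre) ** 2).sum(axis=1)
        v = v + amp * np.exp(-d2 / (2.0 * params.bump_length_scale**2))
    v = v + rng.normal(0.0, params.noise_sd, size=len(xy))
    return np.clip(v, 0.0, 1.0)


def assign_truth(
    layout: list[VineTruth],
    stage: str,
    vigour_params: VigourFieldParams,
    seed: int,
) -> list[VineTruth]:
    """Draw per-vine vigour and derive canopy height/width for one growth stage.

    height = (h_min + (h_max - h_min) * vigour) * stage_scale, width analogous.
    The same seed reproduces the same vigour field across stages, so repeated
    calls model the same plot observed at different dates.
    """
    if not layout:
        raise InvalidParameterError("layout must be non-empty")
    if stage not in STAGE_SCALE:
        raise InvalidParameterError(f"unknown stage {stage!r}; expected one of {STAGES}")
    rng = np.random.default_rng(seed)
    xy = np.array([[v.x, v.y] for v in layout])
    bbox = (xy[:, 0].min(), xy[:, 1].min(), xy[:, 0].max(), xy[:, 1].max())
    vigour = _vigour_surface(xy, vigour_params, rng, bbox)
    scale = STAGE_SCALE[stage]
    out = []
    for vine, vig in zip(layout, vigour):
        out.append(
            replace(
                vine,
                stage=stage,
                vigour_true=float(vig),
                height_true=float(
                    (vigour_params.h_min + (vigour_params.h_max - vigour_params.h_min) * vig)
                    * scale
                ),
                width_true=float(
                    (vigour_params.w_min + (vigour_params.w_max - vigour_params.w_min) * vig)
                    * scale
                ),
            )
        )
    return out


def vine_canopy_polygon(vine: VineTruth, field_spec: FieldSpec) -> Polygon:
    """Rectangular canopy footprint: along-row length min(vine_spacing, 1.2 m),
    across-row width = width_true, centred on the vine, oriented with the row."""
    if vine.width_true is None:
        raise InvalidParameterError("vine has no assigned width_true")
    along, across = field_spec.axes
    half_l = min(field_spec.vine_spacing, 1.2) / 2.0
    half_w = vine.width_true / 2.0
    c = np.array([vine.x, vine.y])
    corners = [
        c + half_l * along + half_w * across,
        c + half_l * along - half_w * across,
        c - half_l * along - half_w * across,
        c - half_l * along + half_w * across,
    ]
    return Polygon([tuple(p) for p in corners])


def _paint(mask_target: np.ndarray, poly: Polygon, transform: GridTransform) -> None:
    """Set True on cells whose centres fall inside the polygon (in place)."""
    nrow, ncol = mask_target.shape
    xmin, ymin, xmax, ymax = poly.bounds
    r0, c0 = transform.index_of(xmin, ymax)
    r1, c1 = transform.index_of(xmax, ymin)
    r0, c0 = max(r0, 0), max(c0, 0)
    r1, c1 = min(r1 + 1, nrow - 1), min(c1 + 1, ncol - 1)
    if r1 < r0 or c1 < c0:
        return
    xs, ys = transform.cell_centres((nrow, ncol))
    gx, gy = np.meshgrid(xs[c0 : c1 + 1], ys[r0 : r1 + 1])
    inside = shapely.contains_xy(poly, gx.ravel(), gy.ravel()).reshape(gx.shape)
    mask_target[r0 : r1 + 1, c0 : c1 + 1] |= inside


def rasterize_canopy(
    truths: list[VineTruth], field_spec: FieldSpec, transform: GridTransform,
    shape: tuple[int, int]
) -> np.ndarray:
    """Boolean canopy-footprint grid (cell-centre-in-rectangle membership)."""
    mask = np.zeros(shape, dtype=bool)
    for vine in truths:
        _paint(mask, vine_canopy_polygon(vine, field_spec), transform)
    return mask


def render_scene(
    truths: list[VineTruth],
    field_spec: FieldSpec,
    params: SceneParams,
    seed: int,
) -> MultispectralScene:
    """Render a reflectance band stack for one plot and date.

    Background soil first, then weed patches (intermediate NDVI), then canopy
    rectangles (reflectance affine in each vine's vigour), then shadow strips
    immediately north of each canopy rectangle, then iid Gaussian noise
    truncated to [0, 1]. Deterministic given (seed, params).
    """
    xmin, ymin, xmax, ymax = field_spec.boundary.bounds
    xmin, ymin = xmin - params.margin, ymin - params.margin
    xmax, ymax = xmax + params.margin, ymax + params.margin
    ncol = int(math.ceil((xmax - xmin) / params.gsd))
    nrow = int(math.ceil((ymax - ymin) / params.gsd))
    if ncol < 1 or nrow < 1:
        raise DegenerateRasterError("gsd larger than the field extent")
    transform = GridTransform(origin_x=xmin, origin_y=ymax, pixel_size=params.gsd)
    shape = (nrow, ncol)
    rng = np.random.default_rng(seed)
    band_names = BAND_SETS[params.band_set]

    bands = {b: np.full(shape, params.soil_reflectance[b], dtype=np.float64)
             for b in band_names}

    # weed patches: circles of intermediate reflectance on the soil
    area_ha = (xmax - xmin) * (ymax - ymin) / 10_000.0
    n_patches = rng.poisson(params.weed_patch_density * area_ha)
    weed_mask = np.zeros(shape, dtype=bool)
    for _ in range(n_patches):
        centre = rng.uniform([xmin, ymin], [xmax, ymax])
        radius = rng.uniform(0.5, 1.5)
        _paint(weed_mask, shapely.points(*centre).buffer(radius, quad_segs=8), transform)
    for b in band_names:
        bands[b][weed_mask] = params.weed_reflectance[b]

    # canopy rectangles, vigour-dependent reflectance
    canopy_mask = np.zeros(shape, dtype=bool)
    along, across = field_spec.axes
    north = np.array([0.0, 1.0])
    shadow_mask = np.zeros(shape, dtype=bool)
    for vine in truths:
        poly = vine_canopy_polygon(vine, field_spec)
        vine_cells = np.zeros(shape, dtype=bool)
        _paint(vine_cells, poly, transform)
        canopy_mask |= vine_cells
        for b in band_names:
            bands[b][vine_cells] = _affine(params.canopy_reflectance[b], vine.vigour_true)
        shift = (vine.width_true / 2.0 + params.shadow_offset + params.shadow_width / 2.0)
        shadow_poly = shapely.affinity.translate(
            poly, xoff=float(north[0] * shift), yoff=float(north[1] * shift)
        )
        _paint(shadow_mask, shadow_poly, transform)

    shadow_only = shadow_mask & ~canopy_mask
    for b in band_names:
        bands[b][shadow_only] *= params.shadow_factor

    if params.noise_sd > 0:
        for b in band_names:
            bands[b] += rng.normal(0.0, params.noise_sd, size=shape)
    for b in band_names:
        np.clip(bands[b], 0.0, 1.0, out=bands[b])

    return MultispectralScene(
        bands=bands,
        transform=transform,
        band_set=params.band_set,
        canopy_truth=canopy_mask,
    )


# ---------------------------------------------------------------------------
# satellite degradation


def _block_weights(n_in: int, size_in: float, size_out: float) -> np.ndarray:
    """Row-stochastic (n_out, n_in) matrix of area-weighted 1-D block means.

    Partial blocks at the far edge are normalised over the source extent they
    actually cover — never truncated.
    """
    extent = n_in * size_in
    n_out = int(math.ceil(extent / size_out - 1e-9))
    w = np.zeros((n_out, n_in))
    for j in range(n_out):
        a, b = j * size_out, min((j + 1) * size_out, extent)
        i0 = int(math.floor(a / size_in + 1e-12))
        i1 = int(math.ceil(b / size_in - 1e-12))
        for i in range(i0, min(i1, n_in)):
            overlap = min(b, (i + 1) * size_in) - max(a, i * size_in)
            if overlap > 0:
                w[j, i] = overlap
        w[j] /= w[j].sum()
    return w


def degrade_to_satellite(
    scene: MultispectralScene, target_gsd: float = 3.0
) -> MultispectralScene:
    """Area-weighted block-mean resampling of reflectance to a coarser grid.

    Emulates pixel mixing at satellite resolution: each coarse pixel's
    reflectance is the area-weighted mean of the fine pixels it covers; any
    index (NDVI etc.) must be computed *after* this aggregation, which is what
    narrows its dynamic range relative to the fine grid.
    """
    if target_gsd <= scene.transform.pixel_size:
        raise InvalidParameterError("target_gsd must exceed the scene's pixel size")
    nrow, ncol = scene.shape
    wy = _block_weights(nrow, scene.transform.pixel_size, target_gsd)
    wx = _block_weights(ncol, scene.transform.pixel_size, target_gsd)
    out_bands: dict[str, np.ndarray] = {}
    for name in BAND_SETS["SAT4"]:
        if name not in scene.bands:
            raise InvalidParameterError(f"scene lacks band {name!r} needed for SAT4")
        out_bands[name] = np.clip(wy @ scene.bands[name] @ wx.T, 0.0, 1.0)
    coverage = None
    if scene.canopy_truth is not None:
        coverage = wy @ scene.canopy_truth.astype(float) @ wx.T
    transform = GridTransform(
        origin_x=scene.transform.origin_x,
        origin_y=scene.transform.origin_y,
        pixel_size=target_gsd,
    )
    return MultispectralScene(
        bands=out_bands,
        transform=transform,
        crs=scene.crs,
        band_set="SAT4",
        canopy_truth=coverage,
    )


# ---------------------------------------------------------------------------
# truth table round-trip

_TRUTH_COLUMNS = ["vine_id", "plot", "stage", "height_true", "width_true",
                  "vigour_true", "x", "y"]


def truth_to_frame(truths: list[VineTruth], plot_id: str) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "vine_id": [v.vine_id for v in truths],
            "plot": plot_id,
            "stage": [v.stage for v in truths],
            "height_true": [v.height_true for v in truths],
            "width_true": [v.width_true for v in truths],
            "vigour_true": [v.vigour_true for v in truths],
            "x": [v.x for v in truths],
            "y": [v.y for v in truths],
        },
        columns=_TRUTH_COLUMNS,
    )


def frame_to_truth(frame: pd.DataFrame) -> list[VineTruth]:
    """Inverse of :func:`truth_to_frame`; row/along indices are re-derived lazily
    from the vine_id encoding when present."""
    out = []
    for rec in frame.itertuples(index=False):
        row_index = 0
        parts = rec.vine_id.split("-")
        if len(parts) == 3 and parts[1].startswith("r"):
            row_index = int(parts[1][1:])
        out.append(
            VineTruth(
                vine_id=rec.vine_id,
                row_index=row_index,
                along_row_position=0.0,
                x=float(rec.x),
                y=float(rec.y),
                stage=rec.stage,
                height_true=float(rec.height_true),
                width_true=float(rec.width_true),
                vigour_true=float(rec.vigour_true),
            )
        )
    return out
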