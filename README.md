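# vinecanopy

Vineyard canopy characterisation from multispectral aerial imagery, for
precision-viticulture and spray-dosing workflows: from georeferenced
reflectance rasters (fine UAV-scale, ~6.5 cm; coarse satellite-scale, 3 m) to
three-class NDVI vigour maps, per-vine spectral/geometric features, and
regression models that estimate the canopy structure parameters a sprayer
operator actually needs — canopy height H, canopy width W, and the two
officially recognised dose-expression quantities

```
LWA = 2 · H · 10000 / s      leaf wall area   [m² ha⁻¹]
TRV = H · W · 10000 / s      tree row volume  [m³ ha⁻¹]
```

with `s` the row spacing in metres (the factor 2 counts both faces of the
hedgerow leaf wall).

## What it does

* **Synthetic vineyard scenes** (`vinecanopy.synthetic_scene`): row-structured
  layouts from a plot polygon and planting geometry, per-vine ground truth
  driven by a smooth latent vigour field, multispectral rendering
  (R/G/B/RE/NIR at UAV resolution) with soil, weed and shadow background, and
  area-weighted degradation to a 4-band 3 m satellite grid. Every run is a
  pure function of its seeds.
* **Vigour mapping** (`vinecanopy.vigour_mapping`): NDVI = (NIR − R)/(NIR + R);
  canopy segmentation by manual or Otsu threshold; masked NDVI;
  inverse-distance-weighting interpolation from canopy-pixel anchors to a
  continuous surface; quintile classification into low (< P20), medium and
  high (> P80) vigour. The unsegmentable satellite grid is classified raw.
* **Sampling and extraction** (`vinecanopy.sampling_extraction`): two-stage
  systematic uniform random (SUR) vine sampling; per-vine rectangular sampling
  polygons (1.2 m along the row × one row spacing); mean canopy NDVI,
  pixel-counted projected area and majority vigour class on the fine grid;
  exact overlap-area-weighted NDVI on the coarse grid; 3 m edge-point
  flagging; assembly into a per-vine database table.
* **Statistics** (`vinecanopy.stats_models`): Spearman correlation screening,
  Ln–Ln ordinary least squares gated by a Kolmogorov–Smirnov residual-normality
  test, in single-point (SPD: every vine-date one observation) and aggregated
  (AD: means per plot/year/stage/vigour-class cell) modes, plus an
  edge-sensitivity comparison of correlation matrices with and without
  edge-flagged vines.

## Worked example

```python
from vinecanopy import lwa, trv, gsd_from_sensor

print(f"LWA = {lwa(0.78, 2.2):.2f} m2/ha")   # LWA = 7090.91 m2/ha
print(f"TRV = {trv(0.78, 0.33, 2.2):.2f} m3/ha")  # TRV = 1170.00 m3/ha
print(f"GSD = {gsd_from_sensor(95.0, 5.5e-3, 3.75e-6)*100:.2f} cm/px")  # 6.48 cm/px
```

A vine measured at H = 0.78 m and W = 0.33 m in a plot with 2.2 m rows has a
7,090.91 m² ha⁻¹ leaf wall and a 1,170.00 m³ ha⁻¹ row volume; a 95 m flight
with a 5.5 mm lens and 3.75 µm detector pitch images at 6.48 cm per pixel.

Full synthetic study on the default desk-scale plot (22 m × 12 m, 100 vines,
three growth stages, 25 SUR-sampled vines):

```python
from vinecanopy.config import RunConfig
from vinecanopy.pipeline import build_records, analyse_records
from vinecanopy.stats_models import outcomes_to_frame

cfg = RunConfig()
records, products, design = build_records(cfg)
res = analyse_records(records, cfg)
print(outcomes_to_frame(res.uav_spd + res.uav_ad, "UAV").round(3))
```

prints (75 records = 25 vines × 3 stages; predictor is NDVI_D × Prj_area_D):

```
mode response  slope  intercept  r_squared  ks_p  verdict  n
 SPD      H_M  1.003      0.793      0.910 0.248 accepted 75
 SPD      W_M  1.032      0.034      0.924 0.507 accepted 75
 SPD    LWA_M  1.003      9.908      0.910 0.248 accepted 75
 SPD    TRV_M  2.036      9.249      0.921 0.763 accepted 75
  AD      H_M  1.057      0.845      0.948 0.918 accepted  9
  AD      W_M  1.106      0.101      0.978 0.991 accepted  9
  AD    LWA_M  1.057      9.960      0.948 0.918 accepted  9
  AD    TRV_M  2.164      9.368      0.966 0.927 accepted  9
```

Each row is one Ln–Ln fit: `ks_p` is the residual-normality p-value (the
model is rejected when it falls below 0.05), `r_squared` the coefficient of
determination, and the AD rows show the characteristic improvement from
averaging vines within vigour classes before fitting.

The same pipeline is available from the shell:

```
vinecanopy run-all --out results_dir          # scenes, maps, database, report
vinecanopy simulate | map-vigour | extract | analyse   # individual steps
```

All artefacts (GeoTIFF vigour maps, CSV tables, text report) are written with
JSON metadata sidecars carrying the config hash and seeds; re-running with the
same config is byte-identical.

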