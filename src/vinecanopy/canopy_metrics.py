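"""Manual canopy measurements and the dose-expression parameters LWA and TRV.

Height and width of each vine are measured with a tape by two surveyors, three
times each; the vine's value is the mean of the six replicates. From the mean
height H (m), mean width W (m) and row spacing s (m):

    LWA = 2 * H * 10000 / s      leaf wall area, m^2 per ground hectare
    TRV = H * W * 10000 / s      tree row volume, m^3 per ground hectare

The factor 2 counts both faces of the hedgerow leaf wall. Values are kept at
full precision internally; rounding to 2 d.p. happens only when writing CSV.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ManualMeasurement",
    "MissingDataError",
    "mean_measurement",
    "lwa",
    "trv",
    "read_manual_csv",
    "write_metrics_csv",
    "summarise_manual",
]

N_REPLICATES = 6  # 3 measurements x 2 surveyors


class MissingDataError(ValueError):
    pass


class InvalidParameterError(ValueError):
    pass


@dataclass(frozen=True)
class ManualMeasurement:
    """Six replicate height and width observations for one vine at one stage."""

    vine_id: str
    stage: str
    height_obs: tuple[float, ...]
    width_obs: tuple[float, ...]

    def __post_init__(self) -> None:
        for name, obs in (("height_obs", self.height_obs), ("width_obs", self.width_obs)):
            if len(obs) != N_REPLICATES:
                raise InvalidParameterError(
                    f"{name} needs exactly {N_REPLICATES} replicates, got {len(obs)}"
                )
            if any(o < 0 for o in obs):
                raise InvalidParameterError(f"{name} contains negative values")


def mean_measurement(obs) -> float:
    """Arithmetic mean of replicate observations."""
    obs = list(obs)
    if not obs:
        raise MissingDataError("no observations to average")
    return float(np.mean(obs))


def lwa(height: float, row_spacing: float) -> float:
    """Leaf wall area, m^2 ha^-1 (two-sided hedgerow wall)."""
    if row_spacing <= 0:
        raise InvalidParameterError(f"row_spacing must be > 0, got {row_spacing}")
    if height < 0:
        raise InvalidParameterError("height must be >= 0")
    return 2.0 * height * 10_000.0 / row_spacing


def trv(height: float, width: float, row_spacing: float) -> float:
    """Tree row volume, m^3 ha^-1 (hedgerow cross-section volume per hectare)."""
    if row_spacing <= 0:
        raise InvalidParameterError(f"row_spacing must be > 0, got {row_spacing}")
    if height < 0 or width < 0:
        raise InvalidParameterError("height and width must be >= 0")
    return height * width * 10_000.0 / row_spacing


# ---------------------------------------------------------------------------
# tables

_OBS_COLS = [f"h{i}" for i in range(1, 7)] + [f"w{i}" for i in range(1, 7)]


def read_manual_csv(path: str | Path) -> list[ManualMeasurement]:
    """Read a replicate table: columns vine_id, stage, h1..h6, w1..w6."""
    frame = pd.read_csv(path)
    missing = [c for c in ["vine_id", "stage", *_OBS_COLS] if c not in frame.columns]
    if missing:
        raise MissingDataError(f"manual table lacks columns: {missing}")
    return [
        ManualMeasurement(
            vine_id=str(rec.vine_id),
            stage=str(rec.stage),
            height_obs=tuple(getattr(rec, f"h{i}") for i in range(1, 7)),
            width_obs=tuple(getattr(rec, f"w{i}") for i in range(1, 7)),
        )
        for rec in frame.itertuples(index=False)
    ]


def summarise_manual(
    measurements: list[ManualMeasurement], row_spacing: float
) -> pd.DataFrame:
    """Per-vine means and derived LWA/TRV: columns vine_id, stage, H_M, W_M, LWA_M, TRV_M."""
    rows = []
    for m in measurements:
        h = mean_measurement(m.height_obs)
        w = mean_measurement(m.width_obs)
        rows.append(
            {
                "vine_id": m.vine_id,
                "stage": m.stage,
                "H_M": h,
                "W_M": w,
                "LWA_M": lwa(h, row_spacing),
                "TRV_M": trv(h, w, row_spacing),
            }
        )
    return pd.DataFrame(rows, columns=["vine_id", "stage", "H_M", "W_M", "LWA_M", "TRV_M"])


def write_metrics_csv(frame: pd.DataFrame, path: str | Path) -> None:
    """Write the per-vine metrics table, rounding to 2 d.p. at this boundary."""
    out = frame.copy()
    for col in out.select_dtypes(include="number").columns:
        out[col] = out[col].round(2)
    out.to_csv(path, index=False)
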