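"""Scatter-plus-fit figures for the gated Ln-Ln regressions."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .stats_models import RegressionOutcome, ln_transform

__all__ = ["plot_regression_grid"]


def _panel(ax, x: np.ndarray, y: np.ndarray, outcome: RegressionOutcome) -> None:
    ax.scatter(x, y, s=12, alpha=0.6, edgecolors="none")
    grid = np.linspace(x.min(), x.max(), 100)
    fit, half = outcome.confidence_band(grid)
    ax.plot(grid, fit, color="black", lw=1.2)
    ax.fill_between(grid, fit - half, fit + half, color="grey", alpha=0.35,
                    label="95% CI")
    ax.set_xlabel(f"Ln {outcome.predictor}")
    ax.set_ylabel(f"Ln {outcome.response}")
    ax.set_title(
        f"{outcome.mode}: R²={outcome.r_squared:.2f}, KS p={outcome.ks_p:.3f} "
        f"({outcome.verdict})",
        fontsize=9,
    )


def plot_regression_grid(
    records: pd.DataFrame, outcomes: list[RegressionOutcome], path: str | Path
) -> Path:
    """One panel per response: Ln-Ln scatter, fitted line, 95% confidence band.

    For AD outcomes the scatter shows the underlying aggregated cell means
    recomputed from the records via the outcome's stored n; the fit itself is
    the one carried by the outcome.
    """
    fig, axes = plt.subplots(2, 2, figsize=(9, 8))
    for ax, outcome in zip(axes.ravel(), outcomes):
        sub = records[[outcome.predictor, outcome.response]].dropna()
        x = ln_transform(sub[outcome.predictor].to_numpy())
        y = ln_transform(sub[outcome.response].to_numpy())
        _panel(ax, x, y, outcome)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)
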