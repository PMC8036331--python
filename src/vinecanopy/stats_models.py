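"""Correlation and regression analyses over the vine database.

Spearman rank correlation (ties averaged, pairwise-complete) screens the
remote-sensing variables against the manual canopy parameters. The candidate
relationships are then fitted as Ln-Ln ordinary least squares, gated by a
residual-normality test: residuals are compared to a Normal with mean and sd
estimated from themselves via a one-sample Kolmogorov-Smirnov statistic, and
the linear model is *rejected* when the p-value falls below alpha (default
0.05). With estimated parameters the test is the Lilliefors variant and its
nominal p-values are conservative at small n; the verdict rule is unchanged.

Two analysis modes:

* SPD (single-point data): every vine-date is one observation.
* AD (aggregated data): observations are first averaged within
  (plot, year, stage, vigour class) cells; fits run on the cell means.

Edge sensitivity re-computes a Spearman matrix with and without the
edge-flagged vines, side by side.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "CorrelationMatrix",
    "RegressionOutcome",
    "NonPositiveValueError",
    "FitError",
    "spearman_matrix",
    "ln_transform",
    "fit_gated_ols",
    "spd_analysis",
    "ad_analysis",
    "edge_sensitivity",
    "outcomes_to_frame",
]

RESPONSES = ("H_M", "W_M", "LWA_M", "TRV_M")
CLASSES = ("low", "medium", "high")


class NonPositiveValueError(ValueError):
    """Ln-transform fed non-positive values; offending positions listed."""

    def __init__(self, positions):
        self.positions = list(positions)
        super().__init__(
            f"{len(self.positions)} non-positive value(s) at positions {self.positions[:20]}"
        )


class FitError(ValueError):
    pass


@dataclass(frozen=True)
class CorrelationMatrix:
    """Symmetric Spearman rho matrix over a fixed variable order."""

    variables: tuple[str, ...]
    rho: np.ndarray  # NaN marks undefined entries (constant variables)

    def __post_init__(self) -> None:
        n = len(self.variables)
        if self.rho.shape != (n, n):
            raise ValueError("rho shape must match the variable count")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rho, index=self.variables, columns=self.variables)

    def get(self, a: str, b: str) -> float:
        return float(self.rho[self.variables.index(a), self.variables.index(b)])


@dataclass(frozen=True)
class RegressionOutcome:
    """One gated Ln-Ln OLS fit.

    ``x_mean``, ``x_ss`` (sum of squared x deviations) and ``mse_resid`` are
    retained so a 95% confidence band for the mean response can be drawn
    without refitting.
    """

    response: str
    predictor: str
    slope: float
    intercept: float
    r_squared: float
    ks_p: float
    verdict: str  # "accepted" | "rejected"
    n: int
    mode: str  # "SPD" | "AD"
    alpha: float = 0.05
    slope_se: float = np.nan
    intercept_se: float = np.nan
    x_mean: float = np.nan
    x_ss: float = np.nan
    mse_resid: float = np.nan

    def __post_init__(self) -> None:
        expected = "accepted" if self.ks_p > self.alpha else "rejected"
        if self.verdict != expected:
            raise ValueError("verdict inconsistent with ks_p and alpha")
        if not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise ValueError("r_squared must lie in [0, 1]")

    def confidence_band(self, x: np.ndarray, level: float = 0.95):
        """(fit, half-width) of the mean-response confidence band at x."""
        x = np.asarray(x, dtype=float)
        fit = self.intercept + self.slope * x
        if self.n <= 2 or not np.isfinite(self.mse_resid):
            return fit, np.zeros_like(fit)
        tcrit = stats.t.ppf(0.5 + level / 2.0, self.n - 2)
        half = tcrit * np.sqrt(
            self.mse_resid * (1.0 / self.n + (x - self.x_mean) ** 2 / self.x_ss)
        )
        return fit, half


def spearman_matrix(records: pd.DataFrame, variables: list[str]) -> CorrelationMatrix:
    """Pairwise-complete Spearman rho with averaged ranks for ties.

    A variable constant within a pair's complete cases yields an undefined
    (NaN) entry and a warning.
    """
    k = len(variables)
    rho = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            pair = records[[variables[i], variables[j]]].dropna()
            if len(pair) < 3:
                raise ValueError(
                    f"fewer than 3 complete cases for {variables[i]} vs {variables[j]}"
                )
            a = pair.iloc[:, 0].to_numpy(dtype=float)
            b = pair.iloc[:, 1].to_numpy(dtype=float)
            if np.ptp(a) == 0 or np.ptp(b) == 0:
                warnings.warn(
                    f"constant variable in pair ({variables[i]}, {variables[j]}); "
                    "rho undefined",
                    stacklevel=2,
                )
                r = np.nan
            else:
                r = stats.spearmanr(a, b).statistic
            rho[i, j] = rho[j, i] = r
    return CorrelationMatrix(variables=tuple(variables), rho=rho)


def ln_transform(values) -> np.ndarray:
    """Elementwise natural log; non-positive inputs raise, listing positions."""
    arr = np.asarray(values, dtype=float)
    bad = np.nonzero(~(arr > 0))[0]
    if bad.size:
        raise NonPositiveValueError(bad.tolist())
    return np.log(arr)


def fit_gated_ols(
    x: np.ndarray,
    y: np.ndarray,
    alpha: float = 0.05,
    response: str = "y",
    predictor: str = "x",
    mode: str = "SPD",
) -> RegressionOutcome:
    """OLS of y on x with a residual-normality acceptance gate.

    Inputs are expected already Ln-transformed. Residuals with (numerically)
    zero variance — a perfect fit — are treated as passing the gate (p := 1).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise FitError("x and y lengths differ")
    if len(x) < 3:
        raise FitError("need at least 3 observations")
    if np.ptp(x) == 0:
        raise FitError("zero variance in the predictor")

    model = sm.OLS(y, sm.add_constant(x)).fit()
    resid = model.resid
    sd = resid.std(ddof=1)
    if sd < 1e-12:
        ks_p = 1.0
        r_squared = 1.0
    else:
        ks_p = float(stats.kstest(resid, "norm", args=(resid.mean(), sd)).pvalue)
        r_squared = float(model.rsquared)
    verdict = "accepted" if ks_p > alpha else "rejected"
    return RegressionOutcome(
        response=response,
        predictor=predictor,
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        r_squared=min(max(r_squared, 0.0), 1.0),
        ks_p=ks_p,
        verdict=verdict,
        n=len(x),
        mode=mode,
        alpha=alpha,
        slope_se=float(model.bse[1]),
        intercept_se=float(model.bse[0]),
        x_mean=float(x.mean()),
        x_ss=float(((x - x.mean()) ** 2).sum()),
        mse_resid=float(model.mse_resid) if len(x) > 2 else np.nan,
    )


def _gated_fits(
    frame: pd.DataFrame,
    predictor: str,
    responses,
    mode: str,
    alpha: float,
) -> list[RegressionOutcome]:
    out = []
    for response in responses:
        sub = frame[[predictor, response]].dropna()
        x = ln_transform(sub[predictor].to_numpy())
        y = ln_transform(sub[response].to_numpy())
        out.append(
            fit_gated_ols(x, y, alpha=alpha, response=response,
                          predictor=predictor, mode=mode)
        )
    return out


def spd_analysis(
    records: pd.DataFrame,
    predictor: str,
    responses=RESPONSES,
    alpha: float = 0.05,
) -> list[RegressionOutcome]:
    """Single-point-data fits: one Ln-Ln gated OLS per response, every
    vine-date one observation, plots/years/stages pooled."""
    return _gated_fits(records, predictor, responses, "SPD", alpha)


def ad_analysis(
    records: pd.DataFrame,
    predictor: str,
    responses=RESPONSES,
    class_col: str = "C_vigour_D",
    group_cols=("Plot", "Year", "BBCH"),
    alpha: float = 0.05,
) -> list[RegressionOutcome]:
    """Aggregated-data fits: observations averaged within
    (plot, year, stage, vigour class) cells before fitting.

    A vigour class absent from some (plot, year, stage) cell is simply
    dropped, with a warning naming it.
    """
    cols = [predictor, *responses]
    keys = [*group_cols, class_col]
    cells = records.dropna(subset=cols).groupby(keys, observed=True)[cols].mean().reset_index()
    expected = records[list(group_cols)].drop_duplicates()
    n_expected = len(expected) * len(CLASSES)
    if len(cells) < n_expected:
        got = set(map(tuple, cells[keys].itertuples(index=False)))
        for grp in expected.itertuples(index=False):
            for cls in CLASSES:
                if (*grp, cls) not in got:
                    warnings.warn(f"empty vigour-class cell dropped: {(*grp, cls)}",
                                  stacklevel=2)
    return _gated_fits(cells, predictor, responses, "AD", alpha)


def edge_sensitivity(
    records: pd.DataFrame, variables: list[str]
) -> tuple[CorrelationMatrix, CorrelationMatrix]:
    """Spearman matrices (considering edges, rejecting edges) side by side."""
    if "Edge_pnt" not in records.columns:
        raise ValueError("records lack the Edge_pnt flag")
    with_edges = spearman_matrix(records, variables)
    interior = records.loc[~records["Edge_pnt"].astype(bool)]
    if interior.empty:
        raise ValueError("all records are edge points; rejected-set matrix undefined")
    without_edges = spearman_matrix(interior, variables)
    return with_edges, without_edges


def outcomes_to_frame(outcomes: list[RegressionOutcome], platform: str = "") -> pd.DataFrame:
    """One row per fit: mode, platform, response, slope, intercept, R2, ks_p, verdict, n."""
    return pd.DataFrame(
        [
            {
                "mode": o.mode,
                "platform": platform,
                "response": o.response,
                "predictor": o.predictor,
                "slope": o.slope,
                "intercept": o.intercept,
                "r_squared": o.r_squared,
                "ks_p": o.ks_p,
                "verdict": o.verdict,
                "n": o.n,
            }
            for o in outcomes
        ]
    )
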