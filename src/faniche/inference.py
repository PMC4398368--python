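"""The association layer: simple linear regressions with field conventions.

Per-population mean FA and morphological disparity are each regressed on
environmental suitability at the local and regional scales, and — as
nuisance checks — on per-population sample size and mean centroid size,
giving eight ordinary least-squares regressions in all.  Results are
reported as F(1, n-2), p, R^2, slope, the convention of the source
literature; a Holm-adjusted p column is emitted alongside for
transparency (no gate is applied — the tests are treated as independent).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = ["RegressionResult", "simple_linear_regression", "run_association_suite"]

ALPHA = 0.05


@dataclass
class RegressionResult:
    response_name: str
    predictor_name: str
    n: int
    f_stat: float
    df1: int
    df2: int
    r_squared: float
    slope: float
    intercept: float
    p_value: float
    significant: bool

    def format_report(self) -> str:
        return (
            f"{self.response_name} ~ {self.predictor_name}: "
            f"F_1,{self.df2} = {self.f_stat:.2f}; P = {self.p_value:.3g}; "
            f"R2 = {self.r_squared:.3f}; b = {self.slope:.4f}"
        )


def simple_linear_regression(
    y: np.ndarray, x: np.ndarray, response_name: str = "y", predictor_name: str = "x"
) -> RegressionResult:
    """Ordinary least squares of y on x with the two-sided F(1, n-2) test."""
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if y.shape != x.shape or y.ndim != 1:
        raise ValueError("y and x must be 1D vectors of equal length")
    n = y.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0:
        raise ValueError("constant predictor: regression undefined")
    if np.ptp(y) == 0:
        raise ValueError("zero response variance")
    xc = x - x.mean()
    yc = y - y.mean()
    sxx = float(xc @ xc)
    sxy = float(xc @ yc)
    syy = float(yc @ yc)
    if syy == 0:
        raise ValueError("zero response variance")
    slope = sxy / sxx
    intercept = float(y.mean() - slope * x.mean())
    r2 = sxy**2 / (sxx * syy)
    df2 = n - 2
    f = df2 * r2 / (1.0 - r2) if r2 < 1.0 else np.inf
    p = float(stats.f.sf(f, 1, df2))
    # Shapiro-Wilk on residuals, logged as a diagnostic only
    resid = yc - slope * xc
    if n >= 3:
        sw = stats.shapiro(resid)
        logger.debug(
            "%s ~ %s residual Shapiro-Wilk W=%.3f p=%.3f",
            response_name,
            predictor_name,
            sw.statistic,
            sw.pvalue,
        )
    return RegressionResult(
        response_name=response_name,
        predictor_name=predictor_name,
        n=n,
        f_stat=float(f),
        df1=1,
        df2=df2,
        r_squared=float(r2),
        slope=float(slope),
        intercept=intercept,
        p_value=p,
        significant=p < ALPHA,
    )


#: the eight (response, predictor) pairs of the association battery
SUITE_PAIRS = [
    ("mean_fa", "suitability_local"),
    ("mean_fa", "suitability_regional"),
    ("disparity", "suitability_local"),
    ("disparity", "suitability_regional"),
    ("mean_fa", "n"),
    ("disparity", "n"),
    ("mean_fa", "mean_cs"),
    ("disparity", "mean_cs"),
]


def run_association_suite(summaries: pd.DataFrame) -> pd.DataFrame:
    """Run the eight-regression battery on a population-summary table.

    ``summaries`` needs columns mean_fa, disparity, n, mean_cs,
    suitability_local, suitability_regional (one row per population).
    Regressions whose predictor or response is missing/degenerate are
    skipped with a warning; the rest of the suite continues.
    """
    rows = []
    for response, predictor in SUITE_PAIRS:
        if response not in summaries.columns or predictor not in summaries.columns:
            logger.warning("skipping %s ~ %s: column missing", response, predictor)
            continue
        sub = summaries[[response, predictor]].dropna()
        if len(sub) < 3:
            logger.warning("skipping %s ~ %s: fewer than 3 complete populations", response, predictor)
            continue
        try:
            res = simple_linear_regression(
                sub[response].to_numpy(),
                sub[predictor].to_numpy(),
                response_name=response,
                predictor_name=predictor,
            )
        except ValueError as exc:
            logger.warning("skipping %s ~ %s: %s", response, predictor, exc)
            continue
        rows.append(
            {
                "response": response,
                "predictor": predictor,
                "n": res.n,
                "f": res.f_stat,
                "df1": res.df1,
                "df2": res.df2,
                "p": res.p_value,
                "r2": res.r_squared,
                "slope": res.slope,
                "intercept": res.intercept,
            }
        )
    table = pd.DataFrame(rows)
    if not table.empty:
        table["p_holm"] = _holm(table["p"].to_numpy())
    return table


def _holm(p: np.ndarray) -> np.ndarray:
    """Holm step-down adjusted p-values."""
    m = p.size
    order = np.argsort(p)
    adjusted = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adjusted[idx] = min(1.0, running)
    return adjusted
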