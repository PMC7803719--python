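"""Group aggregation and the depth-trend (horizontality) test.

If temporal additivity holds equally well at all cortical depths, the
cross-validated prediction correlations should be constant over depth: an
ordinary-least-squares line fitted to r as a function of normalized depth
should not deviate significantly from horizontal. The verdict uses the
slope's two-sided t-test only; the intercept test describes the overall
fit quality.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = ["TrendFit", "aggregate_group", "fit_depth_trend", "test_horizontal"]

CONSISTENT = "consistent-with-additivity"
VIOLATED = "violated"


@dataclass(frozen=True)
class TrendFit:
    """OLS fit of correlation over normalized depth for one ROI."""

    roi: int | str
    intercept: float
    slope: float
    t_intercept: float
    t_slope: float
    p_intercept: float
    p_slope: float
    df: int
    n_points: int

    def report_line(self) -> str:
        return (
            f"{self.roi}: intercept = {self.intercept:.3f} "
            f"(t({self.df}) = {self.t_intercept:.2f}, p = {self.p_intercept:.3g}); "
            f"slope = {self.slope:.3f} "
            f"(t({self.df}) = {self.t_slope:.2f}, p = {self.p_slope:.3g})"
        )


def aggregate_group(
    results: dict[int | str, pd.DataFrame], ci_level: float = 0.95
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stack per-subject additivity tables and summarize across subjects.

    Returns (long table with a ``subject`` column, group summary with mean
    and t-based CI per (roi, bin, condition)). Subjects must share the
    same (roi, bin, condition) structure.
    """
    if not results:
        raise ValueError("no subjects given")
    frames = []
    key = None
    for subject, table in results.items():
        idx = table[["roi", "bin", "condition"]].sort_values(
            ["roi", "bin", "condition"]
        ).reset_index(drop=True)
        if key is None:
            key = idx
        elif not key.equals(idx):
            raise ValueError(f"subject {subject} has inconsistent bins/conditions")
        frames.append(table.assign(subject=subject))
    long = pd.concat(frames, ignore_index=True)

    def _summ(g: pd.DataFrame) -> pd.Series:
        n = len(g)
        mean = g["median_r"].mean()
        if n >= 2:
            half = stats.t.ppf(0.5 + ci_level / 2, n - 1) * g["median_r"].std(ddof=1) / np.sqrt(n)
        else:
            half = np.nan
        return pd.Series(
            {"mean_r": mean, "ci_lo": mean - half, "ci_hi": mean + half,
             "mean_depth": g["mean_depth"].mean(), "n_subjects": n}
        )

    summary = (
        long.groupby(["roi", "bin", "condition"])
        .apply(_summ, include_groups=False)
        .reset_index()
    )
    return long, summary


def fit_depth_trend(points: pd.DataFrame, roi: int | str) -> TrendFit:
    """OLS of correlation on mean normalized depth, with coefficient t-tests.

    ``points`` needs columns ``mean_depth`` and a correlation column
    (``median_r`` or ``r``). Each row is one point (typically one subject x
    condition x depth bin). Two-sided t-tests of slope = 0 and intercept
    = 0 use df = n - 2. Numerically perfect fits (zero residual) are
    special-cased: a coefficient indistinguishable from zero gets t = 0,
    p = 1, otherwise t = inf, p = 0.
    """
    rcol = "median_r" if "median_r" in points.columns else "r"
    depth = np.asarray(points["mean_depth"], dtype=float)
    y = np.asarray(points[rcol], dtype=float)
    if len(y) < 3:
        raise ValueError("need at least 3 points for the depth trend")
    if np.ptp(depth) <= 0:
        raise ValueError("depth values are all equal; trend is undefined")
    X = sm.add_constant(depth)
    fit = sm.OLS(y, X).fit()
    df = int(fit.df_resid)
    scale = max(1.0, float(np.mean(np.abs(y))))
    if np.sqrt(fit.ssr / max(df, 1)) < 1e-10 * scale:  # exact fit: 0/0 t-stats
        coefs = fit.params
        ts, ps = [], []
        for c in coefs:
            if abs(c) < 1e-8 * scale:
                ts.append(0.0)
                ps.append(1.0)
            else:
                ts.append(np.inf if c > 0 else -np.inf)
                ps.append(0.0)
        return TrendFit(roi, coefs[0], coefs[1], ts[0], ts[1], ps[0], ps[1], df, len(y))
    return TrendFit(
        roi,
        float(fit.params[0]),
        float(fit.params[1]),
        float(fit.tvalues[0]),
        float(fit.tvalues[1]),
        float(fit.pvalues[0]),
        float(fit.pvalues[1]),
        df,
        len(y),
    )


def test_horizontal(fit: TrendFit, alpha: float = 0.05) -> str:
    """Horizontality verdict: consistent when the slope is not significant.

    The verdict never uses the intercept test (a nonzero overall
    correlation is expected; only a depth dependence would indicate a
    violation of additivity across depth).
    """
    return CONSISTENT if fit.p_slope >= alpha else VIOLATED
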