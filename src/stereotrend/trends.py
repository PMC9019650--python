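"""Linear decade trends in narrative scores and the slope-difference test.

Each framing's CANS series is regressed on a decade index (1810 -> 0,
1820 -> 1, ...), so the intercept is interpretable as the 1810 score and
the slope is the change per decade.  Percent decline over D decades is
100 * (-slope) * (D - 1) / intercept — D decades span D - 1 decade
intervals — with positive values meaning decline.

Whether two framings' slopes differ is tested with a pooled homoscedastic
regression on group, decade index, and their interaction; the interaction
F equals the squared t of the interaction coefficient, on (1, N - 4)
degrees of freedom for N total points.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import ComputationError, DataError
from .valence import NarrativeScoreSeries

DECADE_ORIGIN = 1810


@dataclass(frozen=True)
class TrendFit:
    framing: str
    intercept: float
    slope: float
    se_intercept: float
    se_slope: float
    p_intercept: float
    p_slope: float
    ci95_intercept: tuple[float, float]
    ci95_slope: tuple[float, float]
    n_decades: int
    percent_decline: float


@dataclass(frozen=True)
class SlopeComparison:
    F: float
    df1: int
    df2: int
    p: float
    slope_diff: float


def decade_index(decades: np.ndarray, origin: int = DECADE_ORIGIN) -> np.ndarray:
    return (np.asarray(decades, dtype=float) - origin) / 10.0


def percent_decline(intercept: float, slope: float, n_decades: int) -> float:
    """Percent change over ``n_decades`` decades relative to the intercept.

    Positive = decline.  D decades cover D - 1 decade intervals, so the
    total change is slope * (D - 1).
    """
    if intercept <= 0:
        raise DataError(f"percent_decline needs a positive intercept, got {intercept}")
    if n_decades < 2:
        raise DataError("percent_decline needs n_decades >= 2")
    return 100.0 * (-slope) * (n_decades - 1) / intercept


def fit_decade_trend(
    series: pd.Series | NarrativeScoreSeries,
    framing: str = "",
    origin: int = DECADE_ORIGIN,
) -> TrendFit:
    """OLS fit of a CANS series on the decade index.

    ``series`` is a pandas Series indexed by decade label, or a
    :class:`NarrativeScoreSeries` together with a framing name.
    """
    if isinstance(series, NarrativeScoreSeries):
        series = series.series(framing)
    y = series.to_numpy(dtype=float)
    t = decade_index(series.index.to_numpy(), origin)
    if len(y) < 3:
        raise DataError(f"fit_decade_trend needs >= 3 decades, got {len(y)}")
    if np.ptp(t) == 0:
        raise ComputationError("degenerate trend fit: zero variance in decade index")
    x = sm.add_constant(t)
    res = sm.OLS(y, x).fit()
    ci = res.conf_int(alpha=0.05)
    intercept, slope = res.params
    return TrendFit(
        framing=framing or (series.name or ""),
        intercept=float(intercept),
        slope=float(slope),
        se_intercept=float(res.bse[0]),
        se_slope=float(res.bse[1]),
        p_intercept=float(res.pvalues[0]),
        p_slope=float(res.pvalues[1]),
        ci95_intercept=(float(ci[0][0]), float(ci[0][1])),
        ci95_slope=(float(ci[1][0]), float(ci[1][1])),
        n_decades=len(y),
        percent_decline=percent_decline(float(intercept), float(slope), len(y)),
    )


def compare_slopes(
    series_a: pd.Series,
    series_b: pd.Series,
    origin: int = DECADE_ORIGIN,
) -> SlopeComparison:
    """Interaction F-test for a slope difference between two decade series.

    Fits y ~ 1 + group + t + group:t over the pooled points; the test of
    the interaction coefficient gives F = t^2 on (1, N - 4) df under the
    shared-error-variance assumption.  Symmetric in the group labels.
    """
    for s in (series_a, series_b):
        if len(s) < 3:
            raise DataError("compare_slopes needs >= 3 points per series")
    t = np.concatenate([decade_index(series_a.index.to_numpy(), origin),
                        decade_index(series_b.index.to_numpy(), origin)])
    g = np.concatenate([np.zeros(len(series_a)), np.ones(len(series_b))])
    y = np.concatenate([series_a.to_numpy(dtype=float), series_b.to_numpy(dtype=float)])
    x = np.column_stack([np.ones_like(t), g, t, g * t])
    res = sm.OLS(y, x).fit()
    tval = res.tvalues[3]
    df2 = int(res.df_resid)
    return SlopeComparison(
        F=float(tval**2),
        df1=1,
        df2=df2,
        p=float(res.pvalues[3]),
        slope_diff=float(res.params[3]),
    )


def trend_report(fits: list[TrendFit]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "framing": f.framing,
                "intercept": f.intercept,
                "ci_low_intercept": f.ci95_intercept[0],
                "ci_high_intercept": f.ci95_intercept[1],
                "slope": f.slope,
                "se_slope": f.se_slope,
                "p_slope": f.p_slope,
                "n_decades": f.n_decades,
                "percent_decline": f.percent_decline,
            }
            for f in fits
        ]
    )


def plot_trends(
    scores: NarrativeScoreSeries,
    fits: dict[str, TrendFit],
    path,
    origin: int = DECADE_ORIGIN,
) -> None:
    """Scatter + fitted lines with pointwise 95% confidence bands."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from scipy import stats as sps

    fig, ax = plt.subplots(figsize=(8, 5))
    for framing in scores.framings():
        s = scores.series(framing)
        fit = fits[framing]
        t = decade_index(s.index.to_numpy(), origin)
        yhat = fit.intercept + fit.slope * t
        resid = s.to_numpy() - yhat
        n = len(s)
        mse = (resid**2).sum() / (n - 2)
        tbar = t.mean()
        sxx = ((t - tbar) ** 2).sum()
        se_line = np.sqrt(mse * (1 / n + (t - tbar) ** 2 / sxx))
        crit = sps.t.ppf(0.975, n - 2)
        (line,) = ax.plot(s.index, yhat, label=f"{framing} (slope {fit.slope:+.4f}/decade)")
        ax.scatter(s.index, s.to_numpy(), s=18, color=line.get_color(), alpha=0.6)
        ax.fill_between(s.index, yhat - crit * se_line, yhat + crit * se_line,
                        color=line.get_color(), alpha=0.15)
    ax.set_xlabel("decade")
    ax.set_ylabel("cumulative narrative score (1-5)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
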