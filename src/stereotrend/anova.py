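"""Two-way mixed-design (split-plot) ANOVA with partial eta squared.

One between-units factor (e.g. framing) and one within-units factor
(e.g. century) measured on every unit.  The between main effect is tested
against units-within-groups variation; the within main effect and the
interaction are tested against the within x units-within-groups error.

With exactly two within levels the decomposition reduces exactly to two
one-dimensional analyses — unit sums carry the between effect, unit
differences carry the within and interaction effects — which handles
unbalanced group sizes with Type III-equivalent (unweighted-means) tests
and reproduces the classical formulas in the balanced case.  For more than
two within levels a regression-based Type III decomposition is used.

Degrees of freedom for a 2 x 2 design with N complete units: every effect
is tested on (1, N - 2).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ComputationError, DataError

logger = logging.getLogger(__name__)

EFFECTS = ("between", "within", "interaction")


@dataclass(frozen=True)
class AnovaResult:
    """Per-effect F tests; ``table`` is indexed by effect name with columns
    [ss, ss_error, df1, df2, F, p, partial_eta_sq]."""

    table: pd.DataFrame

    def effect(self, name: str) -> pd.Series:
        return self.table.loc[name]


def partial_eta_squared(ss_effect: float, ss_error: float) -> float:
    """SS_effect / (SS_effect + SS_error)."""
    if ss_effect < 0 or ss_error < 0:
        raise DataError("sums of squares must be nonnegative")
    if ss_effect == 0 and ss_error == 0:
        raise ComputationError("partial eta squared undefined: both sums of squares zero")
    return ss_effect / (ss_effect + ss_error)


def _validate(table: pd.DataFrame) -> pd.DataFrame:
    required = {"unit", "between", "within", "response"}
    missing = required - set(table.columns)
    if missing:
        raise DataError(f"mixed-design table missing columns: {sorted(missing)}")
    if table.duplicated(["unit", "within"]).any():
        dup = table[table.duplicated(["unit", "within"])].iloc[0]
        raise DataError(f"unit {dup['unit']!r} has duplicate rows for within level {dup['within']!r}")
    groups_per_unit = table.groupby("unit")["between"].nunique()
    if (groups_per_unit > 1).any():
        bad = groups_per_unit[groups_per_unit > 1].index[0]
        raise DataError(f"unit {bad!r} appears under more than one between level")
    within_levels = sorted(table["within"].unique())
    if len(within_levels) < 2 or table["between"].nunique() < 2:
        raise DataError("need >= 2 levels of each factor")
    # complete cases only
    counts = table.groupby("unit")["within"].nunique()
    complete = counts[counts == len(within_levels)].index
    dropped = len(counts) - len(complete)
    if dropped:
        logger.warning("dropping %d incomplete unit(s)", dropped)
    table = table[table["unit"].isin(complete)]
    group_sizes = table.groupby("between")["unit"].nunique()
    if (group_sizes < 2).any():
        raise DataError(f"every between group needs >= 2 complete units, got {dict(group_sizes)}")
    return table


def two_way_mixed_anova(table: pd.DataFrame) -> AnovaResult:
    """Mixed ANOVA on a long-format table with columns
    (unit, between, within, response)."""
    table = _validate(table)
    wide = table.pivot(index="unit", columns="within", values="response").sort_index(axis=1)
    group = table.drop_duplicates("unit").set_index("unit")["between"].reindex(wide.index)
    k = wide.shape[1]
    if k == 2:
        rows = _anova_two_within(wide.to_numpy(dtype=float), group.to_numpy())
    else:
        rows = _anova_general(wide, group)
    out = pd.DataFrame(rows, index=EFFECTS,
                       columns=["ss", "ss_error", "df1", "df2", "F", "p", "partial_eta_sq"])
    return AnovaResult(out)


def _one_way_ss(values: np.ndarray, groups: np.ndarray) -> tuple[float, float, int, int]:
    """Between-group and residual SS for a one-way layout."""
    grand = values.mean()
    ss_between = 0.0
    ss_within = 0.0
    levels = np.unique(groups)
    for g in levels:
        v = values[groups == g]
        ss_between += len(v) * (v.mean() - grand) ** 2
        ss_within += ((v - v.mean()) ** 2).sum()
    return ss_between, ss_within, len(levels) - 1, len(values) - len(levels)


def _anova_two_within(y: np.ndarray, groups: np.ndarray) -> list[list[float]]:
    """Exact sum/difference decomposition for k = 2 within levels.

    Unit sums s = y1 + y2 carry the between effect; unit differences
    d = y2 - y1 carry the within main effect (Type III: unweighted mean of
    group means tested against zero) and the interaction (group effect on
    d).  SS are reported on the scale of the raw observations (the factor
    1/k cancels from every F and partial eta squared).
    """
    s = y.sum(axis=1)
    d = y[:, 1] - y[:, 0]
    n = len(y)
    levels = np.unique(groups)
    a = len(levels)

    # between-units stratum (divide by k=2 to be on the raw-response scale)
    ss_a, ss_sub, df_a, df_sub = _one_way_ss(s, groups)
    ss_a /= 2.0
    ss_sub /= 2.0

    # within-units stratum
    ss_ab, ss_resid, df_ab, df_resid = _one_way_ss(d, groups)
    ss_ab /= 2.0
    ss_resid /= 2.0
    # within main effect, Type III: unweighted average of group mean differences
    group_means = np.array([d[groups == g].mean() for g in levels])
    group_ns = np.array([(groups == g).sum() for g in levels])
    theta = group_means.mean()
    var_coef = (1.0 / (a**2 * group_ns)).sum()
    ss_b = theta**2 / var_coef / 2.0

    def row(ss_eff, ss_err, df1, df2):
        if ss_err == 0 and ss_eff == 0:
            f = 0.0
            p = 1.0
            pes = 0.0
        elif ss_err == 0:
            f = np.inf
            p = 0.0
            pes = 1.0
        else:
            f = (ss_eff / df1) / (ss_err / df2)
            p = float(sps.f.sf(f, df1, df2))
            pes = partial_eta_squared(ss_eff, ss_err)
        return [ss_eff, ss_err, df1, df2, f, p, pes]

    return [
        row(ss_a, ss_sub, df_a, df_sub),
        row(ss_b, ss_resid, 1, df_resid),
        row(ss_ab, ss_resid, df_ab, df_resid),
    ]


def _anova_general(wide: pd.DataFrame, group: pd.Series) -> list[list[float]]:
    """Regression-based Type III decomposition for k > 2 within levels."""
    from statsmodels.formula.api import ols
    from statsmodels.stats.anova import anova_lm

    n = wide.shape[0]
    k = wide.shape[1]
    a = group.nunique()

    # between stratum: one-way ANOVA on unit means, SS scaled by k
    means = wide.mean(axis=1).to_numpy()
    ss_a, ss_sub, df_a, df_sub = _one_way_ss(means, group.to_numpy())
    ss_a *= k
    ss_sub *= k

    # within stratum: residualize on units, Type III SS for within and interaction
    resid = wide.sub(wide.mean(axis=1), axis=0).stack().rename("resp").reset_index()
    resid.columns = ["unit", "within", "resp"]
    resid["between"] = group.reindex(resid["unit"]).to_numpy()
    model = ols("resp ~ C(within, Sum) + C(between, Sum):C(within, Sum)", data=resid).fit()
    aov = anova_lm(model, typ=3)
    ss_b = float(aov.loc["C(within, Sum)", "sum_sq"])
    ss_ab = float(aov.loc["C(between, Sum):C(within, Sum)", "sum_sq"])
    df_b = k - 1
    df_ab = (a - 1) * (k - 1)
    df_resid = (n - a) * (k - 1)
    # model residual SS on the unit-residualized data is the B x S(A) error;
    # the error df is computed from the split-plot structure, not model.df_resid
    ss_resid = float(model.ssr)

    def row(ss_eff, ss_err, df1, df2):
        if ss_err == 0:
            raise ComputationError("zero error sum of squares")
        f = (ss_eff / df1) / (ss_err / df2)
        return [ss_eff, ss_err, df1, df2, f, float(sps.f.sf(f, df1, df2)),
                partial_eta_squared(ss_eff, ss_err)]

    return [
        row(ss_a, ss_sub, df_a, df_sub),
        row(ss_b, ss_resid, df_b, df_resid),
        row(ss_ab, ss_resid, df_ab, df_resid),
    ]
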