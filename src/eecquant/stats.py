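"""Group statistics for ablation comparisons.

Per-fish total cell counts are compared between control and ablated
groups with an unpaired Student's t test (pooled variance; Welch
available).  Regional counts (group x gut quarter) are analyzed with a
two-way ANOVA — Type-II sums of squares by default, so unbalanced fish
numbers are handled — followed by Tukey's multiple-comparisons test
using the ANOVA's error mean square.  p values map onto the usual star
annotation: ns (p > 0.05), * (p < 0.05), ** (p < 0.01), *** (p < 0.001),
**** (p < 0.0001), with boundary values assigned to the less-significant
label.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf


@dataclass(frozen=True)
class StatResult:
    """One test result: statistic, degrees of freedom, p value, stars."""

    test: str
    comparison: str
    statistic: float
    df: tuple[float, ...]
    p_value: float
    stars: str


@dataclass
class AnovaResult:
    """Two-way ANOVA decomposition plus the error term for Tukey's test."""

    effects: dict[str, StatResult]
    table: pd.DataFrame  # sum_sq, df, F, p per term and Residual
    ms_error: float
    df_error: float

    def __getitem__(self, effect: str) -> StatResult:
        return self.effects[effect]


def star_annotation(p: float) -> str:
    """Significance stars for a p value (0.05/0.01/0.001/0.0001 cuts)."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p value {p} outside [0, 1]")
    if p >= 0.05:
        return "ns"
    if p >= 0.01:
        return "*"
    if p >= 0.001:
        return "**"
    if p >= 0.0001:
        return "***"
    return "****"


def unpaired_t_test(
    totals_control,
    totals_ablated,
    equal_var: bool = True,
    comparison: str = "control vs ablated",
) -> StatResult:
    """Two-sided unpaired t test on per-fish totals.

    Student's pooled-variance flavor by default (n1 + n2 - 2 df); set
    ``equal_var=False`` for Welch.  With zero pooled variance the test is
    degenerate: equal means report t = 0, p = 1; unequal means are an
    error.
    """
    x = np.asarray(totals_control, dtype=float)
    y = np.asarray(totals_ablated, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs n >= 2")
    n1, n2 = len(x), len(y)
    pooled_var = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / (n1 + n2 - 2)
    if equal_var and pooled_var == 0:
        if x.mean() == y.mean():
            return StatResult("unpaired t", comparison, 0.0, (n1 + n2 - 2,), 1.0, "ns")
        raise ValueError("zero pooled variance with unequal means")
    res = sps.ttest_ind(x, y, equal_var=equal_var)
    df = n1 + n2 - 2 if equal_var else float(res.df)
    p = float(res.pvalue)
    return StatResult(
        "unpaired t" if equal_var else "Welch t",
        comparison,
        float(res.statistic),
        (float(df),),
        p,
        star_annotation(p),
    )


def two_way_anova(
    table: pd.DataFrame,
    response: str = "count",
    factor_a: str = "group",
    factor_b: str = "quarter",
    ss_type: int = 2,
) -> AnovaResult:
    """Two-way ANOVA with interaction on a long-format count table.

    Fits ``response ~ A * B`` by least squares and returns sum of
    squares, df, F and p for both main effects and the interaction
    (Type-II SS by default; Type-III via ``ss_type=3``).  For balanced
    data the decomposition is exact:
    SS_total = SS_A + SS_B + SS_AB + SS_error.

    A factor with one level or an empty A x B cell is an error.  When the
    response has no variance at all, every F is reported as 0 with p = 1
    by convention.
    """
    df = table[[response, factor_a, factor_b]].copy()
    df[factor_a] = df[factor_a].astype(str)
    df[factor_b] = df[factor_b].astype(str)
    for fac in (factor_a, factor_b):
        if df[fac].nunique() < 2:
            raise ValueError(f"factor {fac!r} has fewer than 2 levels")
    cells = pd.crosstab(df[factor_a], df[factor_b])
    empty = list(zip(*np.where(cells.to_numpy() == 0)))
    if empty:
        i, j = empty[0]
        raise ValueError(
            f"empty design cell: {factor_a}={cells.index[i]!r}, "
            f"{factor_b}={cells.columns[j]!r}"
        )

    if ss_type == 3:
        formula = (
            f"{response} ~ C({factor_a}, Sum) * C({factor_b}, Sum)"
        )
    else:
        formula = f"{response} ~ C({factor_a}) * C({factor_b})"
    model = smf.ols(formula, data=df).fit()
    no_variance = df[response].nunique() == 1
    aov = sm.stats.anova_lm(model, typ=ss_type)

    term_names = {
        aov.index[0]: factor_a,
        aov.index[1]: factor_b,
        aov.index[2]: f"{factor_a}:{factor_b}",
    }
    ms_error = float(aov.loc["Residual", "sum_sq"] / aov.loc["Residual", "df"])
    df_error = float(aov.loc["Residual", "df"])
    effects: dict[str, StatResult] = {}
    for term, name in term_names.items():
        F = float(aov.loc[term, "F"])
        p = float(aov.loc[term, "PR(>F)"])
        if no_variance or not math.isfinite(F):
            F, p = 0.0, 1.0
        effects[name] = StatResult(
            "two-way ANOVA",
            name,
            F,
            (float(aov.loc[term, "df"]), df_error),
            p,
            star_annotation(p),
        )
    out = aov.rename(index=term_names)
    return AnovaResult(effects=effects, table=out, ms_error=ms_error, df_error=df_error)


def tukey_hsd(
    table: pd.DataFrame,
    effect: str,
    anova: AnovaResult,
    response: str = "count",
) -> list[StatResult]:
    """Tukey's multiple-comparisons test on one factor's marginal means.

    All pairwise differences of the factor's level means, studentized
    with the two-way ANOVA's MS_error and its df (Tukey-Kramer for
    unequal level sizes): q = |m_i - m_j| / sqrt(MSE/2 * (1/n_i + 1/n_j)),
    p from the studentized range distribution with k levels.
    """
    df = table.copy()
    df[effect] = df[effect].astype(str)
    levels = sorted(df[effect].unique())
    if len(levels) < 2:
        raise ValueError(f"factor {effect!r} has fewer than 2 levels")
    means = df.groupby(effect)[response].mean()
    ns = df.groupby(effect)[response].count()
    k = len(levels)
    out = []
    for a, b in itertools.combinations(levels, 2):
        diff = float(means[a] - means[b])
        se = math.sqrt(anova.ms_error / 2.0 * (1.0 / ns[a] + 1.0 / ns[b]))
        if se == 0:
            p = 1.0 if diff == 0 else 0.0
            q = math.inf if diff else 0.0
        else:
            q = abs(diff) / se
            p = float(sps.studentized_range.sf(q, k, anova.df_error))
        p = min(1.0, max(0.0, p))
        out.append(
            StatResult(
                "Tukey HSD",
                f"{a} vs {b}",
                q,
                (float(k), anova.df_error),
                p,
                star_annotation(p),
            )
        )
    return out
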