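"""Group-level statistics: two-way ANCOVA, correlations, two-group tests.

The ANCOVA models ``value ~ group + covariate + group:covariate`` and reports
F-tests for the main effect of group, the main effect of the covariate, and
the interaction, with Type II sums of squares by default (robust to group
imbalance; Type I available for strict emulation of sequential fitting).
Per-group R^2 is the squared Pearson correlation of value and covariate
within each group.  Uncorrected p values are reported alongside the
Bonferroni family-wise threshold rather than silently re-thresholded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm

__all__ = ["AncovaResult", "TwoGroupResult", "ancova", "correlate", "two_group_compare"]


@dataclass
class AncovaResult:
    """Two-way ANCOVA summary for one (dependent, covariate) pair."""

    dependent: str
    covariate: str
    p_group: float
    p_covariate: float
    p_interaction: float
    r2_by_group: dict
    group_means: dict
    group_sems: dict
    flagged: bool = False


def ancova(
    values,
    groups,
    covariate,
    dependent_name: str = "value",
    covariate_name: str = "covariate",
    ss_type: int = 2,
) -> AncovaResult:
    """Two-way ANCOVA of ``values`` on group membership and a covariate.

    Requires >= 3 observations per group and a finite covariate.  A constant
    covariate within any group makes the design singular; the result is then
    flagged and the affected p values are NaN.
    """
    values = np.asarray(values, float)
    covariate = np.asarray(covariate, float)
    groups = np.asarray(groups)
    if not np.all(np.isfinite(covariate)):
        raise ValueError("covariate contains non-finite values")
    levels = pd.unique(groups)
    for g in levels:
        if (groups == g).sum() < 3:
            raise ValueError(f"need >= 3 observations per group; group {g!r} has fewer")

    singular = any(covariate[groups == g].std() == 0 for g in levels)
    df = pd.DataFrame({"value": values, "group": groups, "cov": covariate})
    p_group = p_cov = p_inter = np.nan
    if not singular:
        model = ols("value ~ C(group) * cov", data=df).fit()
        table = anova_lm(model, typ=ss_type)
        p_group = float(table.loc["C(group)", "PR(>F)"])
        p_cov = float(table.loc["cov", "PR(>F)"])
        p_inter = float(table.loc["C(group):cov", "PR(>F)"])
        # an exactly zero interaction SS has p = 1 by convention (F = 0)
        if np.isnan(p_inter) and np.isclose(table.loc["C(group):cov", "sum_sq"], 0):
            p_inter = 1.0

    r2, means, sems = {}, {}, {}
    for g in levels:
        m = groups == g
        v, c = values[m], covariate[m]
        r2[g] = float(np.corrcoef(v, c)[0, 1] ** 2) if v.std() > 0 and c.std() > 0 else np.nan
        means[g] = float(v.mean())
        sems[g] = float(sps.sem(v, ddof=1))
    return AncovaResult(
        dependent=dependent_name,
        covariate=covariate_name,
        p_group=p_group,
        p_covariate=p_cov,
        p_interaction=p_inter,
        r2_by_group=r2,
        group_means=means,
        group_sems=sems,
        flagged=singular,
    )


def correlate(x, y) -> float:
    """Pearson product-moment correlation; requires >= 3 pairs and nonzero
    variance in both series."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired observations")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance: correlation undefined")
    return float(np.corrcoef(x, y)[0, 1])


@dataclass
class TwoGroupResult:
    """Welch two-sample comparison (e.g. SNRI vs non-SNRI participants)."""

    T: float
    p: float
    means: dict
    sems: dict
    flagged: bool = False


def two_group_compare(values, labels) -> TwoGroupResult:
    """Welch two-sample T with two-tailed p between the two label groups."""
    values = np.asarray(values, float)
    labels = np.asarray(labels)
    levels = pd.unique(labels)
    if len(levels) != 2:
        raise ValueError(f"expected exactly 2 groups, got {list(levels)}")
    a = values[labels == levels[0]]
    b = values[labels == levels[1]]
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 observations per group")
    flagged = a.std(ddof=1) == 0 and b.std(ddof=1) == 0
    if flagged:
        t_stat, p = np.nan, np.nan
    else:
        t_stat, p = sps.ttest_ind(a, b, equal_var=False)
    return TwoGroupResult(
        T=float(t_stat),
        p=float(p),
        means={str(levels[0]): float(a.mean()), str(levels[1]): float(b.mean())},
        sems={str(levels[0]): float(sps.sem(a, ddof=1)), str(levels[1]): float(sps.sem(b, ddof=1))},
        flagged=flagged,
    )
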