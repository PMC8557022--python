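"""Cohort-description statistics: summary t-test, exact Fisher 2x2,
exact small-sample Mann-Whitney.

These reproduce the usual case-control "Table 1" comparisons.  The
t-test works from published summary statistics (mean, SD, n per group);
the Fisher test sums hypergeometric point probabilities no larger than
the observed table's; the Mann-Whitney test enumerates all group
assignments exactly whenever the combined sample is small enough.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb, sqrt

import numpy as np
from scipy import stats

from .errors import DegenerateVarianceError, InvalidArgumentError


@dataclass
class SummaryGroup:
    mean: float
    sd: float
    n: int

    def __post_init__(self):
        if self.n < 2:
            raise InvalidArgumentError("summary group needs n >= 2")
        if self.sd < 0:
            raise InvalidArgumentError("sd must be >= 0")


def ttest_from_summary(
    g1: SummaryGroup, g2: SummaryGroup, variant: str = "student"
) -> tuple[float, float, float]:
    """Two-sample t-test from summary statistics.

    ``variant="student"`` pools the variances (df = n1 + n2 - 2);
    ``"welch"`` uses the Welch-Satterthwaite approximation.  Returns
    (t, df, two-sided p).  If both SDs are zero the test is degenerate:
    equal means give p = 1 by convention, unequal means raise.
    """
    if variant not in ("student", "welch"):
        raise InvalidArgumentError("variant must be 'student' or 'welch'")
    if g1.sd == 0 and g2.sd == 0:
        if g1.mean == g2.mean:
            return 0.0, float(g1.n + g2.n - 2), 1.0
        raise DegenerateVarianceError(
            "zero variance in both groups with unequal means"
        )
    diff = g1.mean - g2.mean
    if variant == "student":
        df = g1.n + g2.n - 2
        sp2 = ((g1.n - 1) * g1.sd**2 + (g2.n - 1) * g2.sd**2) / df
        se = sqrt(sp2 * (1.0 / g1.n + 1.0 / g2.n))
    else:
        v1, v2 = g1.sd**2 / g1.n, g2.sd**2 / g2.n
        se = sqrt(v1 + v2)
        df = (v1 + v2) ** 2 / (v1**2 / (g1.n - 1) + v2**2 / (g2.n - 1))
    t = diff / se
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the table [[a, b], [c, d]].

    Sums, over all tables with the observed margins, the hypergeometric
    point probabilities not exceeding the observed table's probability
    (with a 1 + 1e-7 relative tolerance against floating-point ties).
    """
    for x in (a, b, c, d):
        if x < 0 or x != int(x):
            raise InvalidArgumentError("counts must be non-negative integers")
    n = a + b + c + d
    if n == 0:
        raise InvalidArgumentError("at least one count must be positive")
    r1, c1 = a + b, a + c

    def pmf(k: int) -> float:
        return comb(r1, k) * comb(n - r1, c1 - k) / comb(n, c1)

    lo, hi = max(0, c1 - (n - r1)), min(r1, c1)
    p_obs = pmf(a)
    total = sum(pmf(k) for k in range(lo, hi + 1) if pmf(k) <= p_obs * (1 + 1e-7))
    return float(min(total, 1.0))


def mannwhitney_exact(x, y, exact_max_n: int = 20) -> tuple[float, float]:
    """Mann-Whitney U with an exact two-sided p for small samples.

    For combined n <= ``exact_max_n`` every C(n1+n2, n1) assignment of the
    pooled values to group labels is enumerated and the p-value is the
    fraction of assignments whose U is at least as far from the null mean
    n1*n2/2 as the observed U.  Larger samples fall back to the normal
    approximation with tie correction and continuity correction.
    Returns (U of the first sample, two-sided p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise InvalidArgumentError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)  # midranks under ties
    u_obs = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)

    if n1 + n2 <= exact_max_n:
        base = n1 * (n1 + 1) / 2.0
        mid = n1 * n2 / 2.0
        dev_obs = abs(u_obs - mid)
        hits = 0
        total = 0
        for idx in combinations(range(n1 + n2), n1):
            u = ranks[list(idx)].sum() - base
            if abs(u - mid) >= dev_obs - 1e-9:
                hits += 1
            total += 1
        return u_obs, hits / total

    # normal approximation with tie correction
    n = n1 + n2
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / (n * (n - 1))
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if sigma2 <= 0:
        return u_obs, 1.0
    mid = n1 * n2 / 2.0
    z = (abs(u_obs - mid) - 0.5) / sqrt(sigma2)
    return u_obs, float(2.0 * stats.norm.sf(max(z, 0.0)))


def table1_from_sheet(sheet, numeric_vars=("age",), categorical_vars=("sex",)) -> "pd.DataFrame":
    """Table-1-style cohort comparison from a raw sample sheet.

    Numeric variables use the summary t-test on the per-group mean/SD/n;
    two-level categorical variables use the Fisher exact test.
    """
    import pandas as pd

    case = sheet[sheet["group"] == "case"]
    ctrl = sheet[sheet["group"] == "control"]
    rows = []
    for var in numeric_vars:
        g1 = SummaryGroup(case[var].mean(), case[var].std(ddof=1), len(case))
        g2 = SummaryGroup(ctrl[var].mean(), ctrl[var].std(ddof=1), len(ctrl))
        _, _, p = ttest_from_summary(g1, g2)
        rows.append(
            {
                "variable": var,
                "test": "t-test",
                "case": f"{g1.mean:.1f} +/- {g1.sd:.1f}",
                "control": f"{g2.mean:.1f} +/- {g2.sd:.1f}",
                "p": p,
            }
        )
    for var in categorical_vars:
        levels = sorted(set(sheet[var]))
        if len(levels) != 2:
            continue
        a = int((case[var] == levels[0]).sum())
        b = int((case[var] == levels[1]).sum())
        c = int((ctrl[var] == levels[0]).sum())
        d = int((ctrl[var] == levels[1]).sum())
        rows.append(
            {
                "variable": var,
                "test": "fisher",
                "case": f"{a}/{b}",
                "control": f"{c}/{d}",
                "p": fisher_exact_2x2(a, b, c, d),
            }
        )
    return pd.DataFrame(rows)
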