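"""Group-comparison statistics for twin-cohort tables.

Clinical sFGR cohort papers report group differences from printed summary
data: two-sample t-tests on mean ± SD birth weights, count (percent) cells
for categorical outcomes, Mann-Whitney rank-sum Z values for skewed
measures such as placental area ratios, and Fisher/chi-square p values for
small contingency tables.  This module reproduces those calculations from
the summaries alone, so that printed tables can be checked and synthetic
cohorts compared with the same machinery.

The reference summaries of the motivating monochorionic-twin sFGR cohort
(23 sFGR pairs vs 32 uncomplicated controls) are included as module
constants for use in examples and reproduction scripts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sst

__all__ = [
    "SummaryStats",
    "GroupComparison",
    "t_from_summary",
    "proportion_pct",
    "rank_sum_z",
    "fisher_exact_or_chisq",
    "BIRTH_WEIGHT_SFGR_LARGER",
    "BIRTH_WEIGHT_SFGR_SMALLER",
    "BIRTH_WEIGHT_CONTROL_LARGER",
    "BIRTH_WEIGHT_CONTROL_SMALLER",
    "AV_ANASTOMOSIS_COUNTS",
    "GENERAL_CONDITION_COUNTS",
]


@dataclass(frozen=True)
class SummaryStats:
    """(mean, SD, n) summary of one group's measurements."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be non-negative")
        if self.n < 2:
            raise ValueError("n must be at least 2")

    @classmethod
    def from_data(cls, data: Sequence[float]) -> "SummaryStats":
        arr = np.asarray(data, dtype=float)
        return cls(mean=float(arr.mean()), sd=float(arr.std(ddof=1)), n=len(arr))


@dataclass(frozen=True)
class GroupComparison:
    """A two-group test result: statistic, p value and (for t) df."""

    statistic: float
    p_value: float
    df: Optional[float] = None
    method: str = ""


# ---------------------------------------------------------------------------
# Reference cohort summaries (sFGR group n=23 vs control group n=32):
# birth weights in grams of the larger and smaller twin of each pair, the
# arteriovenous-anastomosis counts, and the general-condition 2x2 tables
# (affected count out of group size).
# ---------------------------------------------------------------------------

BIRTH_WEIGHT_SFGR_LARGER = SummaryStats(mean=2119.0, sd=454.0, n=23)
BIRTH_WEIGHT_SFGR_SMALLER = SummaryStats(mean=1444.0, sd=350.0, n=23)
BIRTH_WEIGHT_CONTROL_LARGER = SummaryStats(mean=2362.0, sd=546.0, n=32)
BIRTH_WEIGHT_CONTROL_SMALLER = SummaryStats(mean=2112.0, sd=553.0, n=32)

#: Pairs with at least one arteriovenous anastomosis: (count, group size).
AV_ANASTOMOSIS_COUNTS = {"sfgr": (19, 23), "control": (23, 32)}

#: General-condition comparisons: (affected in sFGR of 23, affected in control of 32).
GENERAL_CONDITION_COUNTS = {
    "senile_parturient": (1, 3),
    "trans_parturient": (2, 7),
    "assisted_reproduction": (2, 8),
    "early_fetal_reduction": (0, 1),
    "hypertension": (3, 3),
}


def t_from_summary(
    a: SummaryStats, b: SummaryStats, variant: str = "pooled"
) -> GroupComparison:
    """Two-sample t-test from summary statistics.

    ``variant="pooled"`` assumes equal variances (Student); ``"welch"``
    does not, with Welch–Satterthwaite degrees of freedom.  p is two-sided.
    """
    if variant not in ("pooled", "welch"):
        raise ValueError(f"variant must be 'pooled' or 'welch', got {variant!r}")
    res = sst.ttest_ind_from_stats(
        a.mean, a.sd, a.n, b.mean, b.sd, b.n, equal_var=(variant == "pooled")
    )
    if variant == "pooled":
        df = float(a.n + b.n - 2)
    else:
        va, vb = a.sd**2 / a.n, b.sd**2 / b.n
        df = (va + vb) ** 2 / (va**2 / (a.n - 1) + vb**2 / (b.n - 1))
    return GroupComparison(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        df=df,
        method=f"t_{variant}",
    )


def proportion_pct(count: int, total: int) -> float:
    """Percentage 100*count/total, rounded half-up to one decimal place.

    Matches the count(percent) cell convention of clinical tables, e.g.
    19 of 23 → 82.6.
    """
    if total <= 0:
        raise ValueError("total must be positive")
    if not 0 <= count <= total:
        raise ValueError("count must lie in [0, total]")
    pct = Decimal(100 * count) / Decimal(total)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def rank_sum_z(sample_x: Sequence[float], sample_y: Sequence[float]) -> GroupComparison:
    """Mann-Whitney rank-sum comparison as a normal-approximation Z.

    U is computed from midranks; Z = (U - n1 n2 / 2) / sigma with the
    standard tie-corrected variance

        sigma^2 = (n1 n2 / 12) * [(n + 1) - sum(t^3 - t) / (n (n - 1))]

    over tie groups of size t.  p is the two-sided normal tail.  Fully
    tied data (sigma = 0) gives Z = 0, p = 1.
    """
    x = np.asarray(sample_x, dtype=float)
    y = np.asarray(sample_y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = len(x), len(y)
    n = n1 + n2
    ranks = sst.rankdata(np.concatenate([x, y]))
    u1 = float(ranks[:n1].sum()) - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    _, tie_counts = np.unique(np.concatenate([x, y]), return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1))) if n > 1 else 0.0
    if var <= 0:
        return GroupComparison(statistic=0.0, p_value=1.0, method="mann_whitney_z")
    z = (u1 - mu) / math.sqrt(var)
    p = 2.0 * sst.norm.sf(abs(z))
    return GroupComparison(statistic=z, p_value=min(1.0, p), method="mann_whitney_z")


def fisher_exact_or_chisq(table_2x2) -> GroupComparison:
    """Two-sided test of a 2x2 contingency table.

    Uses Fisher's exact test when any expected cell count is below 5
    (small clinical tables routinely have cells of 0 or 1), otherwise the
    chi-square test with Yates continuity correction.  The statistic is
    the odds ratio for Fisher and the chi-square value otherwise.
    """
    table = np.asarray(table_2x2)
    if table.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(table < 0) or not np.issubdtype(table.dtype, np.integer):
        if np.any(table != np.rint(table)) or np.any(table < 0):
            raise ValueError("cells must be non-negative integers")
        table = table.astype(int)
    total = table.sum()
    if total == 0:
        raise ValueError("table must contain at least one observation")
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / total
    if np.any(expected < 5):
        odds, p = sst.fisher_exact(table, alternative="two-sided")
        return GroupComparison(statistic=float(odds), p_value=float(p), method="fisher")
    chi2, p, df, _ = sst.chi2_contingency(table, correction=True)
    return GroupComparison(
        statistic=float(chi2), p_value=float(p), df=float(df), method="chi2_yates"
    )
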