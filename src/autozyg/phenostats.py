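"""Phenotype and product-quality statistics.

Group summaries, Welch two-sample t-tests (from raw data or published
summary statistics), one-way ANOVA with Bonferroni-corrected pairwise
comparisons, fold changes, CIELAB color metrics (hue angle in degrees,
chroma, a*/b*), and percent cook loss.  Tests are two-sided throughout.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class GroupSummary:
    label: str
    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.sd < 0:
            raise ValueError("sd must be non-negative")
        if self.sd > 0 and self.n < 2:
            raise ValueError("sd requires n >= 2")

    @classmethod
    def from_values(cls, label: str, values) -> "GroupSummary":
        v = np.asarray(values, dtype=float)
        return cls(label=label, n=len(v), mean=float(v.mean()),
                   sd=float(v.std(ddof=1)) if len(v) > 1 else 0.0)


@dataclass
class TestResult:
    statistic: float
    df: float
    p_value: float
    method: str
    adjusted_p: float | None = None


@dataclass
class ColorReading:
    L_star: float
    a_star: float
    b_star: float
    hue_angle_deg: float
    chroma: float
    a_over_b: float


def welch_t_from_summary(g1: GroupSummary, g2: GroupSummary) -> TestResult:
    """Welch t-test from group summaries (unequal variances,
    Welch-Satterthwaite degrees of freedom, two-sided p)."""
    for g in (g1, g2):
        if g.n < 2:
            raise ValueError(f"group {g.label!r}: cannot test with n < 2")
    if g1.sd == 0 and g2.sd == 0:
        if g1.mean == g2.mean:
            return TestResult(0.0, float(g1.n + g2.n - 2), 1.0, "welch_t")
        raise ValueError("both groups have zero variance and different means")
    v1, v2 = g1.sd**2 / g1.n, g2.sd**2 / g2.n
    t = (g1.mean - g2.mean) / math.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1**2 / (g1.n - 1) + v2**2 / (g2.n - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return TestResult(statistic=t, df=df, p_value=float(min(p, 1.0)), method="welch_t")


def welch_t(values1, values2, labels=("group1", "group2")) -> TestResult:
    return welch_t_from_summary(
        GroupSummary.from_values(labels[0], values1),
        GroupSummary.from_values(labels[1], values2),
    )


def anova_bonferroni(
    groups: list, labels: list[str] | None = None
) -> tuple[TestResult, pd.DataFrame]:
    """One-way ANOVA plus Bonferroni-corrected pairwise Welch comparisons.

    All observations identical gives F = 0, p = 1 (rather than NaN).
    Pairwise p-values are multiplied by the number of pairs and capped at 1.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    for g in arrays:
        if len(g) < 2:
            raise ValueError("each group needs n >= 2")
    labels = labels or [f"group{i + 1}" for i in range(len(arrays))]
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        overall = TestResult(0.0, float(len(arrays) - 1), 1.0, "anova")
    else:
        f, p = stats.f_oneway(*arrays)
        overall = TestResult(float(f), float(len(arrays) - 1), float(p), "anova")
    pairs = [
        (i, j) for i in range(len(arrays)) for j in range(i + 1, len(arrays))
    ]
    rows = []
    for i, j in pairs:
        if np.ptp(np.concatenate([arrays[i], arrays[j]])) == 0:
            res = TestResult(0.0, float(len(arrays[i]) + len(arrays[j]) - 2), 1.0,
                             "welch_t")
        else:
            res = welch_t(arrays[i], arrays[j], (labels[i], labels[j]))
        adj = min(1.0, res.p_value * len(pairs))
        rows.append(
            {
                "group1": labels[i],
                "group2": labels[j],
                "t": res.statistic,
                "df": res.df,
                "p_value": res.p_value,
                "adjusted_p": adj,
            }
        )
    return overall, pd.DataFrame(rows)


def fold_change(
    mean_numerator: float, mean_denominator: float, decimals: int | None = None
) -> float:
    """Ratio of group means; ``decimals`` applies reporting-style rounding."""
    if mean_denominator <= 0:
        raise ValueError("denominator mean must be positive")
    ratio = mean_numerator / mean_denominator
    return round(ratio, decimals) if decimals is not None else ratio


def color_metrics(L_star: float, a_star: float, b_star: float) -> ColorReading:
    """CIELAB derived metrics: hue angle arctan(b*/a*) in degrees, chroma
    sqrt(a*^2 + b*^2), and the a*/b* ratio (NaN, flagged, when b* = 0)."""
    if a_star <= 0:
        raise ValueError("a* must be positive for meat color readings")
    hue = math.degrees(math.atan(b_star / a_star))
    chroma = math.hypot(a_star, b_star)
    if b_star == 0:
        logger.warning("b* = 0: a*/b* undefined, hue angle 0")
        a_over_b = float("nan")
        hue = 0.0
    else:
        a_over_b = a_star / b_star
    return ColorReading(L_star, a_star, b_star, hue, chroma, a_over_b)


def cook_loss(initial_weight: float, final_weight: float) -> float:
    """Percent weight lost in cooking: 100 x (initial - final) / initial."""
    if initial_weight <= 0:
        raise ValueError("initial weight must be positive")
    if final_weight > initial_weight:
        raise ValueError("final weight exceeds initial weight")
    return 100.0 * (initial_weight - final_weight) / initial_weight


def group_summary_table(df: pd.DataFrame, value_col: str, group_col: str) -> pd.DataFrame:
    """Per-group n/mean/sd report."""
    out = (
        df.groupby(group_col)[value_col]
        .agg(n="count", mean="mean", sd=lambda v: v.std(ddof=1))
        .reset_index()
    )
    return out
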