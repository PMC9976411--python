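"""Statistical analysis of trial tables and of printed summary statistics.

The analysis plan mirrors the experimental protocol: a Shapiro-Wilk
normality gate on each group, then a Student's t-test (or one-way ANOVA for
more than two groups) when both groups look normal, otherwise a
Mann-Whitney U test.  A from-summary t-test lets reported mean +/- SD +/- n
triples be re-analyzed without raw data.  All tests are two-sided.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy import stats as sps

__all__ = [
    "SummaryStats",
    "ComparisonResult",
    "TestName",
    "summarize",
    "compare_groups",
    "t_test_from_summary",
    "anova_oneway",
]


class TestName(str, Enum):
    STUDENT_T = "STUDENT_T"
    WELCH_T = "WELCH_T"
    MANN_WHITNEY = "MANN_WHITNEY"
    ANOVA_ONEWAY = "ANOVA_ONEWAY"
    SHAPIRO_WILK = "SHAPIRO_WILK"


@dataclass(frozen=True)
class SummaryStats:
    """mean +/- sd over n values (sample sd, n-1 denominator)."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.sd < 0:
            raise ValueError("sd must be non-negative")

    def __str__(self) -> str:
        return f"{self.mean:.2f}±{self.sd:.2f} (n={self.n})"


@dataclass(frozen=True)
class ComparisonResult:
    test_name: TestName
    statistic: float
    p_value: float
    df: float | tuple[float, float] | None = None
    gate: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value out of [0, 1]")

    def to_dict(self) -> dict:
        return {
            "test_name": self.test_name.value,
            "statistic": self.statistic,
            "df": list(self.df) if isinstance(self.df, tuple) else self.df,
            "p_value": self.p_value,
            "gate": self.gate,
        }


def summarize(values) -> SummaryStats:
    """mean, sample sd (0 by convention for n=1) and n."""
    v = np.asarray(values, dtype=float).ravel()
    if v.size == 0:
        raise ValueError("cannot summarize an empty sample")
    sd = float(np.std(v, ddof=1)) if v.size > 1 else 0.0
    return SummaryStats(float(np.mean(v)), sd, int(v.size))


def compare_groups(a, b, alpha: float = 0.05) -> ComparisonResult:
    """Normality-gated two-group comparison.

    Shapiro-Wilk on each group; if both p > ``alpha`` a (pooled) Student's
    t-test is used, otherwise a Mann-Whitney U test.  The gate decisions are
    attached to the result.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each group needs at least 3 values")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        raise ValueError("both groups are constant; no test is meaningful")
    gate = {}
    normal = True
    for name, grp in (("a", a), ("b", b)):
        if np.ptp(grp) == 0:
            # Shapiro-Wilk is undefined on a constant sample; treat as
            # non-normal so the rank test handles it
            gate[name] = {"statistic": float("nan"), "p_value": 0.0}
            normal = False
            continue
        w = sps.shapiro(grp)
        gate[name] = {"statistic": float(w.statistic), "p_value": float(w.pvalue)}
        normal = bool(normal and (w.pvalue > alpha))
    gate["alpha"] = alpha
    gate["normal"] = normal
    if normal:
        t = sps.ttest_ind(a, b, equal_var=True)
        return ComparisonResult(
            TestName.STUDENT_T,
            float(t.statistic),
            float(t.pvalue),
            df=float(len(a) + len(b) - 2),
            gate=gate,
        )
    u = sps.mannwhitneyu(a, b, alternative="two-sided")
    return ComparisonResult(
        TestName.MANN_WHITNEY, float(u.statistic), float(u.pvalue), gate=gate
    )


def t_test_from_summary(
    mean_a: float,
    sd_a: float,
    n_a: int,
    mean_b: float,
    sd_b: float,
    n_b: int,
    pooled: bool = True,
) -> ComparisonResult:
    """Two-sample t-test recomputed from reported mean/sd/n triples.

    ``pooled=True`` gives the classical Student test with n_a + n_b - 2
    degrees of freedom; ``pooled=False`` the Welch variant.  Two zero-sd
    groups with equal means return p = 1 by convention.
    """
    if n_a < 2 or n_b < 2:
        raise ValueError("need n >= 2 per group")
    if sd_a < 0 or sd_b < 0:
        raise ValueError("sds must be non-negative")
    if sd_a == 0 and sd_b == 0:
        if mean_a == mean_b:
            return ComparisonResult(
                TestName.STUDENT_T if pooled else TestName.WELCH_T,
                0.0, 1.0, df=float(n_a + n_b - 2),
            )
        raise ValueError("zero variance with unequal means: t is undefined")
    res = sps.ttest_ind_from_stats(
        mean_a, sd_a, n_a, mean_b, sd_b, n_b, equal_var=pooled
    )
    if pooled:
        df: float | tuple = float(n_a + n_b - 2)
        name = TestName.STUDENT_T
    else:
        va, vb = sd_a**2 / n_a, sd_b**2 / n_b
        df = float(
            (va + vb) ** 2 / (va**2 / (n_a - 1) + vb**2 / (n_b - 1))
        )
        name = TestName.WELCH_T
    return ComparisonResult(name, float(res.statistic), float(res.pvalue), df=df)


def anova_oneway(groups) -> ComparisonResult:
    """One-way ANOVA over >= 2 groups; df = (k - 1, N - k)."""
    arrs = [np.asarray(g, dtype=float).ravel() for g in groups]
    if len(arrs) < 2:
        raise ValueError("need at least two groups")
    if any(len(g) < 2 for g in arrs):
        raise ValueError("each group needs at least 2 values")
    k = len(arrs)
    n_total = sum(len(g) for g in arrs)
    if all(np.ptp(g) == 0 for g in arrs) and len({g[0] for g in arrs}) == 1:
        # identical constant groups: no variance anywhere, F = 0 by convention
        return ComparisonResult(
            TestName.ANOVA_ONEWAY, 0.0, 1.0, df=(float(k - 1), float(n_total - k))
        )
    f = sps.f_oneway(*arrs)
    stat = float(f.statistic)
    p = float(f.pvalue)
    if np.isnan(stat):  # identical groups with zero within-variance
        stat, p = 0.0, 1.0
    return ComparisonResult(
        TestName.ANOVA_ONEWAY, stat, p, df=(float(k - 1), float(n_total - k))
    )
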