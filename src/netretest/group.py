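"""Between-group statistics: pooled t-tests and the 2x2 chi-square.

Group comparisons of reliability scores use the two-sided pooled-variance
(Student) t-test with a Bonferroni-adjusted fixed significance level of
0.05 / m for m networks compared (0.05 / 9 = 0.0056 for the nine-network
design).  Demographic tables built from published summary statistics use the
same pooled t-test computed from means, SDs and group sizes alone, and the
Pearson chi-square without continuity correction for 2x2 sex counts — the
conventions under which the reference demographic table's printed p-values
reproduce.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .types import DegenerateInputError

N_NETWORKS_DEFAULT = 9


@dataclass(frozen=True)
class SummaryStats:
    """Published group summary: mean (SD), n."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be nonnegative")
        if self.n < 2:
            raise ValueError("n must be >= 2")


@dataclass(frozen=True)
class GroupComparison:
    label: str
    statistic: float
    df: float
    p: float
    significant_bonferroni: bool
    alpha_bonferroni: float


def _pooled_t(
    mean_a: float, sd_a: float, n_a: int, mean_b: float, sd_b: float, n_b: int
):
    df = n_a + n_b - 2
    sp2 = ((n_a - 1) * sd_a**2 + (n_b - 1) * sd_b**2) / df
    if sp2 == 0:
        if mean_a == mean_b:
            return 0.0, float(df), 1.0
        raise DegenerateInputError(
            "zero pooled variance with unequal means: t statistic undefined"
        )
    t = (mean_a - mean_b) / np.sqrt(sp2 * (1.0 / n_a + 1.0 / n_b))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(min(p, 1.0))


def _comparison(label, t, df, p, m_tests) -> GroupComparison:
    alpha = 0.05 / m_tests
    return GroupComparison(
        label=label,
        statistic=t,
        df=df,
        p=p,
        significant_bonferroni=bool(p < alpha),
        alpha_bonferroni=alpha,
    )


def compare_groups(
    scores_a, scores_b, m_tests: int = N_NETWORKS_DEFAULT, label: str = ""
) -> GroupComparison:
    """Two-sided pooled-variance t-test between two groups of subject scores.

    ``m_tests`` sets the Bonferroni-adjusted significance level 0.05/m at
    which the ``significant_bonferroni`` flag is raised (9 networks by
    default, giving the 0.0056 level).
    """
    a = np.asarray(scores_a, dtype=np.float64)
    b = np.asarray(scores_b, dtype=np.float64)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if a.size < 2 or b.size < 2:
        raise DegenerateInputError("each group needs >= 2 subjects")
    t, df, p = _pooled_t(
        a.mean(), a.std(ddof=1), a.size, b.mean(), b.std(ddof=1), b.size
    )
    return _comparison(label, t, df, p, m_tests)


def ttest_from_summary(
    a: SummaryStats, b: SummaryStats, m_tests: int = 1, label: str = ""
) -> GroupComparison:
    """Pooled t-test from published means, SDs and ns only (df = n_a+n_b−2)."""
    t, df, p = _pooled_t(a.mean, a.sd, a.n, b.mean, b.sd, b.n)
    return _comparison(label, t, df, p, m_tests)


def chisq_2x2(
    a_yes: int, a_no: int, b_yes: int, b_no: int, m_tests: int = 1, label: str = ""
) -> GroupComparison:
    """Pearson chi-square on a 2x2 table, df = 1, no continuity correction.

    Equals n(ad−bc)² / ((a+b)(c+d)(a+c)(b+d)) exactly.
    """
    cells = (a_yes, a_no, b_yes, b_no)
    if any(c < 0 for c in cells):
        raise ValueError("cell counts must be nonnegative")
    a, b, c, d = (float(x) for x in cells)
    n = a + b + c + d
    margins = ((a + b), (c + d), (a + c), (b + d))
    if any(m == 0 for m in margins):
        raise DegenerateInputError(
            f"chi-square undefined: zero margin in table {cells}"
        )
    chi2 = n * (a * d - b * c) ** 2 / np.prod(margins)
    p = float(stats.chi2.sf(chi2, 1))
    return _comparison(label, float(chi2), 1.0, p, m_tests)
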