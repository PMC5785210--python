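"""Group summaries and hypothesis tests for pipeline outputs.

Summary statistics follow the conventions of the slice experiments this
package targets: mean ± SEM for curve data, and boxplots whose central
line is the median, box edges the 25th/75th percentiles, whiskers the
furthest points within 1.5×IQR of the box, points beyond that drawn as
outliers, with a 95% confidence interval of the median by the
``±1.57×IQR/√n`` notch convention.

Hypothesis tests are the two-tailed Student's t-test (equal-variance by
default; Welch behind a flag) for two groups and one-way ANOVA with
Bonferroni-corrected pairwise post-hoc t-tests for three or more.
Normality is assumed, not tested; :func:`distribution_diagnostics` reports
skew and kurtosis but never changes which test runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats as sps


class StatsError(ValueError):
    """Invalid statistical input."""


#: Significance cutoffs and their star labels, strongest first.
STAR_LEVELS = ((0.0005, "***"), (0.005, "**"), (0.05, "*"))


def significance_stars(p: float) -> str:
    """Star annotation at the 0.05 / 0.005 / 0.0005 cutoffs ('' if n.s.)."""
    for cutoff, stars in STAR_LEVELS:
        if p < cutoff:
            return stars
    return ""


@dataclass
class GroupSummary:
    """Per-group descriptive statistics (mean ± SEM plus boxplot stats)."""

    label: str
    n: int
    mean: float
    sem: float
    median: float
    q25: float
    q75: float
    whisker_lo: float
    whisker_hi: float
    outliers: np.ndarray
    ci95_lo: float
    ci95_hi: float


@dataclass
class TestResult:
    """Outcome of a hypothesis test, with optional post-hoc pairs."""

    test: str
    statistic: float
    p_value: float
    pairwise: List[Tuple[str, str, float]] = field(default_factory=list)

    @property
    def stars(self) -> str:
        return significance_stars(self.p_value)


def _clean(label: str, values) -> np.ndarray:
    x = np.asarray(values, dtype=np.float64)
    x = x[np.isfinite(x)]
    if x.size == 0:
        raise StatsError(f"group {label!r} is empty")
    return x


def summarize(groups: Dict[str, Sequence[float]]) -> List[GroupSummary]:
    """Mean, SEM and boxplot statistics for each group.

    SEM uses the sample SD (n−1 denominator); a single-value group gets
    SEM 0 and a degenerate box.  Whiskers extend to the furthest data
    point within 1.5×IQR of the box; the median's 95% CI uses
    ``median ± 1.57×IQR/√n``.
    """
    out = []
    for label, values in groups.items():
        x = _clean(label, values)
        n = x.size
        mean = float(x.mean())
        sem = float(x.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
        q25, med, q75 = (float(v) for v in np.percentile(x, [25, 50, 75]))
        iqr = q75 - q25
        lo_fence, hi_fence = q25 - 1.5 * iqr, q75 + 1.5 * iqr
        inliers = x[(x >= lo_fence) & (x <= hi_fence)]
        outliers = x[(x < lo_fence) | (x > hi_fence)]
        half_ci = 1.57 * iqr / np.sqrt(n)
        out.append(GroupSummary(
            label=label, n=n, mean=mean, sem=sem, median=med,
            q25=q25, q75=q75,
            whisker_lo=float(inliers.min()), whisker_hi=float(inliers.max()),
            outliers=np.sort(outliers),
            ci95_lo=med - half_ci, ci95_hi=med + half_ci))
    return out


def two_tailed_t(
    group_a: Sequence[float],
    group_b: Sequence[float],
    equal_var: bool = True,
    labels: Tuple[str, str] = ("a", "b"),
) -> TestResult:
    """Two-sample two-tailed Student's t-test (Welch if ``equal_var`` is
    False)."""
    a = _clean(labels[0], group_a)
    b = _clean(labels[1], group_b)
    if a.size < 2 or b.size < 2:
        raise StatsError("t-test needs n >= 2 in each group")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if float(a.mean()) == float(b.mean()):
            # identical constant groups: no evidence of any difference
            return TestResult(test="t" if equal_var else "welch_t",
                              statistic=0.0, p_value=1.0)
        raise StatsError("zero pooled variance with unequal means")
    t, p = sps.ttest_ind(a, b, equal_var=equal_var)
    return TestResult(test="t" if equal_var else "welch_t",
                      statistic=float(t), p_value=float(p))


def one_way_anova(groups: Dict[str, Sequence[float]]) -> TestResult:
    """One-way ANOVA with Bonferroni-corrected pairwise post-hoc t-tests.

    The omnibus F and p come from the standard between/within
    decomposition; each pair of groups is then compared with the
    equal-variance t-test and its p-value multiplied by the number of
    pairs (capped at 1).
    """
    if len(groups) < 2:
        raise StatsError("one-way ANOVA needs >= 2 groups")
    arrays = {k: _clean(k, v) for k, v in groups.items()}
    for k, x in arrays.items():
        if x.size < 2:
            raise StatsError(f"group {k!r} needs n >= 2")
    if all(x.var(ddof=1) == 0 for x in arrays.values()) and \
            len({float(x.mean()) for x in arrays.values()}) == 1:
        f, p = 0.0, 1.0
    else:
        f, p = sps.f_oneway(*arrays.values())
    n_pairs = len(arrays) * (len(arrays) - 1) // 2
    pairwise = []
    for ka, kb in combinations(arrays, 2):
        res = two_tailed_t(arrays[ka], arrays[kb], labels=(ka, kb))
        adj = min(1.0, res.p_value * n_pairs)
        pairwise.append((ka, kb, adj))
    return TestResult(test="one_way_anova", statistic=float(f),
                      p_value=float(p), pairwise=pairwise)


def bonferroni(p_values: Sequence[float], n_tests: Optional[int] = None) -> np.ndarray:
    """Bonferroni adjustment: ``min(1, p × n_tests)`` per value."""
    p = np.asarray(p_values, dtype=np.float64)
    m = len(p) if n_tests is None else n_tests
    return np.minimum(1.0, p * m)


def distribution_diagnostics(groups: Dict[str, Sequence[float]]) -> Dict[str, Dict[str, float]]:
    """Skewness and excess kurtosis per group — reported for the record
    only; the choice of test never depends on them."""
    out = {}
    for label, values in groups.items():
        x = _clean(label, values)
        out[label] = {
            "n": int(x.size),
            "skew": float(sps.skew(x)) if x.size > 2 else float("nan"),
            "excess_kurtosis": float(sps.kurtosis(x)) if x.size > 3 else float("nan"),
        }
    return out
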