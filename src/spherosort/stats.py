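"""Two-sample comparison following the normality-gated decision tree.

Shapiro–Wilk on each sample decides the branch: if either sample rejects
normality at the gate (default 0.05) the comparison is a Wilcoxon rank-sum
test; otherwise an F test on the variances chooses between the Student
(pooled-variance) and Welch two-sample t-tests.  All tests are unpaired and
two-sided.  Significance stars: * p<0.05, ** p<0.01, *** p<0.001.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = ["ComparisonResult", "compare_groups", "significance_stars", "benjamini_hochberg"]


@dataclass
class ComparisonResult:
    """Outcome of one two-sample comparison.

    ``test_name`` records which branch of the decision tree ran;
    ``normality_p`` holds the per-sample Shapiro–Wilk p-values and
    ``variance_p`` the F-test p-value (None when the Wilcoxon branch ran).
    """

    test_name: str  # "student-t" | "welch-t" | "wilcoxon-rank-sum"
    p_value: float
    statistic: float
    normality_p: tuple[float, float]
    variance_p: float | None
    n: tuple[int, int]
    sidedness: str = "two-sided"
    paired: bool = False

    @property
    def stars(self) -> str:
        return significance_stars(self.p_value)


def significance_stars(p: float) -> str:
    """Annotation at the 0.05 / 0.01 / 0.001 levels; 'ns' otherwise."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def _f_test_two_sided(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Variance-ratio F test, two-sided, as in R's var.test."""
    vx = np.var(x, ddof=1)
    vy = np.var(y, ddof=1)
    dfx, dfy = len(x) - 1, len(y) - 1
    f = vx / vy
    cdf = sps.f.cdf(f, dfx, dfy)
    p = 2.0 * min(cdf, 1.0 - cdf)
    return float(f), float(min(p, 1.0))


def compare_groups(
    x,
    y,
    alpha_gate: float = 0.05,
) -> ComparisonResult:
    """Compare two independent samples by the normality-gated decision tree.

    Parameters
    ----------
    x, y : array-like
        Samples of at least 3 observations each.
    alpha_gate : float
        Significance level used both for the Shapiro–Wilk normality gate and
        for the F-test variance gate.

    Notes
    -----
    A constant sample makes Shapiro–Wilk undefined; the comparison then falls
    through to the Wilcoxon branch with a warning.  Rejection of normality in
    EITHER sample routes to Wilcoxon (the conservative choice).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or len(y) < 3:
        raise ValueError(f"need n >= 3 per sample, got {len(x)} and {len(y)}")

    def shapiro_p(s: np.ndarray) -> float | None:
        if np.ptp(s) == 0:
            return None
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return float(sps.shapiro(s).pvalue)

    px, py = shapiro_p(x), shapiro_p(y)
    degenerate = px is None or py is None
    if degenerate:
        warnings.warn("constant sample: Shapiro-Wilk undefined, using Wilcoxon")
    normal = (not degenerate) and px >= alpha_gate and py >= alpha_gate

    if not normal:
        method = "exact" if max(len(x), len(y)) <= 20 else "asymptotic"
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
        return ComparisonResult(
            test_name="wilcoxon-rank-sum",
            p_value=float(res.pvalue),
            statistic=float(res.statistic),
            normality_p=(px if px is not None else np.nan, py if py is not None else np.nan),
            variance_p=None,
            n=(len(x), len(y)),
        )

    f_stat, f_p = _f_test_two_sided(x, y)
    equal_var = f_p >= alpha_gate
    res = sps.ttest_ind(x, y, equal_var=equal_var, alternative="two-sided")
    return ComparisonResult(
        test_name="student-t" if equal_var else "welch-t",
        p_value=float(res.pvalue),
        statistic=float(res.statistic),
        normality_p=(px, py),
        variance_p=f_p,
        n=(len(x), len(y)),
    )


def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values (off by default in all pipelines)."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p_values, dtype=float)
    return multipletests(p, method="fdr_bh")[1]
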