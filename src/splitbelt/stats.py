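"""Group statistics: mass-univariate tests with adaptive FDR control.

Epoch contrasts are tested per activity-vector component with the
two-tailed Wilcoxon signed-rank test on paired per-subject differences
(the non-parametric analog of a paired t test); effect sizes are
across-subject median differences.  The many comparisons (360 by
default) are controlled with the Benjamini-Krieger-Yekutieli two-stage
linear step-up procedure at FDR q = 0.05, and a display mask
additionally requires an absolute median effect above 10% of baseline
maximum so that significant-but-negligible components are not shown.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import stats as sps


class DegenerateComparisonError(ValueError):
    pass


class UndefinedCorrelationError(ValueError):
    pass


# --------------------------------------------------------------------------
# Wilcoxon signed-rank, vectorized across components

@lru_cache(maxsize=64)
def signed_rank_distribution(n: int) -> np.ndarray:
    """Exact null pmf of the positive-rank sum W+ for n untied pairs.

    Computed by the standard generating-polynomial recursion
    prod_{r=1..n} (1 + x^r) / 2^n; entry w is P(W+ = w),
    w = 0 .. n(n+1)/2.
    """
    pmf = np.array([1.0])
    for r in range(1, n + 1):
        nxt = np.zeros(pmf.size + r)
        nxt[: pmf.size] += pmf
        nxt[r:] += pmf
        pmf = nxt
    return pmf / 2.0**n

def _exact_two_tailed_p(w: float, n: int) -> float:
    pmf = signed_rank_distribution(n)
    w = int(round(w))
    lower = pmf[: w + 1].sum()
    upper = pmf[w:].sum()
    return float(min(1.0, 2.0 * min(lower, upper)))


def signed_rank_p(diffs: np.ndarray, exact_max_n: int = 25) -> tuple[float, bool]:
    """Two-tailed signed-rank p for one vector of paired differences.

    Zero differences are dropped before ranking (Wilcoxon's original
    treatment); ties among |d| get average ranks.  The exact null
    distribution is used for n <= ``exact_max_n`` when the ranks are
    untied, otherwise the normal approximation with tie correction.
    Returns (p, tie_flag); an all-zero vector yields p = 1 with the tie
    flag set.
    """
    d = np.asarray(diffs, float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        return 1.0, True
    ranks = sps.rankdata(np.abs(d))
    w_plus = ranks[d > 0].sum()
    has_ties = np.unique(np.abs(d)).size < n
    if n <= exact_max_n and not has_ties:
        return _exact_two_tailed_p(w_plus, n), False
    # normal approximation with tie correction on the rank variance
    mu = n * (n + 1) / 4.0
    _, counts = np.unique(np.abs(d), return_counts=True)
    tie_term = (counts**3 - counts).sum() / 48.0
    sigma2 = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    if sigma2 <= 0:
        return 1.0, True
    z = (w_plus - mu - 0.5 * np.sign(w_plus - mu)) / np.sqrt(sigma2)
    return float(min(1.0, 2.0 * sps.norm.sf(abs(z)))), has_ties


@dataclass
class VariableTestResult:
    """Per-component outcome of a mass-univariate epoch contrast."""

    effect: np.ndarray          # across-subject median difference, % baseline max
    p: np.ndarray
    tie_flag: np.ndarray
    significant: np.ndarray | None = None
    displayed: np.ndarray | None = None


def wilcoxon_map(
    epoch_a: np.ndarray, epoch_b: np.ndarray, exact_max_n: int = 25
) -> VariableTestResult:
    """Component-wise Wilcoxon signed-rank contrast of two epochs.

    ``epoch_a``/``epoch_b`` have shape (n_subjects, n_components); the
    test is applied to the paired differences a - b of each component.
    """
    a = np.asarray(epoch_a, float)
    b = np.asarray(epoch_b, float)
    if a.shape != b.shape:
        raise ValueError("epoch matrices must have identical shape")
    if a.shape[0] < 5:
        raise ValueError("need at least 5 subjects")
    d = a - b
    m = d.shape[1]
    p = np.empty(m)
    ties = np.zeros(m, dtype=bool)
    for j in range(m):
        p[j], ties[j] = signed_rank_p(d[:, j], exact_max_n)
    return VariableTestResult(effect=np.median(d, axis=0), p=p, tie_flag=ties)


# --------------------------------------------------------------------------
# Benjamini-Krieger-Yekutieli two-stage FDR

@dataclass
class FdrResult:
    q: float
    critical_p: float
    reject: np.ndarray
    m0_estimate: int
    n_rejected: int = field(init=False)

    def __post_init__(self) -> None:
        self.n_rejected = int(self.reject.sum())


def _bh_step_up(p: np.ndarray, alpha: float) -> np.ndarray:
    """Benjamini-Hochberg linear step-up rejection mask at level alpha."""
    m = p.size
    order = np.argsort(p, kind="stable")
    thresh = alpha * (np.arange(1, m + 1)) / m
    below = p[order] <= thresh
    if not below.any():
        return np.zeros(m, dtype=bool)
    k = np.flatnonzero(below).max()
    mask = np.zeros(m, dtype=bool)
    mask[order[: k + 1]] = True
    return mask


def bky_fdr(pvalues: np.ndarray, q: float = 0.05) -> FdrResult:
    """Two-stage adaptive linear step-up FDR control.

    Stage 1 runs BH at q' = q/(1+q) and estimates the number of true
    nulls as m0 = m - r1.  If r1 = 0 nothing is rejected; if r1 = m
    everything is.  Otherwise stage 2 runs BH at q' * m / m0 and its
    rejections are returned.  The realized critical p value is the
    largest rejected p (0 when nothing is rejected).
    """
    p = np.asarray(pvalues, float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    m = p.size
    q1 = q / (1.0 + q)
    stage1 = _bh_step_up(p, q1)
    r1 = int(stage1.sum())
    if r1 == 0:
        reject = stage1
        m0 = m
    elif r1 == m:
        reject = np.ones(m, dtype=bool)
        m0 = 0
    else:
        m0 = m - r1
        reject = _bh_step_up(p, q1 * m / m0)
    critical = float(p[reject].max()) if reject.any() else 0.0
    return FdrResult(q=q, critical_p=critical, reject=reject, m0_estimate=m0)


def display_mask(
    test: VariableTestResult, fdr: FdrResult, threshold_pct: float = 10.0
) -> np.ndarray:
    """Components that are significant AND have |median effect| > threshold.

    Used only for display: it suppresses statistically significant but
    small (presumably meaningless) differences.
    """
    test.significant = fdr.reject
    test.displayed = fdr.reject & (np.abs(test.effect) > threshold_pct)
    return test.displayed


# --------------------------------------------------------------------------
# Scalar group comparisons

@dataclass
class PairedComparison:
    t: float
    p: float
    mean_change: float
    cohens_d: float
    n: int
    degenerate: bool = False


def paired_beta_comparison(
    values_a: np.ndarray, values_b: np.ndarray
) -> PairedComparison:
    """Two-tailed paired t test of per-subject scalars (e.g. betas).

    Cohen's d is mean(diff)/sd(diff) with the sample (ddof=1) standard
    deviation.  Identical pairs (sd = 0) are reported with a degenerate
    flag rather than an error.
    """
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be 1-d and equal length")
    if a.size < 3:
        raise DegenerateComparisonError("need at least 3 pairs")
    d = a - b
    sd = d.std(ddof=1)
    if sd == 0:
        return PairedComparison(
            t=float("nan"), p=float("nan"), mean_change=float(d.mean()),
            cohens_d=float("nan"), n=d.size, degenerate=True,
        )
    t, p = sps.ttest_rel(a, b)
    return PairedComparison(
        t=float(t), p=float(p), mean_change=float(d.mean()),
        cohens_d=float(d.mean() / sd), n=d.size,
    )


def spearman_assoc(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rank correlation with average-rank ties, two-tailed p.

    The p value uses the t approximation for n >= 10 and an exact
    permutation distribution below (matching common package behaviour;
    cohort sizes of 14-15 always use the approximation).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 5:
        raise ValueError("need paired samples with n >= 5")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise UndefinedCorrelationError("constant input has no rank correlation")
    if x.size >= 10:
        rho, p = sps.spearmanr(x, y)
    else:
        res = sps.permutation_test(
            (x,), lambda xs: sps.spearmanr(xs, y).statistic,
            permutation_type="pairings", n_resamples=np.inf, alternative="two-sided",
        )
        rho = float(sps.spearmanr(x, y).statistic)
        p = res.pvalue
    return float(rho), float(p)
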