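"""Rank-based statistical comparison layer.

Workflow: screen each metric's distribution for normality with the
Anderson-Darling test; when normality fails (the usual case for bounded
percentages like VAF and accuracy), compare with rank statistics — the
Wilcoxon signed-rank test for paired two-method contrasts and the Friedman
test for k-treatment designs — applying a Bonferroni-adjusted significance
level to post-hoc families.

The Wilcoxon implementation uses an exact null distribution (dynamic
program over signed-rank sums, mid-ranked ties included) for n <= 25 pairs
and a normal approximation with continuity and tie corrections above that.
All tests are deterministic functions of their inputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


class StatError(ValueError):
    """Raised on degenerate or undersized statistical inputs."""


@dataclass
class StatOutcome:
    """One hypothesis-test result with its decision at the working level."""

    test_name: str
    statistic: float
    p_value: float
    n: int
    alpha: float = 0.05
    adjusted_alpha: float | None = None
    decision: str = "fail_to_reject"

    def to_dict(self) -> dict:
        return {
            "test_name": self.test_name,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "n": self.n,
            "alpha": self.alpha,
            "adjusted_alpha": self.adjusted_alpha,
            "decision": self.decision,
        }


def _decide(p: float, level: float) -> str:
    return "reject" if p < level else "fail_to_reject"


def anderson_darling_normality(x, alpha: float = 0.05) -> StatOutcome:
    """Anderson-Darling test of composite normality (mean and sd estimated).

    The A² statistic comes from scipy; the p-value uses the standard
    small-sample-corrected approximation for the normal family
    (A²* = A²(1 + 0.75/n + 2.25/n²) with the Stephens/D'Agostino piecewise
    exponential tail formulas).
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 8:
        raise StatError("Anderson-Darling needs at least 8 observations")
    if np.ptp(x) == 0.0:
        raise StatError("constant sample: normality test degenerate")
    import warnings

    with warnings.catch_warnings():
        # only the A² statistic is used; the p-value below comes from the
        # Stephens small-sample-corrected formula, not scipy's table lookup
        warnings.simplefilter("ignore", FutureWarning)
        a2 = float(sps.anderson(x, dist="norm").statistic)
    a2_star = a2 * (1.0 + 0.75 / n + 2.25 / n**2)
    if a2_star >= 0.6:
        p = np.exp(1.2937 - 5.709 * a2_star + 0.0186 * a2_star**2)
    elif a2_star >= 0.34:
        p = np.exp(0.9177 - 4.279 * a2_star - 1.38 * a2_star**2)
    elif a2_star >= 0.2:
        p = 1.0 - np.exp(-8.318 + 42.796 * a2_star - 59.938 * a2_star**2)
    else:
        p = 1.0 - np.exp(-13.436 + 101.14 * a2_star - 223.73 * a2_star**2)
    p = float(np.clip(p, 0.0, 1.0))
    return StatOutcome(
        test_name="anderson_darling",
        statistic=a2,
        p_value=p,
        n=n,
        alpha=alpha,
        decision=_decide(p, alpha),
    )


def _exact_signed_rank_tail(ranks: np.ndarray, w_plus: float):
    """Exact P(W+ <= w) and P(W+ >= w) under the signed-rank null.

    Dynamic program over the distribution of the positive-rank sum when each
    of the n ranks independently enters with probability 1/2.  Ranks are
    doubled so mid-ranks (halves) become integers.
    """
    r2 = np.rint(2.0 * ranks).astype(int)
    total = int(r2.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    counts /= counts.sum()
    w2 = int(np.rint(2.0 * w_plus))
    return counts[: w2 + 1].sum(), counts[w2:].sum()


def wilcoxon_signed_rank(x, y, alpha: float = 0.05, exact_max_n: int = 25) -> StatOutcome:
    """Two-sided paired Wilcoxon signed-rank test.

    Zero differences are dropped, tied absolute differences are mid-ranked.
    Exact enumeration of the null for n <= ``exact_max_n``; otherwise the
    normal approximation with continuity and tie corrections.  The reported
    statistic is the signed rank-sum difference W+ - W-, which flips sign
    when x and y are swapped while the p-value is unchanged.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise StatError("x and y must be equal-length 1-D paired vectors")
    d = x - y
    d = d[d != 0.0]
    n = len(d)
    if n < 5:
        raise StatError(
            f"only {n} nonzero differences; need at least 5 for a meaningful test"
        )
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())

    if n <= exact_max_n:
        p_le, p_ge = _exact_signed_rank_tail(ranks, w_plus)
        p = min(1.0, 2.0 * min(p_le, p_ge))
    else:
        mean = n * (n + 1) / 4.0
        _, tie_counts = np.unique(ranks, return_counts=True)
        tie_term = float(((tie_counts**3 - tie_counts)).sum()) / 48.0
        sd = np.sqrt(n * (n + 1) * (2 * n + 1) / 24.0 - tie_term)
        if sd == 0.0:
            raise StatError("degenerate variance in normal approximation")
        # continuity correction toward the mean
        z = (w_plus - mean - 0.5 * np.sign(w_plus - mean)) / sd
        p = float(min(1.0, 2.0 * sps.norm.sf(abs(z))))
    return StatOutcome(
        test_name="wilcoxon_signed_rank",
        statistic=w_plus - w_minus,
        p_value=float(p),
        n=n,
        alpha=alpha,
        decision=_decide(p, alpha),
    )


def friedman_test(scores, alpha: float = 0.05) -> StatOutcome:
    """Friedman rank test for k related treatments over b blocks.

    Entries are ranked within each block (ties mid-ranked); the chi-square
    statistic with k-1 degrees of freedom uses the standard tie correction.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 2:
        raise StatError("scores must be a blocks x treatments matrix")
    b, k = scores.shape
    if k < 2:
        raise StatError("need at least 2 treatments")
    if b < 2:
        raise StatError("need at least 2 blocks")
    ranks = np.vstack([sps.rankdata(row) for row in scores])
    rank_sums = ranks.sum(axis=0)
    chi2 = 12.0 / (b * k * (k + 1)) * float((rank_sums**2).sum()) - 3.0 * b * (k + 1)
    # tie correction: divide by 1 - sum(t^3 - t) / (b k (k^2 - 1))
    tie_sum = 0.0
    for row in scores:
        _, counts = np.unique(row, return_counts=True)
        tie_sum += float((counts**3 - counts).sum())
    correction = 1.0 - tie_sum / (b * k * (k**2 - 1))
    if correction <= 0.0:
        chi2 = 0.0  # every block fully tied: no evidence of treatment effect
    else:
        chi2 /= correction
    p = float(sps.chi2.sf(chi2, k - 1))
    return StatOutcome(
        test_name="friedman",
        statistic=float(chi2),
        p_value=p,
        n=b,
        alpha=alpha,
        decision=_decide(p, alpha),
    )


def bonferroni_adjust(alpha: float, m: int) -> float:
    """Bonferroni-adjusted significance level alpha/m for m comparisons."""
    if m < 1:
        raise StatError("m must be >= 1")
    if not 0 < alpha < 1:
        raise StatError("alpha must lie in (0, 1)")
    return alpha / m
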