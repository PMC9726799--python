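"""Statistical primitives for marker selection and diagnostic evaluation.

Rank tests delegate to scipy with an explicit policy for when the exact
null distribution is used; the ROC machinery, the minimum-corner-distance
cut-off rule, McNemar's test and the DeLong paired-AUC comparison are
implemented here because the selection cascade and the evaluation layer
depend on their precise conventions (tie handling, tie-breaking, strict
vs inclusive thresholds).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "TestResult",
    "RocResult",
    "rank_sum_test",
    "signed_rank_test",
    "roc_curve",
    "select_cutoff",
    "mcnemar_test",
    "delong_auc_variance",
    "delong_paired_auc_test",
]

#: Exact rank-sum enumeration is used when both samples have at most this
#: many observations and the pooled data are tie-free.
RANK_SUM_EXACT_MAX_N = 8
#: Exact signed-rank enumeration is used up to this many nonzero pairs.
SIGNED_RANK_EXACT_MAX_N = 10
#: Exact binomial McNemar is used when the discordant count is at most this.
MCNEMAR_EXACT_MAX_DISCORDANT = 25


@dataclass(frozen=True)
class TestResult:
    """A test statistic with its p-value and provenance tags."""

    statistic: float
    p_value: float
    method: str
    alternative: str = "two-sided"
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (0.0 <= self.p_value <= 1.0 or np.isnan(self.p_value)):
            raise ValueError(f"p-value outside [0, 1]: {self.p_value}")

    def to_dict(self) -> dict:
        return {"statistic": float(self.statistic), "p_value": float(self.p_value),
                "method": self.method, "alternative": self.alternative,
                **self.extra}


# ---------------------------------------------------------------------------
# rank tests
# ---------------------------------------------------------------------------

def rank_sum_test(x, y, alternative: str = "two-sided") -> TestResult:
    """Mann-Whitney U test of ``x`` against ``y``.

    Uses the exact null distribution when both samples have at most
    :data:`RANK_SUM_EXACT_MAX_N` observations and the pooled values are
    tie-free; otherwise the tie-corrected normal approximation with
    continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("rank_sum_test requires two nonempty samples")
    pooled = np.concatenate([x, y])
    tie_free = np.unique(pooled).size == pooled.size
    exact = tie_free and x.size <= RANK_SUM_EXACT_MAX_N and y.size <= RANK_SUM_EXACT_MAX_N
    method = "exact" if exact else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative=alternative, method=method,
                           use_continuity=True)
    return TestResult(statistic=float(res.statistic), p_value=float(res.pvalue),
                      method=f"mann-whitney-u/{method}", alternative=alternative)


def signed_rank_test(pre, post, alternative: str = "two-sided") -> TestResult:
    """Wilcoxon signed-rank test on paired samples (``pre`` vs ``post``).

    Zero differences are dropped.  With at most
    :data:`SIGNED_RANK_EXACT_MAX_N` nonzero pairs the full sign-pattern
    enumeration is used (ties in |difference| receive average ranks, which
    the enumeration handles exactly); larger samples use the normal
    approximation.  ``alternative="greater"`` tests pre > post.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape or pre.size == 0:
        raise ValueError("signed_rank_test requires equal-length nonempty samples")
    d = pre - post
    d = d[d != 0]
    if d.size == 0:
        warnings.warn("signed_rank_test: all differences are zero; p = 1")
        return TestResult(statistic=0.0, p_value=1.0,
                          method="wilcoxon-signed-rank/degenerate",
                          alternative=alternative)
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    n = d.size
    if n <= SIGNED_RANK_EXACT_MAX_N:
        # enumerate all 2^n sign assignments of the observed ranks
        sums = np.zeros(1)
        for r in ranks:
            sums = np.concatenate([sums, sums + r])
        total = sums.size
        p_greater = float(np.count_nonzero(sums >= w_plus - 1e-12)) / total
        p_less = float(np.count_nonzero(sums <= w_plus + 1e-12)) / total
        if alternative == "greater":
            p = p_greater
        elif alternative == "less":
            p = p_less
        else:
            p = min(1.0, 2.0 * min(p_greater, p_less))
        method = "wilcoxon-signed-rank/exact"
    else:
        res = sps.wilcoxon(d, alternative=alternative, method="approx",
                           correction=True)
        p = float(res.pvalue)
        method = "wilcoxon-signed-rank/asymptotic"
    return TestResult(statistic=w_plus, p_value=p, method=method,
                      alternative=alternative)


# ---------------------------------------------------------------------------
# ROC machinery
# ---------------------------------------------------------------------------

@dataclass
class RocResult:
    """An empirical ROC curve.

    Thresholds are the midpoints between adjacent distinct pooled scores,
    bracketed by -inf and +inf; at threshold ``t`` sensitivity is the
    fraction of disease-present scores strictly above ``t`` and
    specificity the fraction of disease-absent scores at or below ``t``.
    The AUC is the pairwise-comparison (Mann-Whitney) estimate with ties
    counted 1/2.
    """

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    n_present: int
    n_absent: int
    cutoff: float | None = None
    sens_at_cutoff: float | None = None
    spec_at_cutoff: float | None = None
    accuracy_at_cutoff: float | None = None

    def to_dict(self) -> dict:
        return {"auc": float(self.auc), "cutoff": self.cutoff,
                "sens_at_cutoff": self.sens_at_cutoff,
                "spec_at_cutoff": self.spec_at_cutoff,
                "accuracy_at_cutoff": self.accuracy_at_cutoff,
                "n_present": self.n_present, "n_absent": self.n_absent}


def _pairwise_auc(present: np.ndarray, absent: np.ndarray) -> float:
    """AUC = (#present>absent + 0.5 * #ties) / (n1 * n0), via pooled ranks."""
    n1, n0 = present.size, absent.size
    ranks = sps.rankdata(np.concatenate([present, absent]))
    u = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def roc_curve(scores_present, scores_absent) -> RocResult:
    """Empirical ROC of disease-present vs disease-absent scores."""
    present = np.asarray(scores_present, dtype=float)
    absent = np.asarray(scores_absent, dtype=float)
    if present.size == 0 or absent.size == 0:
        raise ValueError("roc_curve requires nonempty score lists for both classes")
    pooled = np.unique(np.concatenate([present, absent]))
    mids = (pooled[:-1] + pooled[1:]) / 2.0 if pooled.size > 1 else np.empty(0)
    thresholds = np.concatenate([[-np.inf], mids, [np.inf]])
    sens = np.array([(present > t).mean() for t in thresholds])
    spec = np.array([(absent <= t).mean() for t in thresholds])
    return RocResult(thresholds=thresholds, sensitivity=sens, specificity=spec,
                     auc=_pairwise_auc(present, absent),
                     n_present=present.size, n_absent=absent.size)


def select_cutoff(roc: RocResult) -> float:
    """Threshold minimizing the distance to the ROC upper-left corner.

    Minimizes ``sqrt((1-sens)^2 + (1-spec)^2)``; ties are broken toward
    higher specificity, then toward a higher threshold.  The chosen
    operating point is also cached on the RocResult.
    """
    d2 = (1.0 - roc.sensitivity) ** 2 + (1.0 - roc.specificity) ** 2
    best = 0
    for i in range(1, roc.thresholds.size):
        if d2[i] < d2[best] - 1e-15:
            best = i
        elif abs(d2[i] - d2[best]) <= 1e-15:
            if (roc.specificity[i], roc.thresholds[i]) > \
                    (roc.specificity[best], roc.thresholds[best]):
                best = i
    roc.cutoff = float(roc.thresholds[best])
    roc.sens_at_cutoff = float(roc.sensitivity[best])
    roc.spec_at_cutoff = float(roc.specificity[best])
    tp = roc.sens_at_cutoff * roc.n_present
    tn = roc.spec_at_cutoff * roc.n_absent
    roc.accuracy_at_cutoff = float((tp + tn) / (roc.n_present + roc.n_absent))
    return roc.cutoff


# ---------------------------------------------------------------------------
# McNemar
# ---------------------------------------------------------------------------

def mcnemar_test(b: int, c: int) -> TestResult:
    """McNemar's test from the two discordant-pair counts.

    Exact two-sided binomial when ``b + c`` is at most
    :data:`MCNEMAR_EXACT_MAX_DISCORDANT`; otherwise the chi-square
    approximation with continuity correction.  ``b + c = 0`` yields
    p = 1 with a warning.
    """
    if b < 0 or c < 0:
        raise ValueError("discordant counts must be nonnegative")
    n = b + c
    if n == 0:
        warnings.warn("mcnemar_test: no discordant pairs; p = 1")
        return TestResult(statistic=0.0, p_value=1.0, method="mcnemar/degenerate")
    if n <= MCNEMAR_EXACT_MAX_DISCORDANT:
        k = min(b, c)
        p = min(1.0, 2.0 * float(sps.binom.cdf(k, n, 0.5)))
        return TestResult(statistic=float(k), p_value=p, method="mcnemar/exact-binomial")
    stat = (abs(b - c) - 1.0) ** 2 / n
    p = float(sps.chi2.sf(stat, df=1))
    return TestResult(statistic=stat, p_value=p, method="mcnemar/chi2-cc")


# ---------------------------------------------------------------------------
# DeLong paired AUC comparison
# ---------------------------------------------------------------------------

def _placements(scores: np.ndarray, labels: np.ndarray
                ) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC and placement values (V10 per present sample, V01 per absent)."""
    x = scores[labels == 1]
    y = scores[labels == 0]
    m, n = x.size, y.size
    cmp_matrix = (x[:, None] > y[None, :]).astype(float)
    cmp_matrix += 0.5 * (x[:, None] == y[None, :])
    v10 = cmp_matrix.mean(axis=1)
    v01 = cmp_matrix.mean(axis=0)
    return float(v10.mean()), v10, v01


def delong_auc_variance(scores, labels) -> tuple[float, float]:
    """DeLong estimate of a single AUC and its sampling variance."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    auc, v10, v01 = _placements(scores, labels)
    s10 = v10.var(ddof=1) if v10.size > 1 else 0.0
    s01 = v01.var(ddof=1) if v01.size > 1 else 0.0
    return auc, float(s10 / v10.size + s01 / v01.size)


def delong_paired_auc_test(scores_a, scores_b, labels) -> TestResult:
    """DeLong test of the AUC difference between two paired scorers.

    ``labels`` is binary (1 = disease present) and both score vectors are
    evaluated on the same samples.  A zero variance of the difference
    (e.g. identical score vectors) returns p = 1 with a degenerate flag.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels).astype(int)
    if a.shape != b.shape or a.shape != labels.shape:
        raise ValueError("paired scores and labels must have equal length")
    if len(np.unique(labels)) != 2:
        raise ValueError("labels must contain both classes")

    auc_a, v10_a, v01_a = _placements(a, labels)
    auc_b, v10_b, v01_b = _placements(b, labels)
    m, n = v10_a.size, v01_a.size
    s10 = np.cov(np.stack([v10_a, v10_b]), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.stack([v01_a, v01_b]), ddof=1) if n > 1 else np.zeros((2, 2))
    var = ((s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m
           + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n)
    diff = auc_a - auc_b
    if var <= 0:
        return TestResult(statistic=0.0, p_value=1.0, method="delong/degenerate",
                          extra={"auc_a": auc_a, "auc_b": auc_b, "degenerate": True})
    z = diff / np.sqrt(var)
    p = float(2.0 * sps.norm.sf(abs(z)))
    return TestResult(statistic=float(z), p_value=p, method="delong",
                      extra={"auc_a": auc_a, "auc_b": auc_b,
                             "auc_difference": diff, "variance": float(var)})


def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (step-up FDR)."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        rank = m - rank_from_top
        running = min(running, p[idx] * m / rank)
        adj[idx] = running
    return adj
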