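"""Paired nonparametric tests and ROC analysis.

These are the cohort-level primitives: Spearman rank correlation (exact
permutation p for small n, t-approximation otherwise), the Wilcoxon
signed-rank paired test (exact sign-vector enumeration for small
tie-free samples, normal approximation with tie and continuity
corrections otherwise), and empirical ROC analysis with the Youden-index
optimal cutpoint.

Small-sample exactness matters here because the study design pairs each
case's two edema sub-volumes, so n is the case count, not the voxel
count.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

_SPEARMAN_EXACT_MAX_N = 10
_WILCOXON_EXACT_MAX_N = 12


# ---------------------------------------------------------------------------
# Spearman


def _rank(x: np.ndarray) -> np.ndarray:
    return sps.rankdata(x, method="average")


def spearman(x, y) -> tuple[float, float]:
    """Spearman rho and two-sided p.

    rho is the Pearson correlation of mid-ranks (average ranks for ties).
    For n <= 10 the p-value is exact, from full enumeration of the n!
    rank permutations; for larger n the usual t-approximation with n-2
    degrees of freedom is used.  Constant inputs raise ``ValueError``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("rho undefined for a constant input vector")
    rx, ry = _rank(x), _rank(y)
    rxc, ryc = rx - rx.mean(), ry - ry.mean()
    denom = np.sqrt((rxc ** 2).sum() * (ryc ** 2).sum())
    rho = float((rxc * ryc).sum() / denom)

    if n <= _SPEARMAN_EXACT_MAX_N:
        p = _spearman_exact_p(rxc, ryc, denom, abs(rho))
    else:
        t = rho * np.sqrt((n - 2) / max(1.0 - rho ** 2, 1e-300))
        p = float(2.0 * sps.t.sf(abs(t), df=n - 2))
    return rho, min(p, 1.0)


def _spearman_exact_p(rxc, ryc, denom, abs_rho, chunk: int = 40320) -> float:
    """P(|rho_perm| >= |rho_obs|) over all permutations of the y-ranks."""
    n = rxc.size
    count = total = 0
    it = itertools.permutations(range(n))
    while True:
        block = list(itertools.islice(it, chunk))
        if not block:
            break
        P = np.asarray(block)
        rho_p = (ryc[P] * rxc).sum(axis=1) / denom
        count += int((np.abs(rho_p) >= abs_rho - 1e-12).sum())
        total += len(block)
    return count / total


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank, paired


def wilcoxon_paired(a, b) -> tuple[float, float]:
    """Wilcoxon signed-rank test on paired samples.

    Returns ``(W, p)`` where W is the sum of ranks of the positive
    differences ``a - b`` (zero differences dropped, average ranks for
    tied magnitudes).  Exact two-sided p by enumeration of all 2^n sign
    vectors when the number of nonzero differences is <= 12 (valid with
    tied magnitudes too, since signs stay iid under the null conditional
    on the magnitudes); otherwise a normal approximation with tie and
    continuity corrections.  All-zero differences raise ``ValueError``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("a and b must be 1-D vectors of equal length")
    d = a - b
    d = d[d != 0]
    nr = d.size
    if nr == 0:
        raise ValueError("all paired differences are zero; test undefined")
    mag = np.abs(d)
    ranks = _rank(mag)
    w_plus = float(ranks[d > 0].sum())

    if nr <= _WILCOXON_EXACT_MAX_N:
        p = _wilcoxon_exact_p(ranks, w_plus)
    else:
        mean = nr * (nr + 1) / 4.0
        _, tie_counts = np.unique(mag, return_counts=True)
        tie_term = float((tie_counts ** 3 - tie_counts).sum()) / 48.0
        var = nr * (nr + 1) * (2 * nr + 1) / 24.0 - tie_term
        if var <= 0:
            raise ValueError("zero variance in signed-rank statistic")
        # continuity correction toward the mean
        delta = w_plus - mean
        cc = 0.5 * np.sign(delta)
        z = (delta - cc) / np.sqrt(var)
        p = float(2.0 * sps.norm.sf(abs(z)))
    return w_plus, min(p, 1.0)


def _wilcoxon_exact_p(ranks: np.ndarray, w_obs: float) -> float:
    """Two-sided exact p over all 2^n assignments of signs to ranks."""
    n = ranks.size
    signs = np.array(list(itertools.product((0.0, 1.0), repeat=n)))
    dist = signs @ ranks
    lo = float(np.mean(dist <= w_obs + 1e-9))
    hi = float(np.mean(dist >= w_obs - 1e-9))
    return 2.0 * min(lo, hi)


# ---------------------------------------------------------------------------
# ROC


@dataclass
class ROCCurve:
    """Empirical ROC over all distinct score cutpoints.

    ``direction`` is ``"above_positive"`` when larger scores indicate the
    positive class under the fitted orientation (chosen so that the
    training AUC is >= 0.5), ``"below_positive"`` otherwise.  Sensitivity
    and specificity are reported per threshold under that orientation;
    the decision rule at threshold t is ``score >= t`` (above) or
    ``score <= t`` (below).
    """

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    youden_threshold: float
    youden_j: float
    direction: str

    @property
    def youden_sensitivity(self) -> float:
        i = int(np.argmin(np.abs(self.thresholds - self.youden_threshold)))
        return float(self.sensitivity[i])

    @property
    def youden_specificity(self) -> float:
        i = int(np.argmin(np.abs(self.thresholds - self.youden_threshold)))
        return float(self.specificity[i])


def auc_mann_whitney(scores, labels) -> float:
    """Non-oriented AUC = U / (n1 n0): probability that a positive
    outranks a negative, ties counted half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be present")
    r = _rank(scores)
    u = r[labels == 1].sum() - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


def roc_analysis(scores, labels) -> ROCCurve:
    """Empirical ROC with auto-orientation and the Youden cutpoint.

    The AUC equals the Mann-Whitney statistic U/(n1 n0) with tie
    correction.  The Youden threshold maximizes sensitivity +
    specificity - 1 over the observed score values; ties are broken
    toward higher specificity, then toward the more conservative
    (smaller positive-call set) threshold.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be 1-D vectors of equal length")
    if not set(np.unique(labels)) <= {0, 1}:
        raise ValueError("labels must be binary 0/1")
    auc_raw = auc_mann_whitney(scores, labels)
    if auc_raw >= 0.5:
        direction, eff, auc = "above_positive", scores, auc_raw
    else:
        direction, eff, auc = "below_positive", -scores, 1.0 - auc_raw

    thresholds = np.unique(scores)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    sens = np.empty(thresholds.size)
    spec = np.empty(thresholds.size)
    for i, t in enumerate(thresholds):
        pred = scores >= t if direction == "above_positive" else scores <= t
        sens[i] = (pred & (labels == 1)).sum() / n_pos
        spec[i] = (~pred & (labels == 0)).sum() / n_neg

    j = sens + spec - 1.0
    best = np.flatnonzero(j >= j.max() - 1e-12)
    best = best[np.argsort(-spec[best], kind="stable")]
    top_spec = spec[best[0]]
    best = best[spec[best] >= top_spec - 1e-12]
    # most conservative threshold among remaining ties
    if direction == "above_positive":
        pick = best[np.argmax(thresholds[best])]
    else:
        pick = best[np.argmin(thresholds[best])]

    return ROCCurve(
        thresholds=thresholds, sensitivity=sens, specificity=spec,
        auc=float(auc), youden_threshold=float(thresholds[pick]),
        youden_j=float(j[pick]), direction=direction)
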