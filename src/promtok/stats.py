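"""Evaluation statistics: AUC, the DeLong test for correlated ROC curves,
Benjamini-Hochberg FDR, and the Pearson correlation test.

AUC is the Mann-Whitney probability that a random positive outscores a
random negative (ties count one half).  The DeLong test compares two
classifiers scored on the *same* records: per-record placement values
("structural components") yield a covariance estimate for the AUC
difference, and ``z = dAUC / sqrt(var)`` is referred to the standard
normal.  Midranks handle ties, following the original treatment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "AUCComparison",
    "auc",
    "delong_test",
    "delong_comparison",
    "bh_fdr",
    "pearson_test",
]


@dataclass
class AUCComparison:
    """One pairwise DeLong comparison, optionally FDR-adjusted."""

    auc_a: float
    auc_b: float
    var_diff: float
    z: float
    p: float
    p_adj: float | None = None

    def __post_init__(self) -> None:
        for v, name in ((self.auc_a, "auc_a"), (self.auc_b, "auc_b")):
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.var_diff < 0:
            raise ValueError("variance must be non-negative")
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("p outside [0, 1]")


def _check_labels(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels)
    pos = np.flatnonzero(labels == 1)
    neg = np.flatnonzero(labels == 0)
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present")
    return pos, neg


def auc(scores, labels) -> float:
    """Mann-Whitney AUC: mean over (pos, neg) pairs of
    ``[s+ > s-] + 0.5 [s+ == s-]``, computed via midranks."""
    scores = np.asarray(scores, dtype=float)
    pos, neg = _check_labels(labels)
    ranks = sps.rankdata(scores)  # midranks
    n_pos, n_neg = len(pos), len(neg)
    return float(
        (ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    )


def _placements(scores: np.ndarray, pos: np.ndarray, neg: np.ndarray):
    """DeLong structural components via midranks.

    V10[i] = average over negatives of [s+_i > s-_j] (+ half ties);
    V01[j] likewise over positives.
    """
    m, n = len(pos), len(neg)
    all_ranks = sps.rankdata(scores)
    pos_ranks = sps.rankdata(scores[pos])
    neg_ranks = sps.rankdata(scores[neg])
    v10 = (all_ranks[pos] - pos_ranks) / n
    v01 = 1.0 - (all_ranks[neg] - neg_ranks) / m
    return v10, v01


def _delong_core(scores_a, scores_b, labels):
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    if scores_a.shape != scores_b.shape:
        raise ValueError("score vectors must cover the same records")
    pos, neg = _check_labels(labels)
    m, n = len(pos), len(neg)
    v10_a, v01_a = _placements(scores_a, pos, neg)
    v10_b, v01_b = _placements(scores_b, pos, neg)
    auc_a = float(v10_a.mean())
    auc_b = float(v10_b.mean())
    # covariance of (auc_a, auc_b) from the structural components
    s10 = np.cov(np.stack([v10_a, v10_b]), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.stack([v01_a, v01_b]), ddof=1) if n > 1 else np.zeros((2, 2))
    cov = s10 / m + s01 / n
    var = float(cov[0, 0] + cov[1, 1] - 2.0 * cov[0, 1])
    d = auc_a - auc_b
    if var <= 0:
        if abs(d) < 1e-12:
            return auc_a, auc_b, 0.0, 0.0, 1.0
        import warnings

        warnings.warn(
            "zero DeLong variance with a nonzero AUC difference; reporting p=0",
            RuntimeWarning,
            stacklevel=3,
        )
        return auc_a, auc_b, 0.0, float(np.sign(d) * np.inf), 0.0
    z = float(d / np.sqrt(var))
    p = float(min(2.0 * sps.norm.sf(abs(z)), 1.0))
    return auc_a, auc_b, var, z, p


def delong_test(scores_a, scores_b, labels) -> tuple[float, float]:
    """Two-sided DeLong test for the AUC difference of two correlated
    classifiers evaluated on the same records.

    Returns ``(z, p)``.  A degenerate zero-variance case returns ``(0, 1)``
    when the AUCs are equal, and ``(inf sign, 0)`` with a warning otherwise.
    """
    _, _, _, z, p = _delong_core(scores_a, scores_b, labels)
    return z, p


def delong_comparison(scores_a, scores_b, labels) -> AUCComparison:
    """Convenience wrapper returning the full :class:`AUCComparison`."""
    auc_a, auc_b, var, z, p = _delong_core(scores_a, scores_b, labels)
    return AUCComparison(auc_a, auc_b, var, z, p)


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, order-preserving with input."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise ValueError("pvalues must be a non-empty 1-d array")
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, p_adj, _, _ = multipletests(p, method="fdr_bh")
    return p_adj


def pearson_test(x, y) -> tuple[float, float]:
    """Sample Pearson r with the two-sided t-test p-value (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d and equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for constant input")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)
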