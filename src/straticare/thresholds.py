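"""ROC analysis of the prognostic scores and cut-off policies.

A prediction is *positive* (predicted RCSI) when the probability score
is at or above the threshold.  The ROC curve enumerates every distinct
score as a candidate threshold; its AUC equals the Mann-Whitney
concordance probability (ties count one half).  The 95% confidence
interval for the AUC uses the DeLong variance estimator, with a
bootstrap percentile interval available as an alternative.

Two cut-off policies mirror common deployment choices: the ROC-optimal
(Youden-style) threshold maximising sensitivity + specificity, with ties
broken toward the higher threshold (higher specificity), and the fixed
0.5 threshold typical of logistic-regression classification.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RocCurve",
    "CutoffPolicy",
    "roc_curve",
    "auc_confidence_interval",
    "auc_bootstrap_ci",
    "youden_cutoff",
    "fixed_cutoff",
    "predict_rcsi",
]


@dataclass
class RocCurve:
    """Sensitivity/specificity at every distinct score threshold
    (thresholds ascending; positive prediction means score >= threshold)."""

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    auc_ci: tuple[float, float]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "threshold": self.thresholds,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
        })


@dataclass(frozen=True)
class CutoffPolicy:
    """A deployable threshold on the prognostic score."""

    kind: str  # "roc_optimal" or "fixed"
    threshold: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.threshold):
            raise ValueError("threshold must be finite")


def _validate(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-d sequences")
    if not (np.any(y == 1) and np.any(y == 0)):
        raise ValueError("labels must contain both classes (AUC undefined otherwise)")
    return s, y


def _mann_whitney_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """P(score of random positive > score of random negative) + 1/2 ties."""
    ranks = stats.rankdata(scores)  # midranks
    m = int(labels.sum())
    n = len(labels) - m
    return float((ranks[labels == 1].sum() - m * (m + 1) / 2) / (m * n))


def roc_curve(scores, labels) -> RocCurve:
    """ROC coordinates over all distinct score thresholds, with AUC and
    its 95% DeLong interval."""
    s, y = _validate(scores, labels)
    thr = np.unique(s)  # ascending
    # counts of positives/negatives at score >= t via suffix sums
    order = np.argsort(s, kind="mergesort")
    s_sorted, y_sorted = s[order], y[order]
    first_idx = np.searchsorted(s_sorted, thr, side="left")
    pos_cum = np.concatenate([np.cumsum(y_sorted[::-1])[::-1], [0]])
    neg_cum = np.concatenate([np.cumsum((1 - y_sorted)[::-1])[::-1], [0]])
    tp = pos_cum[first_idx]
    fp = neg_cum[first_idx]
    m = int(y.sum())
    n = len(y) - m
    sens = tp / m
    spec = (n - fp) / n
    auc = _mann_whitney_auc(s, y)
    ci = auc_confidence_interval(s, y)
    return RocCurve(thresholds=thr, sensitivity=sens, specificity=spec,
                    auc=auc, auc_ci=ci)


# ---------------------------------------------------------------------------
# DeLong variance


def _delong_components(scores: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    tx = stats.rankdata(pos)
    ty = stats.rankdata(neg)
    tz = stats.rankdata(np.concatenate([pos, neg]))
    auc = (tz[:m].sum() - m * (m + 1) / 2) / (m * n)
    v01 = (tz[:m] - tx) / n            # structural components of positives
    v10 = 1.0 - (tz[m:] - ty) / m      # structural components of negatives
    var = (np.var(v01, ddof=1) / m if m > 1 else 0.0) + \
          (np.var(v10, ddof=1) / n if n > 1 else 0.0)
    return float(auc), float(var)


def auc_confidence_interval(scores, labels, level: float = 0.95) -> tuple[float, float]:
    """DeLong 95% (by default) confidence interval for the AUC, clipped
    to [0, 1].  Degenerate single-class inputs raise."""
    s, y = _validate(scores, labels)
    auc, var = _delong_components(s, y)
    z = stats.norm.ppf(0.5 + level / 2)
    half = z * np.sqrt(var)
    return (float(max(0.0, auc - half)), float(min(1.0, auc + half)))


def auc_bootstrap_ci(scores, labels, level: float = 0.95, n_boot: int = 2000,
                     seed: int = 0) -> tuple[float, float]:
    """Percentile bootstrap interval (resampling clients); slower but
    assumption-free alternative to the DeLong interval."""
    s, y = _validate(scores, labels)
    rng = np.random.default_rng(seed)
    n = len(s)
    aucs = []
    while len(aucs) < n_boot:
        idx = rng.integers(0, n, n)
        yb = y[idx]
        if yb.min() == yb.max():
            continue  # single-class resample: AUC undefined, redraw
        aucs.append(_mann_whitney_auc(s[idx], yb))
    lo, hi = np.quantile(aucs, [(1 - level) / 2, 0.5 + level / 2])
    return float(lo), float(hi)


# ---------------------------------------------------------------------------
# Cut-off policies


def youden_cutoff(curve: RocCurve) -> CutoffPolicy:
    """Threshold maximising sensitivity + specificity; ties break toward
    the higher threshold, i.e. the more specific rule."""
    j = curve.sensitivity + curve.specificity
    best = np.flatnonzero(j == j.max()).max()  # thresholds ascend
    return CutoffPolicy(kind="roc_optimal", threshold=float(curve.thresholds[best]))


def fixed_cutoff(threshold: float = 0.5) -> CutoffPolicy:
    return CutoffPolicy(kind="fixed", threshold=threshold)


def predict_rcsi(scores, policy: CutoffPolicy) -> np.ndarray:
    """1 where score >= policy threshold, else 0 (vectorised)."""
    return (np.asarray(scores, dtype=float) >= policy.threshold).astype(int)
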