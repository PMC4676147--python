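"""Probe-level detection metrics for recurrent and individual-specific CNVs.

Detection is scored cellwise against the simulation ground truth over a
decreasing grid of cutoffs: a probe-cell is predicted positive when its
score exceeds the cutoff (|x_hat| for recurrent CNVs, 1 - w_hat for
individual ones), and truly positive when the corresponding truth entry is
nonzero, gains and losses pooled.  TPR = TP/P, FPR = FP/N and
FDR = FP/(TP+FP) with the empty-discovery case 0/0 defined as 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ROCCurve",
    "default_cutoffs",
    "CALL_THRESHOLD",
    "recurrent_roc",
    "individual_roc",
    "auc",
    "call_cnvs",
]

#: calling rule used for real data: a CNV is claimed where |x_hat| > 0.225
CALL_THRESHOLD = 0.225


@dataclass
class ROCCurve:
    """TPR/FPR/FDR arrays over a decreasing cutoff grid."""

    cutoffs: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    fdr: np.ndarray

    def __post_init__(self):
        for name in ("cutoffs", "tpr", "fpr", "fdr"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=np.float64))
        k = len(self.cutoffs)
        if not (len(self.tpr) == len(self.fpr) == len(self.fdr) == k):
            raise ValueError("curve arrays must share one length")


def default_cutoffs(scores: np.ndarray, n_points: int = 101) -> np.ndarray:
    """Decreasing grid from max|score| towards 0 (exclusive), plus 0.225.

    The calling-rule cutoff is always included so the calling operating
    point sits exactly on the curve.
    """
    top = float(np.max(scores)) if scores.size else 1.0
    if top <= 0:
        top = 1.0
    grid = np.linspace(top, 0.0, n_points + 1)[:-1]  # exclude 0 itself
    grid = np.union1d(grid, [CALL_THRESHOLD])
    return np.sort(grid)[::-1]


def _roc_from_scores(scores: np.ndarray, truth_pos: np.ndarray, cutoffs) -> ROCCurve:
    if scores.shape != truth_pos.shape:
        raise ValueError("score and truth shapes disagree")
    P = int(truth_pos.sum())
    N = truth_pos.size - P
    if P == 0:
        raise ValueError("no positives in truth; TPR is undefined")
    if cutoffs is None:
        cutoffs = default_cutoffs(scores)
    cutoffs = np.asarray(cutoffs, dtype=np.float64)
    if np.any(cutoffs <= 0):
        raise ValueError("cutoffs must be positive")
    cutoffs = np.sort(cutoffs)[::-1]
    s = scores.ravel()
    t = truth_pos.ravel()
    tpr = np.empty(len(cutoffs))
    fpr = np.empty(len(cutoffs))
    fdr = np.empty(len(cutoffs))
    for k, c in enumerate(cutoffs):
        pred = s > c
        tp = int(np.sum(pred & t))
        fp = int(np.sum(pred & ~t))
        tpr[k] = tp / P
        fpr[k] = fp / N if N else 0.0
        fdr[k] = fp / (tp + fp) if (tp + fp) else 0.0
    return ROCCurve(cutoffs=cutoffs, tpr=tpr, fpr=fpr, fdr=fdr)


def recurrent_roc(X_hat: np.ndarray, X_true: np.ndarray, cutoffs=None) -> ROCCurve:
    """ROC/FDR for recurrent-CNV detection: score |x_hat| vs truth x_true != 0."""
    X_hat = np.asarray(X_hat, dtype=np.float64)
    X_true = np.asarray(X_true)
    return _roc_from_scores(np.abs(X_hat), X_true != 0, cutoffs)


def individual_roc(W_hat: np.ndarray, E_true: np.ndarray, cutoffs=None) -> ROCCurve:
    """ROC/FDR for individual-CNV detection: score 1 - w_hat vs truth e_true != 0."""
    W_hat = np.asarray(W_hat, dtype=np.float64)
    E_true = np.asarray(E_true)
    return _roc_from_scores(1.0 - W_hat, E_true != 0, cutoffs)


def auc(curve: ROCCurve) -> float:
    """Trapezoidal area under the ROC curve, closed at (0,0) and (1,1)."""
    fpr = np.concatenate([[0.0], curve.fpr, [1.0]])
    tpr = np.concatenate([[0.0], curve.tpr, [1.0]])
    order = np.argsort(fpr, kind="stable")
    return float(np.trapezoid(tpr[order], fpr[order]))


def call_cnvs(X_hat: np.ndarray, threshold: float = CALL_THRESHOLD):
    """Apply the calling rule |x_hat| > threshold (strict).

    Returns ``(calls, gain_frequency, loss_frequency)`` where calls take
    values in {-1, 0, +1} and the frequencies are per-probe fractions of
    samples called.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    X_hat = np.asarray(X_hat, dtype=np.float64)
    calls = (np.sign(X_hat) * (np.abs(X_hat) > threshold)).astype(int)
    gain = (calls == 1).mean(axis=0)
    loss = (calls == -1).mean(axis=0)
    return calls, gain, loss
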