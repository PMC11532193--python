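"""Replicate-level and discovery-level evaluation metrics.

``summarize_replicates`` condenses an N-replicate Monte-Carlo batch into the
standard calibration summaries: Bias, SEE (empirical SD of the estimates),
SEM (mean of the estimated SEs), MSE, CP (CI coverage of the truth) and the
rejection rate (type I error when the true coefficient is zero, power
otherwise).  ``confusion_metrics`` turns TP/FP/TN/FN counts into FDR, TPR,
F1 and MCC for multi-taxon discovery experiments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ReplicateBatch",
    "ConfusionCounts",
    "summarize_replicates",
    "confusion_metrics",
]


@dataclass
class ReplicateBatch:
    """Estimates, SEs, CIs and test decisions across N replicates.

    All arrays have shape (N, p); ``truth`` has shape (p,) and holds the
    generating parameter values.
    """

    estimates: np.ndarray
    ses: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    rejected: np.ndarray
    truth: np.ndarray

    def __post_init__(self) -> None:
        self.estimates = np.atleast_2d(np.asarray(self.estimates, dtype=float))
        self.ses = np.atleast_2d(np.asarray(self.ses, dtype=float))
        self.ci_lower = np.atleast_2d(np.asarray(self.ci_lower, dtype=float))
        self.ci_upper = np.atleast_2d(np.asarray(self.ci_upper, dtype=float))
        self.rejected = np.atleast_2d(np.asarray(self.rejected, dtype=bool))
        self.truth = np.atleast_1d(np.asarray(self.truth, dtype=float))
        shape = self.estimates.shape
        for name in ("ses", "ci_lower", "ci_upper", "rejected"):
            if getattr(self, name).shape != shape:
                raise ValueError(f"{name} shape {getattr(self, name).shape} != {shape}")
        if self.truth.shape != (shape[1],):
            raise ValueError("truth must have length p")

    @property
    def n_reps(self) -> int:
        return self.estimates.shape[0]


def summarize_replicates(batch: ReplicateBatch) -> list[dict]:
    """Per-parameter calibration summary of a replicate batch.

    Returns one record per parameter with keys ``bias``, ``see``, ``sem``,
    ``mse``, ``cp`` and ``rejection_rate``.  SEE uses the N-1 denominator;
    MSE the 1/N denominator, so MSE = bias^2 + SEE^2 (N-1)/N identically.
    """
    N = batch.n_reps
    if N < 2:
        raise ValueError("SEE is undefined for fewer than 2 replicates")
    out = []
    for j, omega in enumerate(batch.truth):
        est = batch.estimates[:, j]
        covers = (batch.ci_lower[:, j] <= omega) & (omega <= batch.ci_upper[:, j])
        out.append(
            {
                "bias": float(est.mean() - omega),
                "see": float(est.std(ddof=1)),
                "sem": float(batch.ses[:, j].mean()),
                "mse": float(np.mean((est - omega) ** 2)),
                "cp": float(covers.mean()),
                "rejection_rate": float(batch.rejected[:, j].mean()),
            }
        )
    return out


@dataclass
class ConfusionCounts:
    """Discovery confusion counts for one multi-taxon experiment."""

    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self) -> None:
        for name in ("TP", "FP", "TN", "FN"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"{name} must be a non-negative integer")

    @classmethod
    def from_calls(cls, called: np.ndarray, truth: np.ndarray) -> "ConfusionCounts":
        called = np.asarray(called, dtype=bool)
        truth = np.asarray(truth, dtype=bool)
        return cls(
            TP=int(np.sum(called & truth)),
            FP=int(np.sum(called & ~truth)),
            TN=int(np.sum(~called & ~truth)),
            FN=int(np.sum(~called & truth)),
        )


def confusion_metrics(counts: ConfusionCounts) -> dict:
    """FDR, TPR, F1 and MCC from confusion counts.

    Degenerate conventions: FDR = 0 when there are no discoveries
    (TP + FP = 0); F1 = 0 when precision + recall = 0; MCC = 0 when any
    marginal total is zero.
    """
    tp, fp, tn, fn = counts.TP, counts.FP, counts.TN, counts.FN
    fdr = fp / (fp + tp) if (fp + tp) > 0 else 0.0
    tpr = tp / (fn + tp) if (fn + tp) > 0 else 0.0
    precision = tp / (tp + fp) if (tp + fp) > 0 else 0.0
    f1 = (
        2 * precision * tpr / (precision + tpr) if (precision + tpr) > 0 else 0.0
    )
    denom = math.sqrt(
        float(tp + fp) * float(tp + fn) * float(tn + fp) * float(tn + fn)
    )
    mcc = (tp * tn - fp * fn) / denom if denom > 0 else 0.0
    return {"fdr": float(fdr), "tpr": float(tpr), "f1": float(f1), "mcc": float(mcc)}
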