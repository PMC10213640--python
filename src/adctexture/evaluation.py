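"""ROC construction, AUC and operating-point metrics.

AUC is computed by the rank (Mann-Whitney) formulation with midrank ties,
which equals the trapezoidal area under the empirical ROC curve; the
operating point defaults to the threshold maximizing Youden's J
(sensitivity + specificity - 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata
from sklearn.metrics import roc_curve

from .errors import ConfigurationError, InputError

__all__ = ["ROCResult", "OperatingPoint", "roc_auc", "operating_metrics"]


@dataclass
class OperatingPoint:
    threshold: float
    accuracy: float
    sensitivity: float
    specificity: float


@dataclass
class ROCResult:
    """Empirical ROC curve with rank-based AUC.

    ``thresholds[k]`` classifies ``score >= thresholds[k]`` as positive;
    FPR and TPR are non-decreasing along the arrays.
    """

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    scores: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        if not 0.0 <= self.auc <= 1.0:
            raise ValueError("AUC outside [0, 1]")


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> ROCResult:
    """Empirical ROC and AUC for binary labels (1 = unfavorable outcome).

    AUC = (U statistic of positive scores) / (n_pos * n_neg) with midranks,
    i.e. the probability that a random positive outranks a random negative
    (ties counted half).
    """
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels).astype(int).ravel()
    if scores.size != labels.size:
        raise InputError("scores and labels must have equal length")
    if not np.all(np.isfinite(scores)):
        raise InputError("scores must be finite")
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ConfigurationError("both classes must be present")
    ranks = rankdata(scores)
    auc = (ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    fpr, tpr, thr = roc_curve(labels, scores, drop_intermediate=False)
    return ROCResult(
        thresholds=thr, fpr=fpr, tpr=tpr, auc=float(auc), scores=scores, labels=labels
    )


def operating_metrics(
    roc: ROCResult, rule: str = "youden", fixed_threshold: float | None = None
) -> OperatingPoint:
    """Accuracy/sensitivity/specificity at a chosen ROC operating point.

    ``rule="youden"`` picks the threshold maximizing sensitivity +
    specificity - 1 (ties broken toward the first, most conservative,
    threshold); ``rule="fixed_threshold"`` evaluates ``score >=
    fixed_threshold`` directly.
    """
    labels, scores = roc.labels, roc.scores
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if rule == "youden":
        j = roc.tpr - roc.fpr
        k = int(np.argmax(j))
        threshold = float(roc.thresholds[k])
    elif rule == "fixed_threshold":
        if fixed_threshold is None:
            raise ConfigurationError("fixed_threshold rule requires a threshold")
        threshold = float(fixed_threshold)
    else:
        raise ConfigurationError(f"unknown operating rule {rule!r}")
    pred = scores >= threshold
    tp = int((pred & (labels == 1)).sum())
    tn = int((~pred & (labels == 0)).sum())
    return OperatingPoint(
        threshold=threshold,
        accuracy=(tp + tn) / labels.size,
        sensitivity=tp / n_pos,
        specificity=tn / n_neg,
    )
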