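"""Binary-classifier evaluation: confusion metrics, MCC, ROC/AUC, AUC tests.

Threshold-dependent metrics follow the usual definitions on the confusion
counts (sensitivity TP/PS, specificity TN/NS, accuracy, MCC); MCC is the
standard product-moment form, with the algebraically equivalent
"PS/NS" form (numerator 1 - FN/PS - FP/NS over a square-root of marginal
ratios, common in the peptide-prediction literature) provided as a
cross-check. AUC is computed by the rank (Mann-Whitney) formulation with
ties contributing one half, which equals the trapezoidal area under the
empirical ROC step curve.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.metrics import roc_curve as _sk_roc_curve

from .exceptions import ParameterError


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/FN/TN/FP counts; PS = TP+FN positives, NS = TN+FP negatives."""

    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self):
        for name in ("tp", "fn", "tn", "fp"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be non-negative")

    @property
    def ps(self) -> int:
        return self.tp + self.fn

    @property
    def ns(self) -> int:
        return self.tn + self.fp


@dataclass(frozen=True)
class MetricsReport:
    """The five headline metrics of a binary classifier."""

    sensitivity: float
    specificity: float
    accuracy: float
    mcc: float
    auc: float


@dataclass
class ROCCurve:
    """ROC step curve: thresholds descending, matched FPR/TPR arrays."""

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray


def confusion(labels, calls) -> ConfusionCounts:
    """Exact confusion counts from binary labels and binary calls."""
    labels = np.asarray(labels, dtype=int)
    calls = np.asarray(calls, dtype=int)
    if labels.shape != calls.shape or labels.size == 0:
        raise ParameterError("labels and calls must be equal-length, non-empty")
    return ConfusionCounts(
        tp=int(np.sum((labels == 1) & (calls == 1))),
        fn=int(np.sum((labels == 1) & (calls == 0))),
        tn=int(np.sum((labels == 0) & (calls == 0))),
        fp=int(np.sum((labels == 0) & (calls == 1))),
    )


def threshold_metrics(c: ConfusionCounts) -> tuple[float, float, float, float]:
    """(sensitivity, specificity, accuracy, MCC) from confusion counts.

    MCC uses the standard product-moment formula and is defined as 0 when
    any marginal count is zero.
    """
    if c.ps < 1 or c.ns < 1:
        raise ParameterError("metrics require at least one positive and one negative")
    sens = c.tp / c.ps
    spec = c.tn / c.ns
    acc = (c.tp + c.tn) / (c.ps + c.ns)
    denom = (
        (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    )
    mcc = 0.0 if denom == 0 else (c.tp * c.tn - c.fp * c.fn) / math.sqrt(denom)
    return sens, spec, acc, mcc


def mcc_chou_form(c: ConfusionCounts) -> float:
    """MCC via the PS/NS parameterization (radical restored); oracle only.

    MCC = (1 - FN/PS - FP/NS) / sqrt((1 + (FP-FN)/PS) (1 + (FN-FP)/NS)).
    Algebraically identical to the product-moment MCC; kept as an
    independent cross-check, not used for reporting. Returns 0 when a
    marginal is zero, matching :func:`threshold_metrics`.
    """
    if c.ps < 1 or c.ns < 1:
        raise ParameterError("MCC requires at least one positive and one negative")
    num = 1.0 - (c.fn / c.ps + c.fp / c.ns)
    d1 = 1.0 + (c.fp - c.fn) / c.ps
    d2 = 1.0 + (c.fn - c.fp) / c.ns
    if d1 <= 0 or d2 <= 0 or d1 * d2 == 0:
        return 0.0
    return num / math.sqrt(d1 * d2)


def roc_auc(scores, labels) -> tuple[ROCCurve, float]:
    """ROC curve and AUC (rank/Mann-Whitney formulation, ties count half)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise ParameterError("scores and labels length mismatch")
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == 0))
    if n_pos == 0 or n_neg == 0:
        raise ParameterError("AUC requires both classes present")
    ranks = stats.rankdata(scores)  # midranks: ties contribute 1/2
    auc = (ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    fpr, tpr, thresholds = _sk_roc_curve(labels, scores)
    return ROCCurve(thresholds=thresholds, fpr=fpr, tpr=tpr), float(auc)


def compare_auc(aucs_a, aucs_b) -> tuple[float, float, float]:
    """Welch two-sample t-test on per-repeat AUC samples.

    Returns (t statistic, Welch degrees of freedom, two-tailed p). Identical
    samples give t = 0, p = 1; two zero-variance samples with different
    means are degenerate and raise with advice to add repeats.
    """
    a = np.asarray(aucs_a, dtype=float)
    b = np.asarray(aucs_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ParameterError("need at least 2 AUC values per sample")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            return 0.0, float(a.size + b.size - 2), 1.0
        raise ParameterError(
            "both AUC samples have zero variance with different means; "
            "add repeats or jitter to obtain a defined test"
        )
    res = stats.ttest_ind(a, b, equal_var=False)
    sa, sb = va / a.size, vb / b.size
    df = (sa + sb) ** 2 / (sa**2 / (a.size - 1) + sb**2 / (b.size - 1))
    return float(res.statistic), float(df), float(res.pvalue)


def evaluate_model(bundle, dataset) -> MetricsReport:
    """Full metric report of a model bundle on a labeled dataset.

    Warns (but proceeds) when the evaluation data fingerprint matches the
    bundle's training fingerprint — evaluating on training data is the
    classic leakage mistake.
    """
    from .features import encode_dataset  # local import avoids a cycle
    from .modeling import fingerprint_matrix
    from .selection import FeatureSet, subset_matrix

    if not dataset.is_labeled():
        raise ParameterError("evaluation requires a fully labeled dataset")
    labels = np.asarray(dataset.labels, dtype=int)
    matrix = encode_dataset(dataset, bundle.encoder)
    sub = subset_matrix(
        matrix, FeatureSet(cutoff=0.0, feature_names=bundle.feature_names)
    )
    if bundle.training_fingerprint and (
        fingerprint_matrix(sub) == bundle.training_fingerprint
    ):
        warnings.warn("evaluation dataset equals the training data (leakage)")
    probs = bundle.predict_proba(matrix)
    calls = (probs >= bundle.probability_cutoff).astype(int)
    sens, spec, acc, mcc = threshold_metrics(confusion(labels, calls))
    _, auc = roc_auc(probs, labels)
    return MetricsReport(sens, spec, acc, mcc, auc)
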