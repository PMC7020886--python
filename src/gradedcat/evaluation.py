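"""Validity battery: marginal reliability, criterion correlations, ROC/AUC.

AUC uses the Mann-Whitney formulation (ties get half weight); the ROC
curve itself is delegated to scikit-learn and its trapezoidal area agrees
with the Mann-Whitney value, which gives two independent routes to the
same number.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata
from sklearn.metrics import roc_curve as _sk_roc_curve

__all__ = [
    "EvaluationSummary",
    "ROCResult",
    "marginal_reliability",
    "auc",
    "roc_curve",
    "criterion_report",
    "plot_rule_profile",
    "plot_roc",
]


@dataclass(frozen=True)
class EvaluationSummary:
    rule: str
    mean_items: float
    mean_se: float
    marginal_reliability: float
    corr_with_full: float
    corr_with_criterion: float
    auc: float


@dataclass(frozen=True)
class ROCResult:
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float


def marginal_reliability(eaps, ses, form: str = "empirical") -> float:
    """Single-number reliability of a vector of trait estimates.

    ``empirical`` (default): ``var(eap) / (var(eap) + mean(se^2))``;
    ``population``: ``1 - mean(se^2)`` (prior variance fixed at 1).
    """
    eaps = np.asarray(eaps, dtype=float)
    ses = np.asarray(ses, dtype=float)
    if eaps.shape != ses.shape:
        raise ValueError("eaps and ses must align")
    if np.any(ses <= 0):
        raise ValueError("ses must be > 0")
    err = float(np.mean(ses**2))
    if form == "population":
        return 1.0 - err
    v = float(np.var(eaps, ddof=1)) if len(eaps) > 1 else 0.0
    if v == 0.0:
        warnings.warn("zero variance in trait estimates; reliability is 0", stacklevel=2)
        return 0.0
    return v / (v + err)


def _check_labels(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels).astype(bool)
    if labels.all() or not labels.any():
        raise ValueError("both classes must be present")
    return labels


def auc(scores, labels) -> float:
    """Mann-Whitney AUC: P(score_pos > score_neg) + 0.5 P(tie)."""
    scores = np.asarray(scores, dtype=float)
    labels = _check_labels(labels)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must align")
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    ranks = rankdata(scores)  # midranks handle ties with half weight
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def roc_curve(scores, labels) -> ROCResult:
    """ROC over all distinct score thresholds, trapezoidal AUC."""
    scores = np.asarray(scores, dtype=float)
    labels = _check_labels(labels)
    fpr, tpr, _ = _sk_roc_curve(labels.astype(int), scores, drop_intermediate=False)
    area = float(np.trapezoid(tpr, fpr))
    return ROCResult(sensitivity=tpr, specificity=1.0 - fpr, auc=area)


def criterion_report(
    cohort_results: dict,
    criterion_sum,
    high_label,
) -> list[EvaluationSummary]:
    """Per-rule external-validity summary against a criterion total score
    and its high/low dichotomization."""
    criterion_sum = np.asarray(criterion_sum, dtype=float)
    high_label = np.asarray(high_label).astype(bool)
    out = []
    for name, res in cohort_results.items():
        if len(res.eaps) != len(criterion_sum) or len(res.eaps) != len(high_label):
            raise ValueError("cohort results and criterion vectors must align")
        r = float(np.corrcoef(res.eaps, criterion_sum)[0, 1])
        out.append(
            EvaluationSummary(
                rule=name,
                mean_items=res.mean_items,
                mean_se=res.mean_se,
                marginal_reliability=res.marginal_reliability,
                corr_with_full=res.corr_with_full,
                corr_with_criterion=r,
                auc=auc(res.eaps, high_label),
            )
        )
    return out


def plot_rule_profile(eaps, ses, n_items, ax=None):
    """Items used and per-person reliability (1 - se^2) against the trait
    estimate, one marker per respondent."""
    import matplotlib.pyplot as plt

    eaps = np.asarray(eaps, dtype=float)
    ses = np.asarray(ses, dtype=float)
    if ax is None:
        _, ax = plt.subplots()
    ax.plot(eaps, np.asarray(n_items, dtype=float), ".", label="items used")
    ax2 = ax.twinx()
    ax2.plot(eaps, 1.0 - ses**2, "^", color="tab:orange", ms=3, label="reliability")
    ax.set_xlabel("trait estimate")
    ax.set_ylabel("number of items")
    ax2.set_ylabel("reliability")
    return ax


def plot_roc(roc: ROCResult, ax=None):
    """ROC curve (sensitivity vs 1 - specificity) with the chance diagonal."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(1.0 - roc.specificity, roc.sensitivity, label=f"AUC = {roc.auc:.3f}")
    ax.plot([0, 1], [0, 1], "--", color="grey", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend()
    return ax
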