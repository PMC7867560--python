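"""Diagnostic-accuracy statistics for the stone-vs-phlebolith study design.

Stone is the positive class throughout: sensitivity is the stone detection
rate, specificity the phlebolith detection rate.  Confidence intervals are
exact binomial (Clopper-Pearson) by default; ROC/AUC uses trapezoidal
integration with half-credit ties, which equals the Mann-Whitney
concordance probability.  Reader-panel helpers implement the majority vote
(>= 4 of 7) and median-reader summaries, plus the one-sample t-test and
Mann-Whitney U used to compare methods.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.metrics import roc_curve
from statsmodels.stats.proportion import proportion_confint

from .core import PHLEBOLITH, STONE, CalcnetError, normalize_label

_CI_METHODS = {"clopper_pearson": "beta", "wilson": "wilson", "normal": "normal"}


@dataclass
class ConfusionMatrix:
    """2x2 counts with stone as the positive class."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise CalcnetError("confusion-matrix counts must be >= 0")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    @property
    def n_positive(self) -> int:
        return self.tp + self.fn

    @property
    def n_negative(self) -> int:
        return self.fp + self.tn


@dataclass
class MetricsReport:
    """Point estimates with binomial CIs; NaN flags an undefined metric."""

    sensitivity: float
    specificity: float
    accuracy: float
    sensitivity_ci: tuple[float, float]
    specificity_ci: tuple[float, float]
    accuracy_ci: tuple[float, float]
    n: int
    ci_method: str = "clopper_pearson"
    level: float = 0.95

    def as_dict(self) -> dict:
        return {
            "sensitivity": self.sensitivity, "specificity": self.specificity,
            "accuracy": self.accuracy,
            "sensitivity_ci": list(self.sensitivity_ci),
            "specificity_ci": list(self.specificity_ci),
            "accuracy_ci": list(self.accuracy_ci),
            "n": self.n, "ci_method": self.ci_method, "level": self.level,
        }


def _as_binary(labels) -> np.ndarray:
    out = np.empty(len(labels), dtype=np.int8)
    for i, lab in enumerate(labels):
        if isinstance(lab, str):
            out[i] = 1 if normalize_label(lab) == STONE else 0
        else:
            out[i] = 1 if int(lab) == 1 else 0
    return out


def confusion(predicted, truth) -> ConfusionMatrix:
    """Tally predictions against the reference standard (stone positive)."""
    if len(predicted) != len(truth):
        raise CalcnetError(
            f"length mismatch: {len(predicted)} predictions vs {len(truth)} truths")
    p = _as_binary(predicted)
    t = _as_binary(truth)
    return ConfusionMatrix(
        tp=int(((p == 1) & (t == 1)).sum()),
        fn=int(((p == 0) & (t == 1)).sum()),
        fp=int(((p == 1) & (t == 0)).sum()),
        tn=int(((p == 0) & (t == 0)).sum()),
    )


def _proportion_with_ci(k: int, n: int, method: str, level: float
                        ) -> tuple[float, tuple[float, float]]:
    if n == 0:
        return float("nan"), (float("nan"), float("nan"))
    lo, hi = proportion_confint(k, n, alpha=1 - level, method=method)
    return k / n, (float(lo), float(hi))


def metrics(cm: ConfusionMatrix, ci_method: str = "clopper_pearson",
            level: float = 0.95) -> MetricsReport:
    """Sensitivity, specificity and accuracy with binomial CIs.

    A zero row total (no positives or no negatives in the sample) yields
    NaN for the affected metric rather than an error.
    """
    if ci_method not in _CI_METHODS:
        raise CalcnetError(
            f"unknown ci_method {ci_method!r}; expected {sorted(_CI_METHODS)}")
    sm = _CI_METHODS[ci_method]
    sens, sens_ci = _proportion_with_ci(cm.tp, cm.n_positive, sm, level)
    spec, spec_ci = _proportion_with_ci(cm.tn, cm.n_negative, sm, level)
    acc, acc_ci = _proportion_with_ci(cm.tp + cm.tn, cm.total, sm, level)
    return MetricsReport(sens, spec, acc, sens_ci, spec_ci, acc_ci,
                         n=cm.total, ci_method=ci_method, level=level)


def roc_auc(scores, truth) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC by trapezoidal integration over all thresholds, plus the curve.

    Ties receive half credit, so the AUC equals the Mann-Whitney
    concordance probability P(score_stone > score_phlebolith) +
    0.5 P(equal).  Returns (auc, fpr, tpr).
    """
    t = _as_binary(truth)
    s = np.asarray(scores, dtype=float)
    if len(s) != len(t):
        raise CalcnetError("scores and truth must have equal length")
    if t.min() == t.max():
        raise CalcnetError("ROC needs both classes present")
    fpr, tpr, _ = roc_curve(t, s)
    auc = float(np.trapezoid(tpr, fpr))
    return auc, fpr, tpr


def majority_vote(calls: np.ndarray) -> list[str]:
    """Panel decision per calcification: the class chosen by >= (r+1)/2 readers.

    `calls` is (n_calcifications, n_readers) of labels or binary values;
    the reader count must be odd (no tie rule exists for even panels).
    """
    calls = np.asarray(calls)
    if calls.ndim != 2:
        raise CalcnetError("calls must be 2-D (calcifications x readers)")
    n_readers = calls.shape[1]
    if n_readers % 2 == 0:
        raise CalcnetError(
            f"majority vote needs an odd reader count, got {n_readers}")
    out = []
    for row in calls:
        votes = int(_as_binary(row).sum())
        out.append(STONE if votes >= (n_readers + 1) // 2 else PHLEBOLITH)
    return out


def median_reader(per_reader_accuracies) -> float:
    """Accuracy of the reader with the median result (odd panel)."""
    vals = np.asarray(per_reader_accuracies, dtype=float)
    if len(vals) == 0:
        raise CalcnetError("need at least one reader accuracy")
    if len(vals) % 2 == 0:
        raise CalcnetError("median reader requires an odd number of readers")
    return float(np.sort(vals)[len(vals) // 2])


def one_sample_t(values, reference: float) -> tuple[float, float]:
    """Two-sided one-sample t-test of `values` against a fixed reference."""
    vals = np.asarray(values, dtype=float)
    if len(vals) < 2:
        raise CalcnetError("one-sample t-test needs n >= 2")
    if np.ptp(vals) == 0:
        raise CalcnetError("one-sample t-test degenerate: zero variance")
    res = stats.ttest_1samp(vals, popmean=reference)
    return float(res.statistic), float(res.pvalue)


def mann_whitney_u(group_a, group_b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U: exact for small tie-free samples,
    tie-corrected normal approximation otherwise."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise CalcnetError("both groups must be non-empty")
    if max(len(a), len(b)) <= 20 and len(np.unique(np.r_[a, b])) == len(a) + len(b):
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def accuracy_identity_holds(cm: ConfusionMatrix, tol: float = 1e-12) -> bool:
    """Check accuracy = (sens*P + spec*N) / (P+N); true for any 2x2 table."""
    m = metrics(cm)
    if cm.n_positive == 0 or cm.n_negative == 0:
        return True
    lhs = m.accuracy
    rhs = (m.sensitivity * cm.n_positive + m.specificity * cm.n_negative) / cm.total
    return math.isclose(lhs, rhs, abs_tol=tol)
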