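"""Empirical ROC curves, AUC, and Youden-optimal cutoff selection.

The decision rule throughout is "positive iff score ≥ threshold" (every
index here rises with cardiometabolic risk).  Candidate thresholds are the
midpoints between consecutive distinct sorted score values, plus one
sentinel below the minimum (classify everyone positive) and one above the
maximum (everyone negative) — the convention of the major statistical
packages.  AUC is the trapezoidal area under sensitivity vs 1−specificity,
which on this construction equals the Mann-Whitney rank statistic: the
fraction of (positive, negative) pairs correctly ordered, ties counting ½.

The operating point is chosen by maximising Youden's J = sensitivity +
specificity − 1; ties are broken toward the smallest threshold, favouring
sensitivity — the screening use-case.  Note that with a finite sample the
selected cutoff is a midpoint of *observed* values, so a cutoff published
from one cohort is generally not exactly recoverable from another.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

logger = logging.getLogger(__name__)

__all__ = [
    "ROCPoint",
    "ROCCurve",
    "CutoffReport",
    "roc_curve",
    "auc",
    "diagnostics_at",
    "optimal_cutoff",
    "bootstrap_auc_ci",
    "YoudenThresholdClassifier",
]


@dataclass(frozen=True)
class ROCPoint:
    """One operating point of an empirical ROC curve."""

    threshold: float
    sensitivity: float
    specificity: float


@dataclass(frozen=True)
class CutoffReport:
    """Diagnostic summary of one threshold on one score/label set."""

    cutoff: float
    auc: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    youden_j: float
    tp: int
    fp: int
    tn: int
    fn: int

    def as_dict(self) -> dict:
        return {
            "cutoff": self.cutoff,
            "auc": self.auc,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ppv": self.ppv,
            "npv": self.npv,
            "youden_j": self.youden_j,
            "tp": self.tp,
            "fp": self.fp,
            "tn": self.tn,
            "fn": self.fn,
        }


@dataclass
class ROCCurve:
    """Empirical ROC curve: thresholds descending, sensitivity 0 → 1.

    ``tp``/``fp`` hold the confusion counts at each threshold, so every
    operating point can be expanded to a full :class:`CutoffReport`
    without re-touching the raw scores.
    """

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    tp: np.ndarray = field(repr=False)
    fp: np.ndarray = field(repr=False)
    n_pos: int = 0
    n_neg: int = 0

    @property
    def points(self) -> list[ROCPoint]:
        return [
            ROCPoint(float(t), float(se), float(sp))
            for t, se, sp in zip(self.thresholds, self.sensitivity, self.specificity)
        ]

    @property
    def is_degenerate(self) -> bool:
        """True when the scores carry no discrimination (all tied)."""
        return len(self.thresholds) == 2

    def __len__(self) -> int:
        return len(self.thresholds)


def _validate(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels).ravel().astype(bool)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have the same length")
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    n_pos = int(labels.sum())
    if n_pos == 0 or n_pos == len(labels):
        raise ValueError("ROC undefined: both classes must be present")
    return scores, labels


def _candidate_thresholds(scores: np.ndarray) -> np.ndarray:
    """Descending candidates: midpoints of distinct values plus sentinels."""
    v = np.unique(scores)  # ascending, distinct
    mids = (v[:-1] + v[1:]) / 2.0
    lo, hi = v[0] - 1.0, v[-1] + 1.0
    return np.concatenate(([hi], mids[::-1], [lo]))


def roc_curve(scores, labels) -> ROCCurve:
    """Empirical ROC curve of ``scores`` against boolean ``labels``.

    Higher scores must code higher risk.  Raises ``ValueError`` when only
    one class is present; tied scores are handled by the midpoint
    construction (a tie never generates a threshold between equal values).
    """
    scores, labels = _validate(scores, labels)
    thresholds = _candidate_thresholds(scores)
    pos_sorted = np.sort(scores[labels])
    neg_sorted = np.sort(scores[~labels])
    n_pos, n_neg = len(pos_sorted), len(neg_sorted)
    # positives iff score >= t: count by binary search on each class
    tp = n_pos - np.searchsorted(pos_sorted, thresholds, side="left")
    fp = n_neg - np.searchsorted(neg_sorted, thresholds, side="left")
    sens = tp / n_pos
    spec = (n_neg - fp) / n_neg
    return ROCCurve(
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        tp=tp,
        fp=fp,
        n_pos=n_pos,
        n_neg=n_neg,
    )


def auc(curve_or_scores, labels=None) -> float:
    """Area under the ROC curve (trapezoidal, equals the rank statistic)."""
    curve = (
        curve_or_scores
        if isinstance(curve_or_scores, ROCCurve)
        else roc_curve(curve_or_scores, labels)
    )
    fpr = 1.0 - curve.specificity
    return float(np.trapezoid(curve.sensitivity, fpr))


def _report(cutoff, tp, fp, tn, fn, auc_value) -> CutoffReport:
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    ppv = tp / (tp + fp) if tp + fp else float("nan")
    npv = tn / (tn + fn) if tn + fn else float("nan")
    return CutoffReport(
        cutoff=float(cutoff),
        auc=float(auc_value),
        sensitivity=float(sens),
        specificity=float(spec),
        ppv=float(ppv),
        npv=float(npv),
        youden_j=float(sens + spec - 1.0),
        tp=int(tp),
        fp=int(fp),
        tn=int(tn),
        fn=int(fn),
    )


def diagnostics_at(threshold: float, scores, labels) -> CutoffReport:
    """Confusion counts and all diagnostic metrics at a fixed threshold."""
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    scores, labels = _validate(scores, labels)
    pred = scores >= threshold
    tp = int(np.sum(pred & labels))
    fp = int(np.sum(pred & ~labels))
    tn = int(np.sum(~pred & ~labels))
    fn = int(np.sum(~pred & labels))
    return _report(threshold, tp, fp, tn, fn, auc(scores, labels))


def optimal_cutoff(curve_or_scores, labels=None) -> CutoffReport:
    """Youden-optimal operating point of an ROC curve.

    Maximises J = sensitivity + specificity − 1 over all candidate
    thresholds; at ties the smallest threshold wins.  A degenerate curve
    (no discrimination) yields J = 0 with a warning.
    """
    curve = (
        curve_or_scores
        if isinstance(curve_or_scores, ROCCurve)
        else roc_curve(curve_or_scores, labels)
    )
    j = curve.sensitivity + curve.specificity - 1.0
    best_j = j.max()
    # thresholds are stored descending: the last argmax is the smallest
    idx = np.flatnonzero(j == best_j)[-1]
    if curve.is_degenerate:
        warnings.warn("degenerate ROC curve: scores carry no discrimination; J = 0")
    tp, fp = int(curve.tp[idx]), int(curve.fp[idx])
    fn, tn = curve.n_pos - tp, curve.n_neg - fp
    return _report(curve.thresholds[idx], tp, fp, tn, fn, auc(curve))


def bootstrap_auc_ci(
    scores, labels, n_boot: int = 1000, level: float = 0.95, seed: int | None = None
) -> tuple[float, float]:
    """Percentile bootstrap CI for the AUC (optional extra, off by default).

    Resamples subjects with replacement, stratified by class so both
    classes stay present in every replicate.
    """
    scores, labels = _validate(scores, labels)
    rng = np.random.default_rng(seed)
    pos, neg = scores[labels], scores[~labels]
    stats = np.empty(n_boot)
    for b in range(n_boot):
        bp = rng.choice(pos, size=len(pos), replace=True)
        bn = rng.choice(neg, size=len(neg), replace=True)
        stats[b] = auc(
            np.concatenate([bp, bn]),
            np.concatenate([np.ones(len(bp), bool), np.zeros(len(bn), bool)]),
        )
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(stats, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


class YoudenThresholdClassifier(BaseEstimator, ClassifierMixin):
    """Single-score screening classifier with a Youden-optimal threshold.

    ``fit`` builds the empirical ROC curve of the score against the binary
    outcome and stores the J-maximising cutoff; ``predict`` applies
    "positive iff score ≥ cutoff".  Fitted attributes: ``cutoff_``,
    ``auc_``, ``report_`` (a :class:`CutoffReport`), ``curve_``.
    """

    def __init__(self):
        pass

    @staticmethod
    def _scores(X) -> np.ndarray:
        arr = np.asarray(X, dtype=float)
        if arr.ndim == 2:
            if arr.shape[1] != 1:
                raise ValueError("expected a single score column")
            arr = arr[:, 0]
        return arr

    def fit(self, X, y) -> "YoudenThresholdClassifier":
        scores = self._scores(X)
        self.curve_ = roc_curve(scores, y)
        self.report_ = optimal_cutoff(self.curve_)
        self.cutoff_ = self.report_.cutoff
        self.auc_ = self.report_.auc
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = 1
        return self

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "cutoff_"):
            raise AttributeError("classifier is not fitted")
        return (self._scores(X) >= self.cutoff_).astype(int)

    def score(self, X, y) -> float:
        """Youden's J of the fitted cutoff on new data (not accuracy)."""
        rep = diagnostics_at(self.cutoff_, self._scores(X), y)
        return rep.youden_j
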