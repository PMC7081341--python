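"""ROC/AUC machinery, operating-point metrics with coverage, and paired
bootstrap comparisons (mean and [5%, 95%] percentile interval of the AUC and
specificity-at-90%-sensitivity differences over resamples)."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score, roc_curve

from .core import Outcome, ValidationError

__all__ = [
    "EvalReport",
    "DeltaReport",
    "roc_auc",
    "spec_at_sens",
    "bootstrap_delta",
    "conclusive_metrics",
]

logger = logging.getLogger(__name__)


@dataclass
class EvalReport:
    auc: float
    roc: list[tuple[float, float, float]] = field(default_factory=list)
    sensitivity: float | None = None
    specificity: float | None = None
    coverage: float = 1.0
    n: int = 0

    def to_dict(self) -> dict:
        return {
            "auc": self.auc,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "coverage": self.coverage,
            "n": self.n,
        }


@dataclass
class DeltaReport:
    delta_auc_mean: float
    delta_auc_ci: tuple[float, float]
    delta_spec_mean: float
    delta_spec_ci: tuple[float, float]
    n_common: int
    n_boot: int

    def __post_init__(self):
        for mean, (lo, hi) in (
            (self.delta_auc_mean, self.delta_auc_ci),
            (self.delta_spec_mean, self.delta_spec_ci),
        ):
            if not lo <= mean <= hi:
                raise ValidationError("CI must bracket the mean")

    def to_dict(self) -> dict:
        return {
            "delta_auc_mean": self.delta_auc_mean,
            "delta_auc_ci": list(self.delta_auc_ci),
            "delta_spec_mean": self.delta_spec_mean,
            "delta_spec_ci": list(self.delta_spec_ci),
            "n_common": self.n_common,
            "n_boot": self.n_boot,
        }


def _check_two_classes(labels: np.ndarray) -> None:
    if len(np.unique(labels)) < 2:
        raise ValidationError("both classes must be present")


def roc_auc(scores, labels) -> EvalReport:
    """Empirical ROC and trapezoidal AUC (rank-average tie handling)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    _check_two_classes(labels)
    fpr, tpr, thr = roc_curve(labels, scores)
    auc = float(roc_auc_score(labels, scores))
    return EvalReport(
        auc=auc,
        roc=[(float(f), float(t), float(h)) for f, t, h in zip(fpr, tpr, thr)],
        n=len(labels),
    )


def spec_at_sens(scores, labels, target_sensitivity: float = 0.9) -> tuple[float, float]:
    """Largest threshold achieving the target sensitivity; returns
    (threshold, attained specificity), classification rule ``score > t``."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    _check_two_classes(labels)
    pos = np.sort(scores[labels == 1])
    k = int(np.ceil(target_sensitivity * len(pos)))
    cutoff = pos[len(pos) - k]  # k-th largest positive score must stay above t
    candidates = np.concatenate([[-np.inf], np.unique(scores)])
    threshold = float(candidates[candidates < cutoff].max())
    neg = scores[labels == 0]
    specificity = float((neg <= threshold).mean())
    return threshold, specificity


def _fast_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney AUC with rank-averaged ties (no sklearn overhead)."""
    order = np.argsort(scores, kind="mergesort")
    ranks = np.empty(len(scores))
    sorted_scores = scores[order]
    # average ranks over tied groups
    ranks_sorted = np.arange(1, len(scores) + 1, dtype=float)
    i = 0
    while i < len(scores):
        j = i
        while j + 1 < len(scores) and sorted_scores[j + 1] == sorted_scores[i]:
            j += 1
        ranks_sorted[i : j + 1] = (i + j + 2) / 2
        i = j + 1
    ranks[order] = ranks_sorted
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    return (ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)


def bootstrap_delta(
    scores_a, scores_b, labels, n_boot: int = 10000, seed: int = 0
) -> DeltaReport:
    """Paired bootstrap comparison of two screeners on the same children.

    Per resample, children are drawn with replacement and the differences
    ``AUC_b - AUC_a`` and ``spec_b - spec_a`` are computed, the latter at
    thresholds re-set within each resample to achieve 90% sensitivity.
    Reports means and empirical 5th/95th percentiles.  One-class resamples
    are redrawn (and logged) so every reported draw is informative.
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if not (len(scores_a) == len(scores_b) == len(labels)):
        raise ValidationError("score vectors and labels must be aligned")
    _check_two_classes(labels)
    n = len(labels)
    rng = np.random.default_rng(seed)
    d_auc = np.empty(n_boot)
    d_spec = np.empty(n_boot)
    n_redrawn = 0
    for it in range(n_boot):
        while True:
            idx = rng.integers(0, n, n)
            y = labels[idx]
            if 0 < y.sum() < n:
                break
            n_redrawn += 1
        a, b = scores_a[idx], scores_b[idx]
        d_auc[it] = _fast_auc(b, y) - _fast_auc(a, y)
        _, sp_a = spec_at_sens(a, y, 0.9)
        _, sp_b = spec_at_sens(b, y, 0.9)
        d_spec[it] = sp_b - sp_a
    if n_redrawn:
        logger.info("redrew %d degenerate one-class resamples", n_redrawn)
    return DeltaReport(
        delta_auc_mean=float(d_auc.mean()),
        delta_auc_ci=(float(np.percentile(d_auc, 5)), float(np.percentile(d_auc, 95))),
        delta_spec_mean=float(d_spec.mean()),
        delta_spec_ci=(float(np.percentile(d_spec, 5)), float(np.percentile(d_spec, 95))),
        n_common=n,
        n_boot=n_boot,
    )


def conclusive_metrics(outcomes: list[Outcome], labels) -> EvalReport:
    """Coverage plus sensitivity/specificity/AUC over the conclusive subset."""
    labels = np.asarray(labels, dtype=int)
    if len(outcomes) != len(labels):
        raise ValidationError("outcomes and labels must be aligned")
    conclusive = np.array([o.verdict != "inconclusive" for o in outcomes])
    coverage = float(conclusive.mean()) if len(outcomes) else 0.0
    if not conclusive.any():
        raise ValidationError("no conclusive samples")
    verd = np.array([o.verdict == "positive" for o in outcomes])[conclusive]
    y = labels[conclusive]
    n_pos, n_neg = int((y == 1).sum()), int((y == 0).sum())
    sens = float(verd[y == 1].mean()) if n_pos else None
    spec = float((~verd[y == 0]).mean()) if n_neg else None
    scores = np.array(
        [o.score if o.score is not None else float(o.verdict == "positive")
         for o in outcomes]
    )[conclusive]
    auc = _fast_auc(scores, y) if n_pos and n_neg else float("nan")
    return EvalReport(
        auc=float(auc),
        sensitivity=sens,
        specificity=spec,
        coverage=coverage,
        n=int(conclusive.sum()),
    )
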