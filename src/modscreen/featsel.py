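"""Feature-selection procedures.

Three tools live here:

* :func:`shift_reject` — reject questions whose answer distribution drifted
  between the training and deployment cohorts (class-averaged mean absolute
  severity difference statistically greater than ``k_se`` standard errors).
* :func:`perturb_rank` — rank questions by how much nudging their severity
  by one level moves the model response for children near the decision
  threshold.
* :func:`backward_eliminate` — a generic bootstrapped backward elimination.
  This is a reconstruction of a previously published initial-selection step,
  not a faithful reimplementation of it; treat its exact behaviour as
  plumbing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
import pandas as pd
from sklearn.ensemble import HistGradientBoostingClassifier
from sklearn.metrics import roc_auc_score

from .core import SKIP, Dataset, ValidationError

__all__ = [
    "ShiftReport",
    "PerturbationRanking",
    "shift_reject",
    "perturb_rank",
    "shortlist_clinician",
    "backward_eliminate",
]

#: signature shared by every scorer in this package
ScoreFn = Callable[[Dataset], np.ndarray]


@dataclass
class ShiftReport:
    """Per-question distribution-shift statistics and rejection flags."""

    table: pd.DataFrame  # indexed by question id
    k_se: float

    @property
    def rejected(self) -> list[str]:
        return list(self.table.index[self.table["rejected"]])

    @property
    def kept(self) -> list[str]:
        return list(self.table.index[~self.table["rejected"]])


@dataclass
class PerturbationRanking:
    band: tuple[float, float]
    mean_shift: dict[str, float]
    ranked_ids: list[str] = field(init=False)

    def __post_init__(self):
        # descending by mean shift, ties broken by question id for determinism
        self.ranked_ids = sorted(self.mean_shift, key=lambda q: (-self.mean_shift[q], q))

    def top(self, k: int) -> list[str]:
        return self.ranked_ids[:k]


def _class_stats(ds: Dataset, qid: str, cls: int) -> tuple[float, float]:
    """(mean, standard error) of non-SKIP answers to qid among class cls."""
    vals = [
        s.answers[qid]
        for s in ds.sheets
        if s.label == cls and s.answers.get(qid, SKIP) is not SKIP
    ]
    if not vals:
        return np.nan, np.nan
    arr = np.asarray(vals, dtype=float)
    se = arr.std(ddof=1) / np.sqrt(len(arr)) if len(arr) > 1 else np.nan
    return float(arr.mean()), float(se)


def shift_reject(train: Dataset, deploy: Dataset, k_se: float = 3.0) -> ShiftReport:
    """Reject questions whose deployment answer distribution drifted.

    For each question and class ``c``: ``d_c = |mean_deploy - mean_train|``
    and ``se_c = sqrt(se_deploy^2 + se_train^2)``.  The combined statistic is
    ``mean(d_case, d_control) / mean(se_case, se_control)``; a question is
    rejected iff the statistic exceeds ``k_se``.
    """
    for name, ds in (("training", train), ("deployment", deploy)):
        labels = {s.label for s in ds.sheets}
        for cls in (0, 1):
            if cls not in labels:
                raise ValidationError(f"class {cls} empty in {name} dataset")
    if train.question_ids() != deploy.question_ids():
        raise ValidationError("train and deploy datasets must share the question schema")

    rows = []
    for qid in train.question_ids():
        rec: dict[str, float] = {}
        d_by_class, se_by_class = [], []
        for cls, tag in ((1, "case"), (0, "control")):
            m_tr, se_tr = _class_stats(train, qid, cls)
            m_de, se_de = _class_stats(deploy, qid, cls)
            d = abs(m_de - m_tr)
            se = np.sqrt(se_de**2 + se_tr**2)
            rec[f"mean_train_{tag}"] = m_tr
            rec[f"mean_deploy_{tag}"] = m_de
            rec[f"diff_{tag}"] = d
            rec[f"se_{tag}"] = se
            d_by_class.append(d)
            se_by_class.append(se)
        mean_se = np.mean(se_by_class)
        stat = np.mean(d_by_class) / mean_se if mean_se > 0 else np.inf
        rec["statistic"] = stat
        rec["rejected"] = bool(stat > k_se)
        rows.append(rec)
    table = pd.DataFrame(rows, index=pd.Index(train.question_ids(), name="question_id"))
    return ShiftReport(table=table, k_se=k_se)


def _perturbed_copy(ds: Dataset, qid: str, delta: int, idx: np.ndarray) -> Dataset:
    """Copy of ds with question qid nudged by delta for the selected sheets,
    clamped to [0, max_severity]; SKIPs untouched."""
    max_sev = ds.question_map()[qid].max_severity
    sel = set(idx.tolist())
    sheets = []
    for i, s in enumerate(ds.sheets):
        if i in sel and s.answers.get(qid, SKIP) is not SKIP:
            a = int(np.clip(s.answers[qid] + delta, 0, max_sev))
            sheets.append(replace(s, answers={**s.answers, qid: a}))
        else:
            sheets.append(s)
    return Dataset(questions=list(ds.questions), sheets=sheets, age_silo=ds.age_silo)


def perturb_rank(
    score_fn: ScoreFn,
    ds: Dataset,
    threshold: float,
    band: tuple[float, float] = (0.0, 0.1),
) -> PerturbationRanking:
    """Rank questions by perturbation sensitivity near the decision threshold.

    Children scoring in ``(threshold+lo, threshold+hi]`` have each question's
    severity dropped by one level (one question at a time); children in
    ``[threshold-hi, threshold-lo)`` have it raised.  Questions are ranked by
    the mean absolute shift in model response over the affected children.
    The input dataset is never modified.
    """
    lo, hi = band
    if not lo < hi:
        raise ValidationError("band must satisfy lo < hi")
    base = np.asarray(score_fn(ds), dtype=float)
    above = np.where((base > threshold + lo) & (base <= threshold + hi))[0]
    below = np.where((base >= threshold - hi) & (base < threshold - lo))[0]
    if len(above) == 0 and len(below) == 0:
        import warnings

        warnings.warn("no children in the perturbation band; empty ranking")
        return PerturbationRanking(band=band, mean_shift={})

    mean_shift: dict[str, float] = {}
    for qid in ds.question_ids():
        shifts = []
        for idx, delta in ((above, -1), (below, +1)):
            if len(idx) == 0:
                continue
            perturbed = _perturbed_copy(ds, qid, delta, idx)
            new = np.asarray(score_fn(perturbed), dtype=float)
            shifts.append(np.abs(new[idx] - base[idx]))
        mean_shift[qid] = float(np.concatenate(shifts).mean())
    return PerturbationRanking(band=band, mean_shift=mean_shift)


def shortlist_clinician(
    imp_list: list[str],
    band_a: PerturbationRanking,
    band_b: PerturbationRanking,
    top_k: int = 7,
    allow: list[str] | None = None,
) -> list[str]:
    """Merge the top-k of three candidate rankings into one shortlist.

    Ordered by each question's best (minimum) rank across the lists, ties
    broken by question id.  ``allow`` is the expert-consultation hook: when
    given, questions outside it are dropped.
    """
    lists = [imp_list, band_a.ranked_ids, band_b.ranked_ids]
    best_rank: dict[str, int] = {}
    for ranking in lists:
        for rank, qid in enumerate(ranking[:top_k]):
            if qid not in best_rank or rank < best_rank[qid]:
                best_rank[qid] = rank
    selected = sorted(best_rank, key=lambda q: (best_rank[q], q))
    if allow is not None:
        allowed = set(allow)
        selected = [q for q in selected if q in allowed]
    return selected


def _default_eliminator():
    return HistGradientBoostingClassifier(
        max_iter=40, max_leaf_nodes=15, random_state=0, early_stopping=False
    )


def backward_eliminate(
    ds: Dataset,
    n_boot: int = 10,
    min_features: int = 1,
    seed: int = 0,
    tolerance: float = 0.01,
    learner_factory: Callable = _default_eliminator,
) -> list[str]:
    """Bootstrapped backward elimination (reconstruction; see module docstring).

    Repeatedly removes the question whose removal least degrades mean
    out-of-bag AUC over ``n_boot`` bootstrap refits, until ``min_features``
    remain or the best removal would cost more than ``tolerance`` AUC.
    """
    qids = ds.question_ids()
    if min_features > len(qids):
        raise ValidationError("min_features exceeds available questions")
    labels = np.asarray([s.label for s in ds.sheets], dtype=float)
    if np.isnan(labels).any():
        raise ValidationError("backward_eliminate requires a fully labelled dataset")
    frame = ds.to_frame()
    X_full = frame[qids].to_numpy(dtype=float)
    y = labels.astype(int)
    rng = np.random.default_rng(seed)
    n = len(y)

    # fixed bootstrap index sets shared across candidate evaluations
    boot_idx = [rng.integers(0, n, n) for _ in range(n_boot)]
    oob_idx = [np.setdiff1d(np.arange(n), b) for b in boot_idx]

    def mean_oob_auc(cols: list[int]) -> float:
        aucs = []
        for b, o in zip(boot_idx, oob_idx):
            if len(o) == 0 or len(np.unique(y[b])) < 2 or len(np.unique(y[o])) < 2:
                continue
            clf = learner_factory()
            clf.fit(X_full[np.ix_(b, cols)], y[b])
            scores = clf.predict_proba(X_full[np.ix_(o, cols)])[:, 1]
            aucs.append(roc_auc_score(y[o], scores))
        return float(np.mean(aucs)) if aucs else 0.5

    current = list(range(len(qids)))
    current_auc = mean_oob_auc(current)
    while len(current) > min_features:
        best_auc, best_drop = -np.inf, None
        for col in current:
            candidate = [c for c in current if c != col]
            auc = mean_oob_auc(candidate)
            if auc > best_auc:
                best_auc, best_drop = auc, col
        if best_auc < current_auc - tolerance:
            break
        current = [c for c in current if c != best_drop]
        current_auc = best_auc
    return [qids[c] for c in current]
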