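"""Three-run training of an abstention-capable classifier.

Training proceeds in three fits: a helper binary model produces out-of-fold
predictions whose agreement with truth labels each sample "correct" or
"incorrect"; a filter model learns to predict "incorrect" (the runtime
inconclusive gate); and the final binary model is trained only on the
samples the filter deems likely-correct.  The helper model is discarded —
only the filter and the final binary model run at prediction time.

Folds are stratified by the true class label and samples are weight-balanced
over (age, label) cells.  Gradient-boosted trees are the default learner for
all three fits, behind a factory so tests can swap in cheaper models.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
from sklearn.ensemble import HistGradientBoostingClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .core import SKIP, Dataset, Outcome, ScoreSheet, ValidationError

__all__ = ["TrainConfig", "CascadeModel", "train_cascade", "predict", "predict_dataset",
           "tune_thresholds", "feature_matrix"]


def default_learner(**params) -> HistGradientBoostingClassifier:
    kwargs = dict(max_iter=80, max_leaf_nodes=31, random_state=0, early_stopping=False)
    kwargs.update(params)
    return HistGradientBoostingClassifier(**kwargs)


@dataclass
class TrainConfig:
    """Training knobs; ``grid`` is a hyper-parameter grid searched with
    bootstrapped out-of-bag validation."""

    cv_folds: int = 5
    grid: dict[str, list] | None = None
    n_boot: int = 10
    seed: int = 0
    weight_balance: bool = True
    label_target_sensitivity: float = 0.9
    max_inconclusive: float = 0.3

    def __post_init__(self):
        if self.cv_folds < 2:
            raise ValidationError("cv_folds must be >= 2")
        if not 0 <= self.max_inconclusive < 1:
            raise ValidationError("max_inconclusive must be in [0, 1)")


class _ConstantScorer:
    """Fallback when a fit target is single-class (e.g. nothing misclassified)."""

    def __init__(self, value: float):
        self.value = value

    def predict_proba(self, X):
        n = np.asarray(X).shape[0]
        p1 = np.full(n, self.value)
        return np.column_stack([1 - p1, p1])


@dataclass
class CascadeModel:
    """Runtime pair: inconclusive filter + binary classifier, with thresholds."""

    filter_model: object
    binary_model: object
    filter_threshold: float
    decision_threshold: float
    silo: str
    feature_ids: list[str]
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if not 0 <= self.filter_threshold <= 1 or not 0 <= self.decision_threshold <= 1:
            raise ValidationError("thresholds must lie in [0, 1]")

    def filter_scores(self, ds: Dataset) -> np.ndarray:
        X = feature_matrix(ds, self.feature_ids)
        return self.filter_model.predict_proba(X)[:, 1]

    def binary_scores(self, ds: Dataset) -> np.ndarray:
        X = feature_matrix(ds, self.feature_ids)
        return self.binary_model.predict_proba(X)[:, 1]


def feature_matrix(ds: Dataset, feature_ids: list[str]) -> np.ndarray:
    """Dense matrix over feature_ids; SKIP and unanswered become NaN."""
    X = np.full((len(ds.sheets), len(feature_ids)), np.nan)
    col = {qid: j for j, qid in enumerate(feature_ids)}
    for i, sheet in enumerate(ds.sheets):
        for qid, a in sheet.answers.items():
            if qid in col and a is not SKIP:
                X[i, col[qid]] = float(a)
    return X


def _balance_weights(ages: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Inverse-frequency weights over (age-in-years, label) cells."""
    cells = ages // 12 * 2 + y
    uniq, inv, counts = np.unique(cells, return_inverse=True, return_counts=True)
    w = len(y) / (len(uniq) * counts[inv])
    return w


def _sens_threshold(scores: np.ndarray, y: np.ndarray, target: float) -> float:
    """Largest threshold t with sensitivity(score > t) >= target."""
    pos = np.sort(scores[y == 1])
    if len(pos) == 0:
        raise ValidationError("no positive samples")
    # with threshold t, sensitivity = frac(pos > t); choose t just below the
    # k-th largest positive score where k = ceil(target * n_pos)
    k = int(np.ceil(target * len(pos)))
    cutoff = pos[len(pos) - k]
    candidates = np.concatenate([[-np.inf], np.unique(scores)])
    feasible = candidates[candidates < cutoff]
    return float(feasible.max())


def _fit(learner_factory: Callable, X, y, w=None, fallback: float = 0.0, **params):
    if len(np.unique(y)) < 2:
        return _ConstantScorer(fallback)
    model = learner_factory(**params)
    model.fit(X, y, sample_weight=w)
    return model


def _grid_search(
    learner_factory, X, y, w, grid: dict[str, list], n_boot: int, seed: int
) -> dict:
    """Bootstrapped grid search: per grid point, n_boot resamples each fit on
    the resample and scored on its out-of-bag samples; best mean AUC wins."""
    rng = np.random.default_rng(seed)
    n = len(y)
    boots = [rng.integers(0, n, n) for _ in range(n_boot)]
    oobs = [np.setdiff1d(np.arange(n), b) for b in boots]
    keys = sorted(grid)
    best_params, best_auc = {}, -np.inf
    for values in itertools.product(*(grid[k] for k in keys)):
        params = dict(zip(keys, values))
        aucs = []
        for b, o in zip(boots, oobs):
            if len(o) == 0 or len(np.unique(y[b])) < 2 or len(np.unique(y[o])) < 2:
                continue
            model = _fit(learner_factory, X[b], y[b], None if w is None else w[b], **params)
            aucs.append(roc_auc_score(y[o], model.predict_proba(X[o])[:, 1]))
        mean_auc = np.mean(aucs) if aucs else -np.inf
        if mean_auc > best_auc:
            best_auc, best_params = mean_auc, params
    return best_params


def _oof_scores(learner_factory, X, y, strat, w, cv_folds, seed, params) -> np.ndarray:
    """Out-of-fold probability scores, folds stratified by ``strat``."""
    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    oof = np.full(len(y), np.nan)
    for tr, te in skf.split(X, strat):
        model = _fit(
            learner_factory, X[tr], y[tr], None if w is None else w[tr],
            fallback=float(np.mean(y[tr])), **params,
        )
        oof[te] = model.predict_proba(X[te])[:, 1]
    return oof


def train_cascade(
    ds: Dataset,
    cfg: TrainConfig,
    feature_ids: list[str] | None = None,
    learner_factory: Callable = default_learner,
) -> CascadeModel:
    """Run the three training fits and return the runtime model pair.

    Raises on a single-class dataset.  Deterministic under ``cfg.seed``.
    """
    feature_ids = feature_ids or ds.question_ids()
    X = feature_matrix(ds, feature_ids)
    y = np.asarray([s.label for s in ds.sheets])
    if None in ds.labels():
        raise ValidationError("train_cascade requires a fully labelled dataset")
    y = y.astype(int)
    if len(np.unique(y)) < 2:
        raise ValidationError("dataset contains a single class")
    ages = np.asarray([s.age_months for s in ds.sheets])
    w = _balance_weights(ages, y) if cfg.weight_balance else None

    params = {}
    if cfg.grid:
        params = _grid_search(learner_factory, X, y, w, cfg.grid, cfg.n_boot, cfg.seed)

    # fit 1 (helper): out-of-fold predictions -> correct/incorrect labels
    oof = _oof_scores(learner_factory, X, y, y, w, cfg.cv_folds, cfg.seed, params)
    label_cut = _sens_threshold(oof, y, cfg.label_target_sensitivity)
    hard = (oof > label_cut).astype(int)
    incorrect = (hard != y).astype(int)

    # fit 2: the inconclusive filter predicts "incorrect"
    filter_model = _fit(learner_factory, X, incorrect, w, fallback=0.0, **params)

    # initial filter threshold flags at most max_inconclusive of training data;
    # the filter's own out-of-fold scores decide which samples train fit 3
    filter_oof = _oof_scores(
        learner_factory, X, incorrect, y, w, cfg.cv_folds, cfg.seed + 1, params
    )
    fthr = float(np.quantile(filter_oof, 1 - cfg.max_inconclusive))
    keep = filter_oof <= fthr
    if len(np.unique(y[keep])) < 2:  # filter too aggressive: train on everything
        keep = np.ones(len(y), bool)

    # fit 3: final binary classifier on likely-correct samples only
    binary_model = _fit(
        learner_factory, X[keep], y[keep], None if w is None else w[keep],
        fallback=float(np.mean(y)), **params,
    )
    return CascadeModel(
        filter_model=filter_model,
        binary_model=binary_model,
        filter_threshold=min(max(fthr, 0.0), 1.0),
        decision_threshold=0.5,
        silo=ds.age_silo,
        feature_ids=list(feature_ids),
        params=params,
    )


def predict_dataset(model: CascadeModel, ds: Dataset) -> list[Outcome]:
    """Three-way outcomes for every sheet in ds."""
    f = model.filter_scores(ds)
    b = model.binary_scores(ds)
    outcomes = []
    for sheet, fs, bs in zip(ds.sheets, f, b):
        if fs > model.filter_threshold:
            outcomes.append(Outcome(child_id=sheet.child_id, verdict="inconclusive"))
        else:
            verdict = "positive" if bs > model.decision_threshold else "negative"
            outcomes.append(Outcome(child_id=sheet.child_id, verdict=verdict,
                                    score=float(bs)))
    return outcomes


def predict(model: CascadeModel, sheet: ScoreSheet, questions=None) -> Outcome:
    """Outcome for one sheet; SKIPs and absent features are legal (NaN)."""
    from .core import Question

    if questions is None:
        answered = sheet.answered()
        questions = [
            Question(id=qid, max_severity=max(3, answered.get(qid, 0)))
            for qid in model.feature_ids
        ]
    known = {q.id for q in questions}
    ds = Dataset(questions=questions, sheets=[replace(sheet, answers={
        q: a for q, a in sheet.answers.items() if q in known
    })])
    return predict_dataset(model, ds)[0]


def tune_thresholds(
    model: CascadeModel,
    ds: Dataset,
    target_sensitivity: float = 0.9,
    max_inconclusive: float = 0.3,
) -> CascadeModel:
    """Tune the two runtime thresholds on a labelled dataset.

    The filter threshold is the largest value keeping the inconclusive
    fraction at or below ``max_inconclusive`` while maximizing AUC over the
    conclusive subset; the decision threshold is then the largest value whose
    conclusive-subset sensitivity meets ``target_sensitivity``.  Ties prefer
    larger thresholds.  Returns an updated copy.
    """
    from sklearn.metrics import roc_auc_score

    y = np.asarray(ds.labels())
    if None in ds.labels():
        raise ValidationError("tuning requires labels")
    y = y.astype(int)
    f = model.filter_scores(ds)
    b = model.binary_scores(ds)
    n = len(y)

    candidates = np.unique(np.concatenate([f, [0.0, 1.0]]))
    best = None  # (auc, threshold)
    for t in candidates:
        conclusive = f <= t
        if (~conclusive).sum() / n > max_inconclusive:
            continue
        if len(np.unique(y[conclusive])) < 2:
            continue
        auc = roc_auc_score(y[conclusive], b[conclusive])
        if best is None or auc > best[0] + 1e-12 or (
            abs(auc - best[0]) <= 1e-12 and t > best[1]
        ):
            best = (auc, float(t))
    if best is None:
        raise ValidationError(
            "no filter threshold satisfies the inconclusive allowance with both "
            "classes conclusive; best achievable inconclusive fraction is "
            f"{(f > candidates.max()).mean():.3f}"
        )
    fthr = best[1]
    conclusive = f <= fthr
    if (y[conclusive] == 1).sum() == 0:
        raise ValidationError("no conclusive positive samples to set sensitivity")
    dthr = _sens_threshold(b[conclusive], y[conclusive], target_sensitivity)
    dthr = min(max(dthr, 0.0), 1.0)
    return replace(model, filter_threshold=fthr, decision_threshold=float(dthr))
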