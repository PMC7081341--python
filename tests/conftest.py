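import numpy as np
import pytest
from sklearn.ensemble import HistGradientBoostingClassifier

from modscreen.core import SKIP, Dataset, Question, ScoreSheet
from modscreen.synthgen import GeneratorConfig, generate_training


def fast_learner(**params):
    """Cheap GBDT for tests that exercise training paths, not accuracy."""
    kwargs = dict(max_iter=25, max_leaf_nodes=7, random_state=0, early_stopping=False)
    kwargs.update(params)
    return HistGradientBoostingClassifier(**kwargs)


@pytest.fixture
def schema():
    return [Question(id=f"q{i:02d}", max_severity=3) for i in range(4)]


@pytest.fixture
def small_dataset(schema):
    sheets = [
        ScoreSheet("a", 24, 1, "training", {"q00": 2, "q01": 0, "q02": SKIP, "q03": 3}),
        ScoreSheet("b", 50, 0, "training", {"q00": 1, "q01": 1, "q02": 2, "q03": 0}),
        ScoreSheet("c", 36, 1, "deployment", {"q00": 3, "q01": SKIP, "q02": 1, "q03": 2}),
    ]
    return Dataset(questions=schema, sheets=sheets)


@pytest.fixture
def labelled_dataset():
    cfg = GeneratorConfig(n_case=120, n_control=80, n_questions=6,
                          class_separation=1.5, seed=7)
    return generate_training(cfg)


def random_dataset(rng: np.random.Generator, n=20, n_questions=5,
                   skip_prob=0.2, cohort="training") -> Dataset:
    """Arbitrary valid Dataset for property tests."""
    questions = [Question(id=f"q{i:02d}", max_severity=3) for i in range(n_questions)]
    sheets = []
    for i in range(n):
        answers = {}
        for q in questions:
            if rng.random() < skip_prob:
                answers[q.id] = SKIP
            else:
                answers[q.id] = int(rng.integers(0, q.max_severity + 1))
        sheets.append(
            ScoreSheet(
                child_id=f"c{i:04d}",
                age_months=int(rng.integers(0, 96)),
                label=int(rng.integers(0, 2)),
                cohort=cohort,
                answers=answers,
            )
        )
    return Dataset(questions=questions, sheets=sheets)
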