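import copy

import numpy as np
import pytest

from modscreen.core import SKIP, Dataset, Question, ScoreSheet, ValidationError
from modscreen.featsel import (
    PerturbationRanking,
    backward_eliminate,
    perturb_rank,
    shift_reject,
    shortlist_clinician,
)
from modscreen.synthgen import GeneratorConfig, generate_training
from conftest import fast_learner, random_dataset


def _shifted_copy(ds: Dataset, qid: str, delta: int) -> Dataset:
    """Every answer of qid moved by delta, clipped into range."""
    max_sev = ds.question_map()[qid].max_severity
    sheets = []
    for s in ds.sheets:
        answers = dict(s.answers)
        if answers.get(qid, SKIP) is not SKIP:
            answers[qid] = int(np.clip(answers[qid] + delta, 0, max_sev))
        sheets.append(ScoreSheet(s.child_id, s.age_months, s.label, "deployment", answers))
    return Dataset(questions=list(ds.questions), sheets=sheets)


def _relabel_cohort(ds: Dataset, cohort: str) -> Dataset:
    sheets = [ScoreSheet(s.child_id, s.age_months, s.label, cohort, dict(s.answers))
              for s in ds.sheets]
    return Dataset(questions=list(ds.questions), sheets=sheets)


class TestShiftReject:
    def test_identical_datasets_no_rejections(self, labelled_dataset):
        deploy = _relabel_cohort(labelled_dataset, "deployment")
        report = shift_reject(labelled_dataset, deploy)
        assert report.rejected == []
        assert (report.table["statistic"] == 0).all()

    def test_shifted_question_rejected(self):
        cfg = GeneratorConfig(n_case=300, n_control=300, n_questions=5, seed=31)
        train = generate_training(cfg)
        deploy = _relabel_cohort(_shifted_copy(train, "q02", +1), "deployment")
        report = shift_reject(train, deploy)
        assert "q02" in report.rejected

    def test_empty_class_errors(self, labelled_dataset):
        only_cases = Dataset(
            questions=list(labelled_dataset.questions),
            sheets=[s for s in labelled_dataset.sheets if s.label == 1],
        )
        with pytest.raises(ValidationError, match="class 0"):
            shift_reject(labelled_dataset, only_cases)

    def test_null_rejection_rate_small_sample(self):
        # scaled-down version of the acceptance simulation (20 reps here)
        n_reject = 0
        n_total = 0
        for rep in range(20):
            cfg = GeneratorConfig(n_case=200, n_control=200, n_questions=4,
                                  seed=1000 + rep)
            train = generate_training(cfg)
            cfg2 = GeneratorConfig(n_case=200, n_control=200, n_questions=4,
                                   seed=5000 + rep)
            deploy = _relabel_cohort(generate_training(cfg2), "deployment")
            report = shift_reject(train, deploy)
            n_reject += len(report.rejected)
            n_total += 4
        assert n_reject / n_total < 0.1

    def test_statistic_sign_symmetric(self):
        cfg = GeneratorConfig(n_case=200, n_control=200, n_questions=3, seed=33)
        train = generate_training(cfg)
        up = _relabel_cohort(_shifted_copy(train, "q01", +1), "deployment")
        down = _relabel_cohort(_shifted_copy(train, "q01", -1), "deployment")
        s_up = shift_reject(train, up).table.loc["q01", "statistic"]
        s_down = shift_reject(train, down).table.loc["q01", "statistic"]
        assert s_up > 0 and s_down > 0  # |d| in both directions

    def test_scale_covariance(self):
        # doubling all severities doubles d and se alike; statistic unchanged
        cfg = GeneratorConfig(n_case=150, n_control=150, n_questions=2,
                              difficulty_cutpoints=[[-0.5, 0.5, 1.5]] * 2, seed=34)
        train = generate_training(cfg)
        deploy = _relabel_cohort(_shifted_copy(train, "q00", +1), "deployment")

        def doubled(ds):
            qs = [Question(q.id, q.max_severity * 2) for q in ds.questions]
            sheets = [
                ScoreSheet(s.child_id, s.age_months, s.label, s.cohort,
                           {q: (a if a is SKIP else a * 2) for q, a in s.answers.items()})
                for s in ds.sheets
            ]
            return Dataset(questions=qs, sheets=sheets)

        base = shift_reject(train, deploy).table["statistic"]
        scaled = shift_reject(doubled(train), doubled(deploy)).table["statistic"]
        np.testing.assert_allclose(base.to_numpy(), scaled.to_numpy(), rtol=1e-9)

    def test_k_se_parameter(self, labelled_dataset):
        # identical cohorts: statistic is exactly 0, so k_se=0 rejects nothing
        deploy = _relabel_cohort(labelled_dataset, "deployment")
        assert shift_reject(labelled_dataset, deploy, k_se=0.0).rejected == []
        # but any shift at all clears a k_se=0 bar
        shifted = _relabel_cohort(_shifted_copy(labelled_dataset, "q00", 1), "deployment")
        assert "q00" in shift_reject(labelled_dataset, shifted, k_se=0.0).rejected


def _linear_logit_scorer(betas: dict[str, float], intercept: float = 0.0):
    """Score a Dataset with a fixed logistic model; SKIP counts as 0."""

    def score(ds: Dataset) -> np.ndarray:
        out = []
        for s in ds.sheets:
            z = intercept + sum(
                betas.get(q, 0.0) * (0 if a is SKIP else a)
                for q, a in s.answers.items()
            )
            out.append(1.0 / (1.0 + np.exp(-z)))
        return np.asarray(out)

    return score


class TestPerturbRank:
    @pytest.fixture
    def mid_band_dataset(self):
        rng = np.random.default_rng(41)
        return random_dataset(rng, n=60, n_questions=4, skip_prob=0.1)

    def test_ignored_question_ranked_last(self, mid_band_dataset):
        betas = {"q00": 0.4, "q01": 0.3, "q02": 0.2, "q03": 0.0}
        score = _linear_logit_scorer(betas, intercept=-1.0)
        ranking = perturb_rank(score, mid_band_dataset, threshold=0.5, band=(0.0, 0.45))
        assert ranking.mean_shift["q03"] == 0.0
        assert ranking.ranked_ids[-1] == "q03"

    def test_single_question_model_ranked_first(self, mid_band_dataset):
        score = _linear_logit_scorer({"q02": 0.8}, intercept=-1.0)
        ranking = perturb_rank(score, mid_band_dataset, threshold=0.5, band=(0.0, 0.45))
        assert ranking.ranked_ids[0] == "q02"

    def test_matches_coefficient_magnitudes(self, mid_band_dataset):
        # closed-form logit-shift oracle: near threshold 0.5 the response
        # shift from a one-level change is monotone in |beta|
        betas = {"q00": 0.05, "q01": 0.6, "q02": 0.25, "q03": 0.12}
        score = _linear_logit_scorer(betas, intercept=-0.8)
        ranking = perturb_rank(score, mid_band_dataset, threshold=0.5, band=(0.0, 0.45))
        expected = sorted(betas, key=lambda q: -abs(betas[q]))
        assert ranking.ranked_ids == expected

    def test_dataset_unmodified(self, mid_band_dataset):
        before = copy.deepcopy([s.answers for s in mid_band_dataset.sheets])
        score = _linear_logit_scorer({"q00": 0.5}, intercept=-1.0)
        perturb_rank(score, mid_band_dataset, threshold=0.5, band=(0.0, 0.45))
        assert [s.answers for s in mid_band_dataset.sheets] == before

    def test_empty_band_warns(self, mid_band_dataset):
        score = _linear_logit_scorer({"q00": 0.5})
        with pytest.warns(UserWarning):
            ranking = perturb_rank(score, mid_band_dataset, threshold=99.0,
                                   band=(0.0, 0.01))
        assert ranking.ranked_ids == []

    def test_bad_band_rejected(self, mid_band_dataset):
        score = _linear_logit_scorer({"q00": 0.5})
        with pytest.raises(ValidationError):
            perturb_rank(score, mid_band_dataset, threshold=0.5, band=(0.2, 0.1))

    def test_skips_left_untouched(self):
        # a sheet whose only answer to q00 is SKIP contributes zero shift
        qs = [Question("q00"), Question("q01")]
        sheets = [ScoreSheet(f"c{i}", 24, 1, "training", {"q00": SKIP, "q01": 1})
                  for i in range(5)]
        ds = Dataset(questions=qs, sheets=sheets)
        score = _linear_logit_scorer({"q00": 5.0, "q01": 0.1})
        # all children score sigmoid(0.1) ~ 0.525, inside the upper band
        ranking = perturb_rank(score, ds, threshold=0.5, band=(0.0, 0.2))
        assert ranking.mean_shift["q00"] == 0.0
        assert ranking.mean_shift["q01"] > 0.0


class TestShortlist:
    def _ranking(self, ids):
        return PerturbationRanking(band=(0.0, 0.1),
                                   mean_shift={q: -i for i, q in enumerate(ids)})

    def test_identical_rankings_give_top_k(self):
        ids = [f"q{i}" for i in range(10)]
        r = self._ranking(ids)
        out = shortlist_clinician(ids, r, r, top_k=7)
        assert out == ids[:7]

    def test_disjoint_rankings_give_3k(self):
        a = [f"a{i}" for i in range(8)]
        b = [f"b{i}" for i in range(8)]
        c = [f"c{i}" for i in range(8)]
        out = shortlist_clinician(a, self._ranking(b), self._ranking(c), top_k=7)
        assert len(out) == 21
        assert len(out) <= 3 * 7  # bounded by 3*top_k

    def test_engineered_overlap_union_size(self):
        # brute-force set-union oracle
        shared = [f"s{i}" for i in range(5)]
        a = shared + ["a0", "a1"]
        b = shared + ["b0", "b1"]
        c = shared + ["c0", "c1"]
        out = shortlist_clinician(a, self._ranking(b), self._ranking(c), top_k=7)
        expected = set(a[:7]) | set(b[:7]) | set(c[:7])
        assert set(out) == expected
        assert len(out) == len(expected) == 11

    def test_ordered_by_best_rank_then_id(self):
        a = ["x", "y", "z"]
        b = ["z", "y", "x"]
        out = shortlist_clinician(a, self._ranking(b), self._ranking(b), top_k=3)
        # x and z both achieve best rank 0; tie broken by id
        assert out == ["x", "z", "y"]

    def test_allow_list_hook(self):
        ids = [f"q{i}" for i in range(5)]
        r = self._ranking(ids)
        out = shortlist_clinician(ids, r, r, top_k=5, allow=["q1", "q3"])
        assert out == ["q1", "q3"]


class TestBackwardEliminate:
    def test_identity_when_min_features_is_all(self, labelled_dataset):
        qids = labelled_dataset.question_ids()
        out = backward_eliminate(labelled_dataset, n_boot=3,
                                 min_features=len(qids), seed=0,
                                 learner_factory=fast_learner)
        assert sorted(out) == sorted(qids)

    def test_min_features_too_large_errors(self, labelled_dataset):
        with pytest.raises(ValidationError):
            backward_eliminate(labelled_dataset, min_features=99)

    def test_pure_noise_terminates(self):
        rng = np.random.default_rng(51)
        ds = random_dataset(rng, n=80, n_questions=5, skip_prob=0.0)
        out = backward_eliminate(ds, n_boot=3, min_features=1, seed=1,
                                 tolerance=1.0, learner_factory=fast_learner)
        assert len(out) == 1

    def test_planted_signal_survives(self):
        # 2 of 8 questions jointly carry all the signal (label = XOR of their
        # high/low states), so neither is redundant and both must survive
        rng = np.random.default_rng(52)
        n = 300
        z1 = rng.integers(0, 2, n)
        z2 = rng.integers(0, 2, n)
        y = z1 ^ z2
        questions = [Question(f"q{i:02d}") for i in range(8)]
        sheets = []
        for i in range(n):
            answers = {}
            for j, q in enumerate(questions):
                if j == 0:
                    base = 2 * z1[i] + rng.integers(0, 2)
                elif j == 1:
                    base = 2 * z2[i] + rng.integers(0, 2)
                else:
                    base = rng.integers(0, 4)
                answers[q.id] = int(np.clip(base, 0, 3))
            sheets.append(ScoreSheet(f"c{i}", 24 + int(rng.integers(0, 48)),
                                     int(y[i]), "training", answers))
        ds = Dataset(questions=questions, sheets=sheets)
        out = backward_eliminate(ds, n_boot=4, min_features=2, seed=2,
                                 learner_factory=fast_learner)
        assert "q00" in out and "q01" in out
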