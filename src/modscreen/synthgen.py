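"""Synthetic ordinal questionnaire data with the structure downstream stages need.

A graded-response latent-trait model: each child draws a latent trait
``t ~ Normal(mu_class, 1)``, and the answer to question *q* is the number of
that question's cutpoints lying below ``t * discrimination_q + noise``.
Deployment-setting data offsets each question's latent input by a
per-question bias and replaces answers with SKIP at a per-question rate,
emulating the clinic-vs-home answer drift and analyst skips.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from .core import SKIP, Dataset, Question, ScoreSheet, ValidationError

__all__ = [
    "GeneratorConfig",
    "generate_training",
    "generate_deployment",
    "generate_paired",
    "baseline_screener_score",
]

_N_LEVELS = 4  # ordinal codes 0..3


def _default_cutpoints(n_questions: int) -> list[list[float]]:
    # evenly spread so mid-trait children sit near severity 1-2
    return [[-0.8, 0.4, 1.6] for _ in range(n_questions)]


@dataclass
class GeneratorConfig:
    """Knobs of the latent-trait generator; one seed drives every stage."""

    n_case: int = 400
    n_control: int = 200
    n_questions: int = 15
    age_range_months: tuple[int, int] = (18, 72)
    discrimination: list[float] | float = 1.0
    difficulty_cutpoints: list[list[float]] | None = None
    class_separation: float = 1.5
    answer_noise: float = 1.0
    shift_bias: list[float] | float = 0.0
    skip_rate: list[float] | float = 0.15
    baseline_screener_noise: float = 0.0
    seed: int = 0

    # resolved per-question arrays
    _disc: np.ndarray = field(init=False, repr=False)
    _cuts: np.ndarray = field(init=False, repr=False)
    _shift: np.ndarray = field(init=False, repr=False)
    _skip: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        q = self.n_questions
        if self.n_case < 0 or self.n_control < 0 or q < 1:
            raise ValidationError("counts must be non-negative, n_questions >= 1")
        self._disc = self._per_question(self.discrimination, "discrimination")
        if np.any(self._disc <= 0):
            raise ValidationError("discrimination must be > 0")
        cuts = self.difficulty_cutpoints or _default_cutpoints(q)
        if len(cuts) != q:
            raise ValidationError("difficulty_cutpoints length must equal n_questions")
        self._cuts = np.asarray(cuts, dtype=float)
        if np.any(np.diff(self._cuts, axis=1) <= 0):
            raise ValidationError("cutpoints must be strictly increasing")
        self._shift = self._per_question(self.shift_bias, "shift_bias")
        self._skip = self._per_question(self.skip_rate, "skip_rate")
        if np.any((self._skip < 0) | (self._skip > 1)):
            raise ValidationError("skip_rate must be in [0, 1]")
        if self.baseline_screener_noise < 0:
            raise ValidationError("baseline_screener_noise must be >= 0")

    def _per_question(self, value, name: str) -> np.ndarray:
        arr = np.asarray(value, dtype=float)
        if arr.ndim == 0:
            arr = np.full(self.n_questions, float(arr))
        if arr.shape != (self.n_questions,):
            raise ValidationError(f"{name} must be scalar or length n_questions")
        return arr

    def questions(self) -> list[Question]:
        return [
            Question(id=f"q{i:02d}", max_severity=self._cuts.shape[1])
            for i in range(self.n_questions)
        ]

    def rng(self, stream: str) -> np.random.Generator:
        """Independent generator for a named stage, derived from the one seed."""
        # crc32 rather than hash(): stable across interpreter runs
        key = zlib.crc32(stream.encode("utf-8"))
        ss = np.random.SeedSequence(self.seed, spawn_key=(key,))
        return np.random.default_rng(ss)


def _draw_latents(cfg: GeneratorConfig, rng: np.random.Generator):
    """Latent traits, per-question noise, labels and ages for one cohort."""
    n = cfg.n_case + cfg.n_control
    labels = np.concatenate([np.ones(cfg.n_case, int), np.zeros(cfg.n_control, int)])
    mu = np.where(labels == 1, cfg.class_separation, 0.0)
    t = rng.normal(mu, 1.0)
    eps = rng.normal(0.0, cfg.answer_noise, size=(n, cfg.n_questions))
    lo, hi = cfg.age_range_months
    ages = rng.integers(lo, hi + 1, size=n)
    return t, eps, labels, ages


def _codes_from_latent(cfg: GeneratorConfig, t: np.ndarray, eps: np.ndarray,
                       shift: np.ndarray) -> np.ndarray:
    x = t[:, None] * cfg._disc[None, :] + eps + shift[None, :]
    # answer = number of cutpoints below x
    return (x[:, :, None] > cfg._cuts[None, :, :]).sum(axis=2)


def _sheets(cfg: GeneratorConfig, codes, labels, ages, cohort, skip_mask=None,
            id_prefix="c") -> list[ScoreSheet]:
    qids = [q.id for q in cfg.questions()]
    sheets = []
    for i in range(codes.shape[0]):
        answers: dict[str, object] = {}
        for j, qid in enumerate(qids):
            if skip_mask is not None and skip_mask[i, j]:
                answers[qid] = SKIP
            else:
                answers[qid] = int(codes[i, j])
        sheets.append(
            ScoreSheet(
                child_id=f"{id_prefix}{i:05d}",
                age_months=int(ages[i]),
                label=int(labels[i]),
                cohort=cohort,
                answers=answers,
            )
        )
    return sheets


def generate_training(cfg: GeneratorConfig) -> Dataset:
    """Clean clinic-setting cohort: no shift, no skips. Deterministic under seed."""
    rng = cfg.rng("training")
    t, eps, labels, ages = _draw_latents(cfg, rng)
    codes = _codes_from_latent(cfg, t, eps, np.zeros(cfg.n_questions))
    return Dataset(
        questions=cfg.questions(),
        sheets=_sheets(cfg, codes, labels, ages, "training", id_prefix="t"),
    )


def generate_deployment(cfg: GeneratorConfig) -> Dataset:
    """Fresh children from the same latent model, with per-question severity
    drift applied before cutpoint mapping and answers skipped at the
    per-question rate."""
    rng = cfg.rng("deployment")
    t, eps, labels, ages = _draw_latents(cfg, rng)
    codes = _codes_from_latent(cfg, t, eps, cfg._shift)
    skip_mask = rng.random(codes.shape) < cfg._skip[None, :]
    return Dataset(
        questions=cfg.questions(),
        sheets=_sheets(cfg, codes, labels, ages, "deployment", skip_mask, id_prefix="d"),
    )


def generate_paired(cfg: GeneratorConfig, n: int) -> list[tuple[ScoreSheet, ScoreSheet]]:
    """Same child answered under both settings: identical latent trait and
    per-question noise, so with zero shift and zero skip the two sheets agree
    exactly. Pairs are aligned by child_id."""
    if n < 1:
        raise ValidationError("n must be >= 1")
    rng = cfg.rng("paired")
    n_total = n
    labels = (rng.random(n_total) < cfg.n_case / max(cfg.n_case + cfg.n_control, 1)).astype(int)
    mu = np.where(labels == 1, cfg.class_separation, 0.0)
    t = rng.normal(mu, 1.0)
    eps = rng.normal(0.0, cfg.answer_noise, size=(n_total, cfg.n_questions))
    lo, hi = cfg.age_range_months
    ages = rng.integers(lo, hi + 1, size=n_total)
    src_codes = _codes_from_latent(cfg, t, eps, np.zeros(cfg.n_questions))
    dep_codes = _codes_from_latent(cfg, t, eps, cfg._shift)
    skip_mask = rng.random(dep_codes.shape) < cfg._skip[None, :]
    src = _sheets(cfg, src_codes, labels, ages, "training", id_prefix="p")
    dep = _sheets(cfg, dep_codes, labels, ages, "deployment", skip_mask, id_prefix="p")
    return list(zip(src, dep))


def baseline_screener_score(sheet: ScoreSheet, noise: float = 0.0,
                            rng: np.random.Generator | None = None) -> float:
    """Comparator screener: sum the non-SKIP codes, optionally perturbed.

    This is the scoring model of conventional instruments — codes are summed
    and the sum compared against a threshold.
    """
    answered = sheet.answered()
    if not answered:
        raise ValidationError(f"child {sheet.child_id!r}: all answers skipped")
    total = float(sum(answered.values()))
    if noise > 0:
        if rng is None:
            rng = np.random.default_rng()
        total += rng.normal(0.0, noise)
    return total
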