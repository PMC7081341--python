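"""Domain types and CSV/JSON I/O shared by every stage.

The universal record is a :class:`ScoreSheet`: one child's ordinal item
answers plus age, diagnostic label and cohort tag.  Skipped answers are a
distinct :data:`SKIP` marker, never conflated with severity 0 — downstream
noise maps and gradient-boosted learners rely on that distinction.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace

import pandas as pd

__all__ = [
    "SKIP",
    "AGE_SILO_BOUNDARY_MONTHS",
    "Question",
    "ScoreSheet",
    "Dataset",
    "ModuleResponse",
    "Outcome",
    "ValidationError",
    "read_scoresheets",
    "write_scoresheets",
    "read_schema",
    "write_schema",
    "split_by_age",
]

logger = logging.getLogger(__name__)

AGE_SILO_BOUNDARY_MONTHS = 48

#: Legacy instrument codes meaning "not applicable"; normalized to SKIP on read.
LEGACY_NA_CODES = frozenset({7, 8, 9})


class _SkipType:
    """Singleton marker for a skipped answer (distinct from severity 0)."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return "SKIP"

    def __reduce__(self):
        return (_SkipType, ())


SKIP = _SkipType()


class ValidationError(ValueError):
    """Raised when a score sheet or dataset violates its invariants."""


@dataclass(frozen=True)
class Question:
    """One ordinal questionnaire item."""

    id: str
    max_severity: int = 3
    allows_skip: bool = True

    def __post_init__(self):
        if self.max_severity < 1:
            raise ValidationError(f"question {self.id!r}: max_severity must be >= 1")


@dataclass
class ScoreSheet:
    """One child's answers plus demographics and (optional) diagnostic label."""

    child_id: str
    age_months: int
    label: int | None  # 1 = case, 0 = non-case, None = unknown
    cohort: str  # "training" | "deployment"
    answers: dict[str, object] = field(default_factory=dict)  # qid -> int | SKIP

    def __post_init__(self):
        if self.age_months < 0:
            raise ValidationError(f"child {self.child_id!r}: negative age")
        if self.label not in (0, 1, None):
            raise ValidationError(f"child {self.child_id!r}: label must be 0/1/None")
        if self.cohort not in ("training", "deployment"):
            raise ValidationError(f"child {self.child_id!r}: bad cohort {self.cohort!r}")

    def answered(self) -> dict[str, int]:
        """Non-SKIP answers only."""
        return {q: a for q, a in self.answers.items() if a is not SKIP}


@dataclass
class Dataset:
    """A question schema plus a list of score sheets, tagged with an age silo."""

    questions: list[Question]
    sheets: list[ScoreSheet]
    age_silo: str = "mixed"  # "under4" | "over4" | "mixed"

    def __post_init__(self):
        if self.age_silo not in ("under4", "over4", "mixed"):
            raise ValidationError(f"bad age_silo {self.age_silo!r}")
        self.validate()

    def validate(self) -> None:
        qmap = self.question_map()
        if len(qmap) != len(self.questions):
            raise ValidationError("duplicate question ids in schema")
        for i, sheet in enumerate(self.sheets):
            for qid, a in sheet.answers.items():
                if qid not in qmap:
                    raise ValidationError(
                        f"row {i} (child {sheet.child_id!r}): unknown question {qid!r}"
                    )
                if a is SKIP:
                    continue
                if not isinstance(a, int) or not 0 <= a <= qmap[qid].max_severity:
                    raise ValidationError(
                        f"row {i} (child {sheet.child_id!r}), question {qid!r}: "
                        f"answer {a!r} outside [0, {qmap[qid].max_severity}]"
                    )
            if self.age_silo == "under4" and sheet.age_months >= AGE_SILO_BOUNDARY_MONTHS:
                raise ValidationError(f"child {sheet.child_id!r} too old for under4 silo")
            if self.age_silo == "over4" and sheet.age_months < AGE_SILO_BOUNDARY_MONTHS:
                raise ValidationError(f"child {sheet.child_id!r} too young for over4 silo")

    def question_map(self) -> dict[str, Question]:
        return {q.id: q for q in self.questions}

    def question_ids(self) -> list[str]:
        return [q.id for q in self.questions]

    def labels(self) -> list[int | None]:
        return [s.label for s in self.sheets]

    def __len__(self) -> int:
        return len(self.sheets)

    def to_frame(self) -> pd.DataFrame:
        """Tabular view: one row per child, NaN for SKIP / unanswered."""
        qids = self.question_ids()
        rows = []
        for s in self.sheets:
            row = {
                "child_id": s.child_id,
                "age_months": s.age_months,
                "label": s.label,
                "cohort": s.cohort,
            }
            for qid in qids:
                a = s.answers.get(qid, SKIP)
                row[qid] = float(a) if a is not SKIP else float("nan")
            rows.append(row)
        cols = ["child_id", "age_months", "label", "cohort", *qids]
        return pd.DataFrame(rows, columns=cols)

    def subset_questions(self, qids: list[str]) -> "Dataset":
        keep = set(qids)
        qmap = self.question_map()
        questions = [qmap[q] for q in qids]
        sheets = [
            replace(s, answers={q: a for q, a in s.answers.items() if q in keep})
            for s in self.sheets
        ]
        return Dataset(questions=questions, sheets=sheets, age_silo=self.age_silo)


@dataclass(frozen=True)
class ModuleResponse:
    """One module's score for one child; an entry of the response vector."""

    child_id: str
    score: float

    def __post_init__(self):
        if not 0.0 <= self.score <= 1.0:
            raise ValidationError(f"score {self.score} outside [0, 1]")


@dataclass(frozen=True)
class Outcome:
    """Three-way verdict for one child."""

    child_id: str
    verdict: str  # "positive" | "negative" | "inconclusive"
    score: float | None = None

    def __post_init__(self):
        if self.verdict not in ("positive", "negative", "inconclusive"):
            raise ValidationError(f"bad verdict {self.verdict!r}")


_META_COLUMNS = ["child_id", "age_months", "label", "cohort"]


def read_scoresheets(path, schema: list[Question]) -> Dataset:
    """Read a score-sheet CSV against a question schema.

    Empty cells are SKIP.  Legacy "not applicable" codes (7/8/9 above a
    question's severity range) are normalized to SKIP with a logged count.
    Any other out-of-range code raises :class:`ValidationError` naming the
    row and question.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    qmap = {q.id: q for q in schema}
    expected = set(_META_COLUMNS) | set(qmap)
    unknown = [c for c in df.columns if c not in expected]
    if unknown:
        raise ValidationError(f"unknown columns: {unknown}")
    missing = [c for c in _META_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"missing columns: {missing}")

    qids = [c for c in df.columns if c in qmap]
    n_legacy = 0
    sheets = []
    for i, row in enumerate(df.itertuples(index=False)):
        rec = dict(zip(df.columns, row))
        answers: dict[str, object] = {}
        for qid in qids:
            cell = rec[qid].strip()
            if cell == "":
                answers[qid] = SKIP
                continue
            try:
                code = int(cell)
            except ValueError:
                raise ValidationError(
                    f"row {i}, question {qid!r}: non-integer code {cell!r}"
                ) from None
            if code > qmap[qid].max_severity and code in LEGACY_NA_CODES:
                answers[qid] = SKIP
                n_legacy += 1
            elif 0 <= code <= qmap[qid].max_severity:
                answers[qid] = code
            else:
                raise ValidationError(
                    f"row {i}, question {qid!r}: code {code} outside "
                    f"[0, {qmap[qid].max_severity}]"
                )
        label_cell = rec["label"].strip()
        sheets.append(
            ScoreSheet(
                child_id=rec["child_id"],
                age_months=int(rec["age_months"]),
                label=int(label_cell) if label_cell != "" else None,
                cohort=rec["cohort"],
                answers=answers,
            )
        )
    if n_legacy:
        logger.info("normalized %d legacy not-applicable codes to SKIP", n_legacy)
    return Dataset(questions=[qmap[q] for q in qids] or list(schema), sheets=sheets)


def write_scoresheets(ds: Dataset, path) -> None:
    """Write a Dataset as CSV; SKIP becomes an empty cell. Round-trip exact."""
    qids = ds.question_ids()
    records = []
    for s in ds.sheets:
        rec = {
            "child_id": s.child_id,
            "age_months": s.age_months,
            "label": "" if s.label is None else s.label,
            "cohort": s.cohort,
        }
        for qid in qids:
            a = s.answers.get(qid, SKIP)
            rec[qid] = "" if a is SKIP else a
        records.append(rec)
    df = pd.DataFrame(records, columns=_META_COLUMNS + qids)
    df.to_csv(path, index=False)


def read_schema(path) -> list[Question]:
    """Instrument schema JSON: list of {id, max_severity, allows_skip}."""
    with open(path) as fh:
        raw = json.load(fh)
    return [
        Question(
            id=item["id"],
            max_severity=int(item.get("max_severity", 3)),
            allows_skip=bool(item.get("allows_skip", True)),
        )
        for item in raw
    ]


def write_schema(questions: list[Question], path) -> None:
    with open(path, "w") as fh:
        json.dump(
            [
                {"id": q.id, "max_severity": q.max_severity, "allows_skip": q.allows_skip}
                for q in questions
            ],
            fh,
            indent=2,
        )
        fh.write("\n")


def split_by_age(ds: Dataset) -> tuple[Dataset, Dataset]:
    """Partition at 48 months; 48 goes to the older silo. Order preserved."""
    under = [s for s in ds.sheets if s.age_months < AGE_SILO_BOUNDARY_MONTHS]
    over = [s for s in ds.sheets if s.age_months >= AGE_SILO_BOUNDARY_MONTHS]
    return (
        Dataset(questions=list(ds.questions), sheets=under, age_silo="under4"),
        Dataset(questions=list(ds.questions), sheets=over, age_silo="over4"),
    )
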