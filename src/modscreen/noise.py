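"""Setting-noise probability maps estimated from paired sheets, applied as a
stochastic transform.

For each question a conditional table P(deployment answer or SKIP | source
answer) is tallied from paired records of the same child answered under the
two settings.  Applying the map to clean training data yields a dataset that
behaves as if it had been collected in the deployment setting.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

from .core import SKIP, Dataset, ScoreSheet, ValidationError

__all__ = ["NoiseMap", "estimate_noise_map", "inject_noise"]

_SKIP_KEY = "SKIP"


@dataclass
class NoiseMap:
    """Per-question conditional tables over (source code) x (deployment code + SKIP).

    ``probs[qid]`` has shape (max_severity+1, max_severity+2); the last column
    is the SKIP outcome.  Every row sums to 1.
    """

    probs: dict[str, np.ndarray]
    counts: dict[str, np.ndarray] = field(default_factory=dict)
    smoothing_alpha: float = 0.0

    def __post_init__(self):
        for qid, table in self.probs.items():
            table = np.asarray(table, dtype=float)
            self.probs[qid] = table
            if np.any(table < 0):
                raise ValidationError(f"question {qid!r}: negative probability")
            if not np.allclose(table.sum(axis=1), 1.0, atol=1e-9):
                raise ValidationError(f"question {qid!r}: rows must sum to 1")

    def n_codes(self, qid: str) -> int:
        """Number of source codes (max_severity + 1)."""
        return self.probs[qid].shape[0]

    def skip_column(self, qid: str) -> int:
        return self.probs[qid].shape[1] - 1

    def to_json(self, path) -> None:
        payload = {
            "smoothing_alpha": self.smoothing_alpha,
            "probs": {
                qid: {
                    str(s): {
                        (_SKIP_KEY if d == self.skip_column(qid) else str(d)): float(p)
                        for d, p in enumerate(row)
                    }
                    for s, row in enumerate(table)
                }
                for qid, table in self.probs.items()
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "NoiseMap":
        with open(path) as fh:
            payload = json.load(fh)
        probs = {}
        for qid, rows in payload["probs"].items():
            n_src = len(rows)
            table = np.zeros((n_src, n_src + 1))
            for s_key, outcomes in rows.items():
                s = int(s_key)
                for d_key, p in outcomes.items():
                    d = n_src if d_key == _SKIP_KEY else int(d_key)
                    table[s, d] = p
            probs[qid] = table
        return cls(probs=probs, smoothing_alpha=payload.get("smoothing_alpha", 0.0))


def _identity_row(n_out: int, source_code: int) -> np.ndarray:
    row = np.zeros(n_out)
    row[source_code] = 1.0
    return row


def estimate_noise_map(
    pairs: list[tuple[ScoreSheet, ScoreSheet]], smoothing_alpha: float = 0.5
) -> NoiseMap:
    """Tally deployment responses conditional on source responses.

    Rows are Laplace-smoothed with ``smoothing_alpha``; a source code never
    observed at all falls back to the identity (pass-through) row.  Pairs
    where the source answer is SKIP do not contribute (source SKIPs pass
    through unchanged at injection time).
    """
    if not pairs:
        raise ValidationError("need at least one pair")
    qids = sorted({q for src, _ in pairs for q in src.answers})
    for src, dep in pairs:
        if set(src.answers) != set(dep.answers):
            raise ValidationError(
                f"child {src.child_id!r}: paired sheets answer different questions"
            )

    # infer code range per question from the data
    max_code: dict[str, int] = {}
    for qid in qids:
        codes = [
            a
            for src, dep in pairs
            for a in (src.answers.get(qid), dep.answers.get(qid))
            if a is not None and a is not SKIP
        ]
        max_code[qid] = max(codes, default=0)

    counts: dict[str, np.ndarray] = {}
    probs: dict[str, np.ndarray] = {}
    for qid in qids:
        n_src = max_code[qid] + 1
        n_out = n_src + 1  # + SKIP column
        tally = np.zeros((n_src, n_out))
        for src, dep in pairs:
            s = src.answers.get(qid)
            if s is None or s is SKIP:
                continue
            d = dep.answers.get(qid)
            col = n_src if d is SKIP else int(d)
            tally[int(s), col] += 1
        table = np.empty_like(tally)
        for s in range(n_src):
            total = tally[s].sum()
            if total == 0:
                table[s] = _identity_row(n_out, s)
            else:
                table[s] = (tally[s] + smoothing_alpha) / (
                    total + smoothing_alpha * n_out
                )
        counts[qid] = tally
        probs[qid] = table
    return NoiseMap(probs=probs, counts=counts, smoothing_alpha=smoothing_alpha)


def inject_noise(ds: Dataset, noise_map: NoiseMap, seed: int, replicates: int = 1) -> Dataset:
    """Resample every answer independently from its question's conditional row.

    SKIP draws become SKIP markers; source SKIPs pass through unchanged.
    Labels, ages and child ids are untouched.  ``replicates`` > 1 appends
    extra resampled copies of each sheet (data-augmentation multiplicity).
    """
    rng = np.random.default_rng(seed)
    new_sheets: list[ScoreSheet] = []
    for rep in range(replicates):
        for sheet in ds.sheets:
            answers: dict[str, object] = {}
            for qid, a in sheet.answers.items():
                if a is SKIP:
                    answers[qid] = SKIP
                    continue
                if qid not in noise_map.probs:
                    answers[qid] = a
                    continue
                table = noise_map.probs[qid]
                if not 0 <= a < table.shape[0]:
                    raise ValidationError(
                        f"child {sheet.child_id!r}, question {qid!r}: "
                        f"code {a} outside noise-map range [0, {table.shape[0] - 1}]"
                    )
                draw = rng.choice(table.shape[1], p=table[a])
                answers[qid] = SKIP if draw == table.shape[1] - 1 else int(draw)
            child_id = sheet.child_id if replicates == 1 else f"{sheet.child_id}r{rep}"
            new_sheets.append(replace(sheet, child_id=child_id, answers=answers))
    return Dataset(questions=list(ds.questions), sheets=new_sheets, age_silo=ds.age_silo)
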