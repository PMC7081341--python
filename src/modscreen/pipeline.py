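"""End-to-end driver: generate -> noise-inject -> feature-select -> train
cascades per age silo -> combine -> evaluate, from one JSON config.

Three synthetic modules give the combination stage genuinely heterogeneous
inputs: a parent-like module (clean answers, shift-rejected feature set), a
video-like module (trained on noise-injected data), and a clinician-like
module (reduced question set from the perturbation-sensitivity shortlist).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cascade as casc
from . import combine as comb
from . import evaluate as ev
from . import featsel, noise
from .core import Dataset, ValidationError, split_by_age, write_schema, write_scoresheets
from .synthgen import GeneratorConfig, baseline_screener_score, generate_deployment, \
    generate_paired, generate_training

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    train: casc.TrainConfig = field(default_factory=casc.TrainConfig)
    target_sensitivity: float = 0.9
    max_inconclusive: float = 0.3
    n_paired: int = 400
    n_boot: int = 2000
    smoothing_alpha: float = 0.5
    shortlist_top_k: int = 7
    seed: int = 0
    output_dir: str = "pipeline_out"

    def __post_init__(self):
        if not 0 <= self.max_inconclusive < 1:
            raise ValidationError("max_inconclusive must be in [0, 1)")

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = json.load(fh)
        gen = GeneratorConfig(**raw.pop("generator", {}))
        train = casc.TrainConfig(**raw.pop("train", {}))
        return cls(generator=gen, train=train, **raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _train_silo_cascades(ds: Dataset, cfg: PipelineConfig, feature_ids, tag: str):
    """One cascade per populated age silo; returns {silo: model}."""
    models = {}
    for silo_ds in split_by_age(ds):
        if len(silo_ds) == 0 or len(set(silo_ds.labels())) < 2:
            continue
        model = casc.train_cascade(silo_ds, cfg.train, feature_ids=feature_ids)
        model = casc.tune_thresholds(
            model, silo_ds, cfg.target_sensitivity, cfg.max_inconclusive
        )
        models[silo_ds.age_silo] = model
        logger.info("%s cascade trained for silo %s (n=%d)", tag, silo_ds.age_silo,
                    len(silo_ds))
    if not models:
        raise ValidationError(f"{tag}: no silo had both classes")
    return models


def _score_with_silos(models: dict, ds: Dataset) -> np.ndarray:
    """Binary-model scores for every sheet, routed to its silo's cascade."""
    scores = np.full(len(ds.sheets), np.nan)
    for silo_ds in split_by_age(ds):
        if len(silo_ds) == 0:
            continue
        model = models.get(silo_ds.age_silo) or next(iter(models.values()))
        silo_scores = model.binary_scores(silo_ds)
        ids = {s.child_id: i for i, s in enumerate(ds.sheets)}
        for sheet, sc in zip(silo_ds.sheets, silo_scores):
            scores[ids[sheet.child_id]] = sc
    return scores


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run the full demo pipeline; returns the manifest (file -> sha256)."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def save_json(name: str, payload) -> None:
        path = out / name
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")
        written.append(path)

    # -- stage: data generation
    gen = cfg.generator
    train_ds = generate_training(gen)
    deploy_ds = generate_deployment(gen)
    pairs = generate_paired(gen, cfg.n_paired)
    for name, ds in (("training.csv", train_ds), ("deployment.csv", deploy_ds)):
        write_scoresheets(ds, out / name)
        written.append(out / name)
    write_schema(train_ds.questions, out / "schema.json")
    written.append(out / "schema.json")

    # -- stage: noise map from paired records
    nmap = noise.estimate_noise_map(pairs, smoothing_alpha=cfg.smoothing_alpha)
    nmap.to_json(out / "noise_map.json")
    written.append(out / "noise_map.json")
    noisy_train = noise.inject_noise(train_ds, nmap, seed=cfg.seed + 101)

    # -- stage: shift-based feature rejection (parent-like module)
    report = featsel.shift_reject(train_ds, deploy_ds)
    report.table.to_csv(out / "shift_report.csv")
    written.append(out / "shift_report.csv")
    parent_features = report.kept or train_ds.question_ids()

    # -- stage: cascades per silo
    parent_models = _train_silo_cascades(train_ds, cfg, parent_features, "parent")
    video_models = _train_silo_cascades(noisy_train, cfg, None, "video")

    # clinician-like shortlist from perturbation sensitivity of the parent model
    ref_silo = "under4" if "under4" in parent_models else next(iter(parent_models))
    ref_model = parent_models[ref_silo]
    score_fn = ref_model.binary_scores
    thr = ref_model.decision_threshold
    band_a = featsel.perturb_rank(score_fn, train_ds.subset_questions(parent_features),
                                  thr, (0.0, 0.1))
    band_b = featsel.perturb_rank(score_fn, train_ds.subset_questions(parent_features),
                                  thr, (0.1, 0.3))
    imp = band_a.ranked_ids  # importance proxy ranking
    clin_features = featsel.shortlist_clinician(imp, band_a, band_b,
                                                top_k=cfg.shortlist_top_k)
    save_json("clinician_features.json", clin_features)
    clinician_models = _train_silo_cascades(train_ds, cfg, clin_features, "clinician")

    # -- stage: module responses on the deployment cohort
    labels = pd.Series(
        [s.label for s in deploy_ds.sheets],
        index=pd.Index([s.child_id for s in deploy_ds.sheets], name="child_id"),
        name="label",
    )
    responses = pd.DataFrame(
        {
            "parent": _score_with_silos(parent_models, deploy_ds),
            "video": _score_with_silos(video_models, deploy_ds),
            "clinician": _score_with_silos(clinician_models, deploy_ds),
        },
        index=labels.index,
    )
    resp_long = responses.reset_index().melt(
        id_vars="child_id", var_name="module_id", value_name="score"
    ).merge(labels.reset_index(), on="child_id")
    resp_long.to_csv(out / "responses.csv", index=False)
    written.append(out / "responses.csv")

    # -- stage: combination with LOO covariance + band tuning
    cmodel = comb.fit_combination(responses, labels)
    cmodel = comb.tune_band(
        cmodel, labels=labels,
        target_sensitivity=cfg.target_sensitivity,
        max_inconclusive=cfg.max_inconclusive,
    )
    cmodel.to_json(out / "combination_model.json")
    written.append(out / "combination_model.json")
    combined = cmodel.loo_responses
    outcomes = [comb.banded_outcome(cmodel, r, cid) for cid, r in combined.items()]

    # -- stage: evaluation vs the sum-score baseline screener
    rng = np.random.default_rng(cfg.seed + 202)
    baseline = np.array(
        [baseline_screener_score(s, gen.baseline_screener_noise, rng)
         for s in deploy_ds.sheets]
    )
    y = labels.to_numpy()
    reports = {
        "baseline": ev.roc_auc(baseline, y).to_dict(),
        "combined_loo": ev.roc_auc(combined.to_numpy(), y).to_dict(),
        "combined_conclusive": ev.conclusive_metrics(outcomes, y).to_dict(),
    }
    for mod in responses.columns:
        reports[mod] = ev.roc_auc(responses[mod].to_numpy(), y).to_dict()
    delta = ev.bootstrap_delta(
        baseline, combined.to_numpy(), y, n_boot=cfg.n_boot, seed=cfg.seed + 303
    )
    reports["delta_combined_vs_baseline"] = delta.to_dict()
    save_json("eval_reports.json", reports)
    logger.info("evaluation reports written")

    manifest = {p.name: _sha256(p) for p in sorted(written)}
    save_json("manifest.json", manifest)
    return manifest
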