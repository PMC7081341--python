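# modscreen

Modular, abstention-capable screening on ordinal questionnaire data.

The package implements a complete methodology for building and evaluating
multi-module diagnostic screeners that may answer "inconclusive":

- **`modscreen.core`** — domain types (ordinal questions, score sheets with a
  first-class SKIP marker, 48-month age silos) and CSV/JSON I/O.
- **`modscreen.synthgen`** — a graded-response latent-trait generator
  producing training cohorts, deployment cohorts with per-question severity
  drift and skips, and paired two-setting records; plus the conventional
  sum-score baseline screener.
- **`modscreen.noise`** — per-question conditional probability maps
  P(deployment answer or skip | source answer) estimated from paired data and
  applied as a stochastic transform to training data.
- **`modscreen.featsel`** — distribution-shift feature rejection (class-
  averaged mean-severity difference vs 3 standard errors), perturbation-
  sensitivity question ranking near the decision threshold, candidate-list
  shortlisting, and a generic bootstrapped backward elimination.
- **`modscreen.cascade`** — three-run training of an inconclusive filter plus
  final binary classifier (gradient-boosted trees, label-stratified folds,
  (age, label) weight balancing, bootstrapped grid search), with sequential
  threshold tuning under a coverage allowance.
- **`modscreen.combine`** — inverse-covariance pooling of module scores with
  leave-one-out covariance estimation and dual-threshold banding.
- **`modscreen.evaluate`** — ROC/AUC, specificity at a target sensitivity,
  coverage-aware metrics, and paired bootstrap comparisons (mean and
  [5%, 95%] percentile CIs of ΔAUC and ΔSpecificity at 90% sensitivity).
- **`modscreen.pipeline` / `modscreen.cli`** — an end-to-end driver wiring
  three heterogeneous synthetic modules (clean "parent", noise-injected
  "video", reduced-feature "clinician") into the combination stage.

## Tests

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the end-to-end statistical checks (oracle
equivalence of the pooling formula, abstention/combination/noise-injection
benefits, shift-rejection operating characteristics, bootstrap calibration,
tuner-vs-sweep agreement); the rest are per-module unit and property tests.
The full suite takes a few minutes on one CPU.

## CLI

```bash
# generate synthetic training/deployment/paired data
assess synthgen --out data/ --n-paired 400

# estimate a setting-noise map from paired sheets and apply it
assess noise-estimate --source data/paired_source.csv \
    --deployment data/paired_deployment.csv --schema data/schema.json \
    --out map.json
assess noise-inject --data data/training.csv --schema data/schema.json \
    --map map.json --seed 1 --out noisy.csv

# distribution-shift feature rejection
assess featsel shift --train data/training.csv --deploy data/deployment.csv \
    --schema data/schema.json --out shift.csv

# train / tune / predict a cascade
assess cascade train --data data/training.csv --schema data/schema.json \
    --out model.pkl
assess cascade tune --model model.pkl --data data/training.csv \
    --schema data/schema.json --out tuned.pkl
assess cascade predict --model tuned.pkl --data data/deployment.csv \
    --schema data/schema.json --out outcomes.csv

# full pipeline from one JSON config
assess run --config pipeline.json
```

The pipeline config JSON mirrors `modscreen.pipeline.PipelineConfig`; any
omitted field uses its default. All stages derive their randomness from the
single top-level seed, and re-running a pipeline with the same config
reproduces identical output hashes (see `manifest.json` in the output
directory).

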