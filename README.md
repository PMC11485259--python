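# lipidscore

Toolkit for deriving, porting and evaluating intervention-derived multilipid
scores. It implements, end to end on synthetic data with known ground truth:

- **Synthetic data** (`lipidscore.synth`): sparse-precision log-normal
  lipidomes, two-arm/two-visit trials with additive arm effects, cohorts
  with proportional-hazards outcomes driven by a latent score, case-cohort
  and 1:1-matched sampling, repeated measures, second-platform aggregation
  and macronutrient tables coupled to the score.
- **Lipid data model** (`lipidscore.lipids`): lipid name grammar across 16
  classes and three resolutions (molecular species, isobaric species,
  within-class fatty-acid sums), aggregation, >70%-missing filtering,
  left-censored imputation (QRILC-like or half-minimum), scalar dilution
  correction and the natural-log transform.
- **Trial effects** (`lipidscore.effects`): per-lipid baseline-adjusted arm
  effects (OLS on log concentrations), Benjamini–Hochberg FDR, and score
  component selection (weights = estimated effects).
- **Score engine** (`lipidscore.scoring`): weighted-sum scores, scaling to
  the trial intervention contrast or to a reference-sample s.d.,
  sub-scores, and cross-platform reduction (skip-or-impute with regression
  weights learned in a reference dataset carrying both resolutions).
- **Cohort association** (`lipidscore.assoc`): Prentice-weighted Cox for
  case-cohort designs (age time scale, robust dfbeta sandwich with an
  optional finite-sampling variance correction), conditional logistic
  regression for 1:1 matched designs, 10-year-change analysis, three-way
  effect-modification testing with median-stratified fits, and Spearman
  correlation tables.
- **Substitution & diet scores** (`lipidscore.diet`): isocaloric
  leave-one-out macronutrient substitution models (per 8 %E), LCD (0–30,
  total/animal/vegetable), aMed (0–9) and AHEI (0–110, config cut-offs).
- **Network analysis** (`lipidscore.network`): order-independent (stable)
  PC skeleton with Fisher-z partial-correlation tests, Louvain clusters,
  cluster-specific scores (exactly additive to the full score), and
  NetCoupler-style direct-effect classification over all neighbor subsets.
- **Pipeline & CLI** (`lipidscore.pipeline`, `lipidscore.cli`): seeded,
  byte-reproducible end-to-end runs with presets.

## CLI

```sh
lipidscore simulate --preset divas-like --seed 1 --out work/trial
lipidscore derive-effects --trial-dir work/trial --out work/effects.tsv
lipidscore build-score --effects-table work/effects.tsv --trial-dir work/trial \
    --out work/score.json
lipidscore score --matrix work/trial/trial_post.tsv --definition work/score.json \
    --out work/scores.tsv
lipidscore run --seed 1 --preset divas-like --out-dir work/run   # full pipeline
lipidscore network --matrix work/trial/trial_baseline.tsv --out work/edges.tsv
```

All tables are TSV, definitions and metadata JSON; reruns with the same seed
and config are byte-identical. Additional subcommands: `preprocess`,
`reduce-score`, `associate` (case-cohort / matched / change / interaction
designs), `substitute`, `dietscore`, `report`.

## Notes and conventions

- Within-class fatty-acid sums count a fatty acid once per chain carrying
  it (a double-chain species contributes twice); sums are always taken on
  concentrations, never on log values.
- The missingness filter uses a strict inequality (more than 70% missing).
- Higher score = intervention-like lipidome: selected effects are negative,
  so the weighted sum rises under the intervention.
- The QRILC-like imputation is a simplified reimplementation of the
  quantile-regression idea (normal fit via order statistics + truncated
  left-tail draws), not a port of the R package.
- Default covariate distributions, precision-matrix magnitudes and AHEI
  cut-offs are documented assumptions (see module docstrings), not
  calibrations to any study.
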