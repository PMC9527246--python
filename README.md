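# schemasim

A tested re-implementation of a schema-memory consolidation fMRI analysis
pipeline, exercised end-to-end on a synthetic cohort generator with known
ground truth. The package covers:

- **`schemasim.design`** — stimulus-list construction (two 80-pair lists with
  a fixed congruent/incongruent composition over four repeating scenes) and
  encoding/retrieval schedules with timing and a no-adjacent-same-scene
  constraint.
- **`schemasim.behavior`** — operationalized congruency from encoding
  judgments (majority of three), detailed/coarse/forgotten memory-grain
  scoring, percent-correct metrics, and delay-local below-chance (<33%)
  exclusions.
- **`schemasim.cohort`** — synthetic cohorts: per-trial outcomes from
  P(grain | congruency, delay), trial-level ROI patterns built from shared
  context/scene/item components, BOLD runs via double-gamma HRF convolution
  with AR(1) noise/drift/motion spikes, and pre/post rest scans whose
  coupling change is linked to memory scores.
- **`schemasim.estimation`** — least-squares-single (LSS) trial estimation:
  framewise displacement and scrubbing, per-trial design matrices (target +
  up-to-five trial-type nuisance regressors + response windows + 6 motion +
  spike columns), per-voxel OLS t-maps.
- **`schemasim.similarity`** — z-scored patterns, Fisher-transformed Pearson
  similarity under the congruency (within/across context) and granularity
  (same/similar/other-context scene) pairing schemes, restricted to
  cross-run, within-congruency pairs; forgotten-trial variants; univariate
  ROI-mean control.
- **`schemasim.connectivity`** — rest preprocessing (volume trimming,
  artifact flags, aCompCor, motion + derivative + spike regression,
  0.008–0.09 Hz band-pass), inter-ROI Fisher-z coupling deltas, one-tailed
  brain-behavior correlation, and Williams' test for dependent correlations.
- **`schemasim.stats`** — REML mixed models (random participant intercepts,
  with an attempted counterbalancing-group random-slope structure), Wald F
  tests, a Shapiro/Levene → sqrt-transform → variance-weight rule engine,
  estimated marginal means, pairwise contrasts, and Morey within-subject
  error bars.

## CLI

```sh
schemasim design   --seed 1 --out out/design
schemasim simulate --seed 1 --out out/sim            # behavioral cohort
schemasim score    --responses out/sim/outcomes.csv --out out/scores.csv
schemasim estimate --data <dir> --out <dir> [--use-beta]
schemasim similarity --patterns patterns.npy --outcomes meta.csv \
    --scheme congruency --roi mpfc --out similarity.csv
schemasim connectivity --pre <dir> --post <dir> --scores scores.csv \
    --tail one --out out/conn
schemasim stats    --table similarity.csv --model mpfc-congruency --out out/stats
```

## Notes

- All synthetic-effect sizes are artifact choices calibrated only to the
  qualitative shape of the published results; no real-data fitting is
  claimed or possible (raw data are protected).
- Denominator degrees of freedom use a residual (containment-style)
  fallback, labeled `df_method="residual"` in every output, since a
  Satterthwaite implementation is not available in the backend.
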