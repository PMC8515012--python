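# funcfeat

Grounding behavioral model predictions in interpretable generative-model
features, exercised end to end on synthetic data with known ground
truth. The package implements, as a tested reusable pipeline:

- **`funcfeat.gmf`** — a generative model of 3D faces: a demographic
  GLM (constant, sex, age, 2 ethnicity dummies, and all two-/three-way
  interactions — 12 columns for the full factor set) plus an orthogonal
  SVD basis of the residuals. Synthesis, projection, and construction of
  amplified / diagnostic faces. PLY vertex-cloud I/O and model
  serialization.
- **`funcfeat.synth`** — synthetic stand-ins for everything a human
  study would measure: face databases with planted low-rank structure,
  random stimulus sets, simulated observers (choose-1-of-6 plus a
  6-point rating driven by a hidden template), embedding predictor
  spaces with configurable shape/texture fidelity, and enumerators for
  the experiment design and the factorial rendering grid.
- **`funcfeat.forward`** — forward models from any predictor space to
  single-trial ratings: closed-form ridge with one L2 penalty per
  predictor subspace, nested cross-validation over consecutive
  200-trial blocks (9 outer x 8 inner folds at full scale), penalties
  tuned to maximize Kendall's tau-b by a deterministic log2-grid search
  initialized at 2^17 within [2^-30, 2^30]; shape-receptive-field
  extraction and re-prediction of embedding-model predictions; linear
  decoding of shape components scored as a per-vertex error map.
- **`funcfeat.infotheory`** — equipopulated binning (3 bins by
  default), Miller-Madow-corrected mutual information, redundancy via
  pointwise common change in surprisal on a maximum-entropy joint
  constrained by pairwise marginals, permutation noise thresholds and
  exceedance summaries.
- **`funcfeat.revcor`** — reverse correlation: mass-univariate
  regression of stimulus features on responses (OLS or robust
  bisquare), amplification tuning curves on a 0–50 grid (step 0.5),
  and template quality metrics (MAE and inward-outward correlation).
- **`funcfeat.generalization`** — faithfulness classification, NMF
  diagnostic components (C_D, with C_N = 1 − C_D), the 2 x 5 x 5
  generalization stimulus builder (50 stimuli per target), simulated
  identification with within-target min-max normalization, and
  accuracy-error summaries.
- **`funcfeat.pipeline`** — YAML-configured orchestration of all
  stages with explicit seeds, provenance, TSV/figure reporting, and a
  CLI.

## CLI

```sh
funcfeat run-all --profile tiny --out runs/demo        # all stages
funcfeat generate --profile tiny --out runs/demo       # single stage
funcfeat report --profile tiny --out runs/demo
funcfeat run-all --config my_config.yaml --seed 7 --out runs/custom
```

Stages (`generate`, `fit`, `evaluate`, `revcor`, `generalize`,
`report`) communicate only through serialized artifacts in the run
directory, so they can be run separately and in different processes.
The `tiny` profile (4 observers x 2 targets x 180 trials) finishes in
under a minute on one CPU; `paper-scale` mirrors the full design
(14 observers x 4 targets x 1,800 trials).

## Notes on modeling choices

- Identity components are stored unit-variance; synthesis multiplies by
  `s / sqrt(N - 1)`.
- Observer ratings are 6-quantile bins of the chosen face's (noisy)
  template similarity within a session — a monotone rating model with
  near-uniform scale usage.
- Ridge penalty tuning is deterministic (coarse log2 grid plus
  coordinate-wise refinement, 200-evaluation cap) rather than a
  stochastic black-box optimizer; ties resolve to the smallest penalty.
- The redundancy measure's maximum-entropy step uses iterative
  proportional fitting with LP-based support detection; the test suite
  ships an independent dual-space oracle that the fast path must match
  on small alphabets.
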