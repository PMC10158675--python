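# modsew — MODS early-warning pipeline

`modsew` is a tested, reusable pipeline for hourly early warning of multiple
organ dysfunction syndrome (MODS) in ICU patients. It covers the full chain:

- **`modsew.synthetic`** — seeded synthetic ICU cohorts (long-format
  observation tables over eight clinical variables) with analytically known
  MODS onsets, so every downstream stage is testable without access to a
  credentialed clinical database.
- **`modsew.scoring`** — per-organ 0–4 dysfunction sub-scores from clinical
  values (the cardiovascular score is the max of the dopamine-, lactate- and
  heart-rate-mapped scores) and onset detection (first hour with ≥ 2 organs
  at sub-score ≥ 2; both thresholds configurable). Band cut-points ship as a
  YAML config (`src/modsew/data/score_table.default.yaml`); the defaults are
  Marshall-style **placeholders** — drop in your own table to change them.
- **`modsew.features`** — cohort filters (age ≥ 65, first ICU stay > 24 h,
  missing-feature rate < 30 %), forward/backward-fill imputation of clinical
  aggregates (sub-scores are recomputed, never imputed), and exactly **37
  features** per patient-hour: mean/max/min of 8 variables (24), elapsed ICU
  hour (1), six current organ sub-scores and six trailing-24-h rolling
  maxima. Labels mark entries within a 12-hour horizon of onset. Gaussian
  normalization is fitted on the training split only; splits are strictly
  patient-level.
- **`modsew.learners`** — a nine-algorithm catalog behind a uniform
  fit/predict-probability contract, with inverse-frequency class weighting.
  The ninth member is a deep–wide network implemented in NumPy: dense blocks
  with batch normalization whose outputs are *all* concatenated (plus the
  raw input) into a single sigmoid unit. The two gradient-boosting slots are
  backed by scikit-learn's `GradientBoostingClassifier` and
  `HistGradientBoostingClassifier` in this offline build.
- **`modsew.ensemble`** — two stacked topologies (a two-layer stack with 8
  base slots + 1 meta, and a three-layer variant) whose 9 slots are each
  assigned one of the 9 algorithms (9⁹ = 387,420,489 possibilities) by an
  ε-greedy tabular Q-learning search (defaults α=0.1, γ=0.85, ε=0.9) with a
  memoized validation-AUC reward. Meta learners train on out-of-fold base
  probabilities to avoid stacking leakage.
- **`modsew.metrics`** — accuracy/sensitivity/specificity/Youden index,
  rank-based AUC, and a normalized, time-dependent **utility score**:
  alarms near onset earn a piecewise-linear reward, false alarms and missed
  detections are penalized, and the total is normalized so a silent policy
  scores 0 and the optimal alarm policy scores exactly 1.
- **`modsew.shap_explain`** — model-agnostic Kernel-SHAP with marginal
  masking over a frozen, checksummed background set, exact efficiency
  (base value + attributions = model output), and a brute-force
  exact-Shapley oracle (M ≤ 12) used to validate the estimator.
- **`modsew.counterfactuals`** — diverse counterfactual recommendations
  that flip a positive prediction: seeded derivative-free search with
  rule-based repair (sub-scores always consistent with their governing raw
  aggregates, rolling ≥ current, min ≤ mean ≤ max), a determinantal
  diversity term, and a post-hoc rule screen.

## CLI

```bash
modsew pipeline --seed 1 --out-dir runs/demo \
    --set simulate.n_patients=50 --set compose.episodes=25
```

Commands: `simulate`, `featurize`, `train`, `compose`, `evaluate`,
`explain`, `counterfact`, `pipeline` (chains everything). Configuration is
YAML (JSON accepted) with unknown keys rejected; `--set key.sub=value`
overrides individual fields and `--seed` propagates to every stage. Each
run writes plain CSV/JSON artifacts plus `run_manifest.json` recording the
config hash, seed, version and artifact checksums; identical configs yield
identical metrics.

## Caveats

- The exact severity-band cut-points and the exact utility breakpoints of
  the reference implementation are not published; both are configuration
  here (`score_table` YAML, `evaluate.utility` block) with documented
  defaults.
- Real clinical datasets (MIMIC-III/IV) require credentialed access and are
  out of scope; the synthetic generator stands in for them.
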