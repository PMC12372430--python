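# paincat

Graded-response-model (GRM) tooling for patient-reported sleep-quality and
quality-of-life item banks in chronic pain: item calibration, pre-calibration
screening, a computerized-adaptive-testing (CAT) engine, score equating, and
a synthetic-data simulation harness.

## What it does

- **`paincat.item_model`** — domain types (`Item`, `ItemBank`,
  `ResponseMatrix`) with JSON/CSV I/O, category inversion, numeric-rating
  pain banding (0 / 1–3 / 4–6 / 7–10), and empirical quantile splits.
- **`paincat.grm_core`** — Samejima GRM probabilities, Fisher information,
  likelihoods and response sampling (pure logistic metric, no 1.7 scaling
  constant), plus a vectorized bank view used by the heavier machinery.
- **`paincat.calibration`** — marginal maximum-likelihood EM calibration
  under a N(0, 1) latent prior with a fixed 61-node quadrature on [-6, 6],
  outer-product-of-gradients standard errors, and EAP person scores.
- **`paincat.screening`** — mixed Pearson/polychoric/polyserial correlation
  matrices, ML exploratory factor analysis (varimax/oblimin) with the
  0.30 single-factor loading rule, Yen's Q3 local-dependence diagnostic,
  Wald-test differential item functioning with all-other-items anchoring and
  Benjamini–Hochberg correction, discrimination banding
  (0.35 / 0.65 / 1.35 / 1.70 cut points), and a seeded hot-deck imputer.
- **`paincat.cat_engine`** — the adaptive loop: seeded random first item,
  maximum-Fisher-information or Kullback–Leibler item selection,
  ML/EAP/MAP/WLE theta estimation, stopping at SE ≤ 0.3 (configurable),
  T-score reporting (θ×10+50), and theta-level endorsement tables for
  clinical interpretation.
- **`paincat.equating`** — single-group equipercentile equating with
  plus-half percentile ranks, weighted-least-squares linear crosswalks,
  spreadsheet-style half-away-from-zero rounding with range clamping, and
  round-trip symmetry reports.
- **`paincat.synthetic_sim`** — seeded synthetic banks (23-item sleep-like,
  41-item QoL-like templates), cohort generation, the 5000-simulee CAT
  burden simulation with reduction percentages, and a parameter-recovery
  harness.
- **`paincat.cli_app`** — the `paincat` command-line interface.

## CLI

```bash
paincat demo --outdir demo_out --seed 1        # end-to-end synthetic run
paincat calibrate --responses R.csv --out bank.json
paincat screen --responses R.csv --report screen.json
paincat cat --bank bank.json --seed 7          # interactive session
paincat simulate --bank bank.json --n 5000 --seed 1 --total 34 --out burden.json
paincat equate --pairs scores.csv --x ISI --y PSQI --out crosswalk.json
paincat interpret --bank bank.json --out interp.json
paincat curves --bank bank.json --out curve.csv
```

Response CSVs hold one row per respondent (`respondent_id`, one column per
item id, optional `gender`), empty cells for missing; a 1-based coding
origin can be declared with `--origin 1`.

## Conventions

- Response codes are 0-based internally (`0 .. K-1`); missing is NaN.
- Theta is oriented so higher values mean a better construct level; item
  slopes are positive after calibration.
- All randomness flows through explicit integer seeds; fits are
  deterministic given data and configuration.
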