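# fdd11 — Partial Credit Model calibration and scoring for the FDD11 disability instrument

The FDD11 is an 11-question functioning/disability screener (difficulty
seeing, hearing, walking, remembering, self-care, sleeping, household tasks,
community participation, emotional distress, interpersonal relations, bodily
pain) with 5-point ordinal responses, calibrated on pooled multi-country
Model Disability Survey data with a polytomous Rasch model.  This package
reimplements that measurement pipeline for survey analysts and psychometric
researchers:

- **Partial Credit Model (PCM) core** — category probabilities, conditional
  maximum-likelihood (CML) item calibration via elementary symmetric
  functions, ML person measurement with standard errors;
- **scoring** — the published response recoding, the emotion testlet
  (sad/depressed + worried/anxious), the ≤2-missing retention rule, sum
  scoring, the linear 0–100 disability scale and the
  No / Mild / Moderate / Severe cut-offs;
- **diagnostics** — standardized residuals, item/person infit mean squares,
  residual-correlation local-dependence flags, threshold-ordering checks
  with a minimal category-collapse search, targeting summaries and the
  person separation index (PSI);
- **differential item functioning** — per-item two-way ANOVA of residuals on
  group × ability class interval;
- **unidimensionality** — polychoric correlations, parallel analysis and a
  Schmid–Leiman bi-factor check;
- **synthetic data** — a PCM simulator with known truth (mixture ability
  populations, group-level DIF shifts, MCAR missingness, the split
  12-question variant) so every stage is testable without the restricted
  survey microdata.

The published FDD11 calibration (item thresholds with standard errors, scale
anchors, level cut-offs, recode maps) ships as a versioned JSON artifact and
is available as `fdd11.published()`.

## The model

For person ability θ (logits) and item *i* with thresholds τ_i1 … τ_im, the
PCM response probabilities are

    P(X_i = k | θ) ∝ exp( Σ_{j≤k} (θ − τ_ij) ),   k = 0 … m_i,

with the empty sum zero for k = 0.  The sum score over the instrument is the
sufficient statistic for θ, so a complete response pattern is scored by
solving E[score | θ] = s, with SE(θ̂) = I(θ̂)^(−1/2) from the test
information.  Item calibration maximizes the likelihood *conditional* on the
sum scores, which eliminates the person parameters: the estimates do not
depend on the ability distribution.  The 0–100 disability score is the
affine image of θ̂ with anchors −3.71 → 0 and 4.18 → 100, and the published
cut-offs 4.3 / 22.6 / 40.8 (mean ± SD of the pooled score distribution)
define the four disability levels.

## Worked example

`examples/score_survey.py` scores three respondents against the published
calibration:

```
person   sum  ability     SE   0-100  level
anna       0   -3.710     --    0.00  No
ben       15    0.303  0.341   50.86  Severe
chris     30    4.180     --  100.00  Severe
```

`anna` reports no difficulty anywhere: sum score 0 is an extreme score with
no ML estimate, so she receives the published floor anchor (−3.71 logits,
0 on the 0–100 scale).  `ben`'s recoded responses sum to 15, which the PCM
places at 0.303 logits (SE 0.341) and 50.86 on the 0–100 scale — above the
severe-disability cut-off of 40.8.  Other examples calibrate synthetic data
and run the full diagnostic battery (`calibrate_and_diagnose.py`), screen
for country DIF (`dif_screen.py`), check unidimensionality
(`unidimensionality_check.py`) and rebuild the entire published sum-score
conversion table from the thresholds (`reproduce_score_table.py`).

A thin CLI wraps the same pipeline for shell use:

```bash
fdd11 score responses.csv -o scores.csv --exclusions excluded.csv
fdd11 calibrate responses.csv -o calibration.json --report fit.json
fdd11 simulate config.yaml -o synthetic.csv --truth truth.json
```

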