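# Methods

## Model and estimation

The package implements the Partial Credit Model (PCM), the polytomous Rasch
model in which item *i* with categories 0…m_i is characterised by
adjacent-category thresholds τ_i1…τ_im on the same logit continuum as the
person ability θ.  Thresholds are stored *uncentred*, exactly as printed in
the shipped calibration; the item location δ_i is their mean and is a
derived quantity.

**Item calibration (CML).**  Thresholds are estimated by conditional maximum
likelihood.  Conditioning on each person's sum score (the sufficient
statistic for θ) removes the person parameters, so the estimates are
invariant to the ability distribution — the property the recovery and
shift-invariance tests assert.  The conditional likelihood is evaluated
through polytomous elementary symmetric functions computed by the summation
recursion in log space (log-sum-exp convolutions), which is stable for any
realistic instrument length.  The gradient is the classic observed-minus-
expected category count, with expectations from leave-one-item-out symmetric
functions (prefix/suffix convolutions).  Optimisation is L-BFGS-B on the
flattened threshold vector (gradient tolerance 1e-8, at most 200 iterations);
because the likelihood depends only on category counts and score-group
counts, each evaluation is independent of the sample size.  CML identifies
thresholds only up to an additive constant; the reported solution constrains
the mean of all thresholds to zero and records the removed constant.
Standard errors come from the observed information (finite differences of
the analytic gradient), inverted on the identified subspace — the one
near-zero eigenvalue corresponding to the scale shift is dropped explicitly.
Never-observed categories are collapsed to a contiguous range before
estimation (with a warning, or an error if configured); persons with any
missing response or an extreme sum score are excluded from calibration, as
they contribute nothing to the conditional likelihood.

**Person measurement.**  For an interior sum score s the ML ability solves
E[score | θ] = s by bracketed Brent root-finding on [−10, 10] (bracket
widened automatically; tolerance 1e-8 in the expected score), with
SE = I(θ̂)^(−1/2) from the Fisher test information (the sum of item score
variances).  Extreme scores (0 and the maximum) have no ML estimate.  Two
conventions are supported: the calibration artifact's published anchor
abilities (−3.71 / 4.18 for the shipped instrument — treated as published
constants, since the normalisation and extrapolation that produced them are
not documented), or, when no anchors are configured, the ML solution at the
fractional score 0.3 / max − 0.3 (adjustment configurable).  Both are
flagged `extreme_flag`.  Persons with 1–2 missing responses are scored by ML
over their answered items only; the sum-score lookup table applies only to
complete patterns.  How the original analysis scored incomplete responders
is not documented; available-item ML is this package's choice.

## Scoring pipeline

Original 5-point responses (accepted as 0–4 or 1–5) are collapsed per the
published recode table; the two split emotion sub-items, when present, are
summed to 0–8 and recoded to five categories (0,1,1,2,2,3,3,4,4).  Respondents
with more than two missing items are excluded (rule configurable).  The
recoded sum (maximum 30) is converted to θ̂ and mapped affinely to 0–100
(anchors → 0/100, clamped outside).  Levels are assigned left-closed /
right-open at the cut-offs — [c1, c2) is Mild, and so on, with Severe closed
at 100.  The published table never prints a score exactly on a cut-off, so
the convention is unobservable there; left-closed is adopted and documented.
Cut-off derivation from a score distribution uses mean ± SD with the n−1
denominator (immaterial at survey sample sizes, fixed for reproducibility).

## Diagnostics

**Residuals.**  Standardized residuals are (x − E)/√Var.  By default the
moments condition on the person's sum score over answered items — the exact
CML conditional distribution, computed from leave-one-out symmetric
functions.  Under the model these residuals have mean-square exactly 1,
whereas moments evaluated at the estimated ability are deflated by roughly
(L−1)/L because θ̂ is fitted to the same L responses; with 11 items that is
a visible ~0.91.  The θ̂-based convention remains available
(`moments="theta"`).  Extreme sum scores have a point-mass conditional
distribution and produce no residual.

**Infit.**  Information-weighted mean squares Σ(x−E)²/ΣVar per item and per
person; [0.7, 1.3] is reported as the conventional good-fit band for items
and > 2 as person misfit.  A mild side effect of score conditioning is that
the person misfit fraction under the model sits nearer 2% than 5% — the
tail of the person-infit distribution is thinner than its χ²-motivated
approximation.

**Local dependence.**  Pearson correlations of standardized residuals over
pairwise-complete observations; a pair is flagged when r ≥ 0.2 + the mean
off-diagonal correlation.  Because residuals within a score group sum to
zero, the mean off-diagonal correlation is forced near −1/(L−1) ≈ −0.1, so
the operative threshold lands near 0.11 for an 11-item instrument —
matching the threshold reported for the pooled survey analysis.

**Threshold ordering and collapse search.**  An item is flagged when its
thresholds are not strictly increasing.  The collapse search merges, at each
step, the adjacent category pair straddling the largest inversion on the
worst item, refits by CML, and repeats until ordered or categories are
exhausted, returning the cumulative (always monotone, surjective) recode map
and a per-step log.  This is a greedy minimal-change heuristic, not an
exhaustive search.

**Person separation index.**  PSI = (var(θ̂) − mean(SE²))/var(θ̂), floored
at zero; SE² is averaged over measurable (non-extreme) persons.  Several PSI
variants exist in the Rasch literature; this package's default keeps the
extrapolated abilities of extreme scorers in the variance (as the major
Rasch packages do when reporting separation reliability) and exposes
`include_extremes=False` for the strict-exclusion variant.  On simulated
populations matching the published person-location moments the default
yields ≈0.80, consistent with the published 0.82; the strict variant is
systematically lower (≈0.69) because excluding the floor group shrinks the
ability variance while the published person-location moments already
describe retained, estimated abilities.

**Targeting.**  Person and item locations on the shared continuum; item
statistics are computed over all thresholds (so mean/SD/range match the
published targeting table row for items), and the person histogram plus
threshold positions form a person–item map data structure.  No attempt is
made at visual parity with the published figure.

## Differential item functioning

Per item, a two-way ANOVA of standardized residuals on group and ability
class interval (default six quantile bins of θ̂; duplicate quantile edges
are merged with a warning, which happens routinely because θ̂ is discrete
over sum scores).  The reported F and p are the group main effect from a
type-II decomposition of the model with interaction, giving numerator
df = G − 1; a degenerate layout falls back to the additive model.  This
RUMM-style construction matches the df structure of the published DIF
table; the original software routine is not documented.  Under the null the
empirical rejection rate at α = 0.05 is ~4% and power for a 0.5-logit
uniform shift on a well-targeted item at N = 5000 is essentially 1.  No DIF
resolution (item splitting or removal) is implemented, mirroring the
original analysis's decision not to resolve country DIF.

## Unidimensionality

Polychoric correlations use two-step ML per pair (thresholds from marginal
normal quantiles, then a bounded 1-D likelihood maximisation over ρ with
bivariate-normal rectangle probabilities); the pairwise matrix is repaired
to the nearest PSD matrix by eigenvalue clipping when needed, with a
warning.  Parallel analysis compares the observed (principal-component)
eigenvalues position by position against the 95th percentile of eigenvalues
from 100 random standard-normal datasets of the same shape, stopping at the
first failure; pure noise therefore yields 0, though strongly skewed ordinal
margins can let polychoric sampling noise exceed the normal-theory reference
and yield 1.  The bi-factor check extracts the retained number of first-order
factors by principal-axis factoring, rotates with promax (power 4), fits a
single second-order factor to the factor correlations and applies the
Schmid–Leiman orthogonalization; the instrument counts as unidimensional
when every item's general loading exceeds its largest specific loading.
With one retained factor the general factor is that factor and the verdict
is unidimensional by construction.  Heywood cases are flagged in the result,
not silently clipped.  Exploratory bi-factor via Schmid–Leiman was chosen
because the original analysis does not name its bi-factor method;
confirmatory models are out of scope.  Whether the original parallel
analysis used PCA or PAF eigenvalues is also undocumented; PCA eigenvalues
are the default here.

## Synthetic data

The simulator draws abilities from a configurable mixture — by default 25%
at a floor ability of −3.5 plus Normal(−1.0, 1.1) — chosen to mimic a
general adult population in which most respondents report no meaningful
difficulty.  Responses are drawn item-wise from the PCM at the shipped
(recoded-scale) thresholds, optionally with group-specific threshold shifts
(uniform DIF) and MCAR missingness; everything is deterministic given the
seed, and the truth record stores abilities, thresholds, groups and shifts.
The 12-question variant generates the two emotion sub-items at
θ + w·u with a shared person-level component u ~ N(0,1); the default weight
w = 2.0 is set so the sub-items' residual correlation is ≈0.4, the regime
that motivates forming the testlet.  The sub-item thresholds are synthetic
placeholders, not published values.  The generator does not emulate survey
design effects, household clustering, or informative missingness, so
passing tests demonstrate correctness of the machinery under the model —
not robustness to the messiness of real survey data.  The true pooled
ability distribution behind the published calibration is unpublished; all
distribution choices here are synthetic defaults.

## Numerical choices and problem sizes

Probabilities are computed via log-softmax; conditional likelihoods and
symmetric functions entirely in log space.  Root-finding tolerances are
1e-8; probability-sum invariants hold to 1e-12 over |θ| ≤ 30.  The test
suite exercises calibration recovery at N ∈ {500, 2000, 8000}, diagnostic
null behaviour at N = 5000, DIF error rates over 20 seeded replicates of
N = 5000, and the PSI surrogate at N = 10,000 — sizes at which the relevant
Monte-Carlo error is well below the assertion tolerances while the full
suite runs in a few minutes.

## Known limitations

- Marginal maximum likelihood, discrimination parameters (2PL/GPCM) and
  Bayesian estimation are out of scope; so are survey weights and
  prevalence estimation.
- The collapse search is greedy and need not find the globally minimal
  recode; on replicas of the pre-recode situation it is asserted only to
  produce a monotone coarsening that restores ordering.
- CML standard errors ignore the uncertainty of the category-collapse step
  when auto-collapse is used.
- The published extreme-score anchors are consumed as constants; the
  package's fractional-score fallback will not reproduce them exactly.
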