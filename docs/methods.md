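# Methods

## The estimand and the modelling approach

The package addresses a question from the comorbidity / joint-health-state
literature: when diagnoses accumulate, does mean health-state utility fall by
a fixed decrement per diagnosis (additive), by a fixed proportion
(multiplicative), or with curvature? Person-level utility indices are far too
noisy and heterogeneous to answer this directly, so the analysis operates on
*stratum means*: persons are grouped by their number of registered diagnoses
(NoD), each stratum's mean utility is computed, and three parametric forms
are fitted to the (k, mean) points by least squares weighted by stratum size:

- Model A: `u = α + β·k`
- Model B: `u = α + β·k + β₂·k²`
- Model C: `u = α·β^k`, estimated as `ln u = α′ + β′·k` with `α = exp(α′)`,
  `β = exp(β′)`

The size weights make the aggregated regression equivalent to modelling each
person's utility by their stratum label, so coefficients are driven by the
populous low-NoD strata exactly as person-level estimates would be. In all
three models α is interpretable as the expected utility at zero diagnoses
and β as the per-diagnosis penalty (a decrement in A/B, a ratio in C).

Key assumptions: (i) strata are comparable once age, sex, and severity are
adjusted for — i.e. the persons with k+1 diagnoses resemble those with k plus
one more health problem; (ii) stratum means are estimated precisely enough
that the fitted functional form reflects structure rather than noise (hence
the minimum-stratum-size threshold); (iii) V-codes (health-service contacts)
carry no morbidity signal and are excluded from all counts.

## Counting and stratification

- **NoD** counts a person's non-V diagnosis records *with multiplicity*:
  3-digit truncation maps distinct underlying codes onto one 3-digit code, so
  a repeated code is evidence of two diagnoses, not a duplicate row.
- **Stratum retention** keeps the contiguous prefix k = 0, 1, 2, … whose
  strata all hold at least `min_size` persons (default 1000) and stops at the
  first failure. Contiguity keeps k meaningful as a regressor; the threshold
  bounds the standard error of each stratum mean (≈ sd/√1000 ≈ 0.005 utility
  at sd 0.15). The discarded fraction of persons is logged and reported.
- **Descriptives** use unweighted arithmetic means within strata, SDs with
  the n−1 denominator, and the included-cohort size as the denominator for
  percentage columns. The correlation footer is the unweighted Pearson
  correlation of the stratum label with each column of stratum means,
  computed across strata — a 9-point correlation, deliberately not a
  person-level one.

## Age/sex adjustment

A reference OLS model of utility on age (years) and sex (male = 1) is fitted
inside the zero-diagnosis stratum; covariates with p > `drop_alpha` (default
0.05) are removed one at a time, largest p first. Each person's utility is
then shifted by `predict(anchor) − predict(person)`, where the anchor
defaults to the zero-stratum's mean age and male fraction. This additive
counterfactual shift is the simplest scheme consistent with an age–sex
reference surface: it is exact under the reference model's linearity, leaves
anyone at the anchor untouched, and preserves utility ranks within each
(age, sex) cell. The package treats the choice of anchor and of an additive
(rather than, say, ratio-based) shift as configurable design decisions, since
a utility shift and a utility ratio differ only at second order over the
observed range (≈0.7–0.95).

Sex is coded male = 1 throughout; with that coding the fitted reference
coefficients on realistic data are positive for sex and slightly negative
per year of age, matching the expected male-higher/older-lower utility
pattern of both instruments.

## Severity weights and SWNoD

The NoD variable treats a cold and a stroke identically. The severity
adjustment replaces the count by a weighted count:

1. For each code D, the persons with *exactly one* non-V record, that record
   being D (the "sole-diagnosis" set, the intersection of the one-diagnosis
   stratum with the carriers of D), provide an estimate of D's marginal
   burden: `d_D = mean adjusted utility of the zero-diagnosis stratum − mean
   adjusted utility of the sole-diagnosis set`. A person whose single code
   appears twice is *not* sole-diagnosis (two diagnoses); a person with one
   real code plus V-codes is.
2. Codes with at least `min_n` sole-diagnosis persons are weighable
   (`min_n = 1`: relaxed criterion; `min_n = 10`: strict).
3. Weights are normalized by the person-weighted mean decrement over all
   sole-diagnosis individuals with weighable codes: `w_D = d_D / d̄`. This
   forces the mean weight over sole-diagnosis persons to 1 exactly (asserted
   to 1e-9), and hence the mean SWNoD in the retained NoD = 1 stratum to
   1.000 — the anchor that keeps SWNoD on the same scale as NoD.
4. `SWNoD = Σ w_code` over a person's non-V records, with multiplicity.
   Persons carrying any non-weighable code are excluded from the
   severity-adjusted analyses (and counted); the rest are restratified by
   SWNoD rounded half-away-from-zero to a non-negative integer (half-even
   available as a config switch; the choice only matters at exact halves).

Decrements are measured against the zero-stratum *mean*, not the reference
intercept, because utility loss exists even at zero diagnoses and the
empirical baseline respects that. Weights default to being computed from
age/sex-adjusted utilities (matching the adjustment order age, sex, then
severity), with a raw-utilities switch. Negative weights (codes whose
sole-diagnosis mean exceeds the baseline — usually sampling noise for mild
codes) are kept as computed with a logged warning; an optional truncation
clips them to zero and renormalizes so the mean-1 invariant survives.

## Model-selection statistics

- **Adjusted R² and RMSE** are computed on the original utility scale from
  weighted sums of squares about the weighted mean; Model C's fitted values
  are back-transformed first, with no retransformation (smearing) correction
  — the reported `α = exp(α′)` convention matches the plain back-transform.
- **L1O-RMSR**: each stratum is deleted in turn, the model refitted on the
  remaining strata (keeping their size weights), and the deleted stratum's
  mean predicted; the statistic is the plain RMS of the delete-one residuals.
  Weighted refits with unweighted aggregation is the convention this package
  validates against reference values on the bundled fixture; a size-weighted
  aggregation is available via `l1o_aggregate="weighted"`. Residuals for
  Model C are taken on the original scale.
- **RMSD(A, C)** is the size-weighted RMS difference between the two models'
  fitted vectors — identical to the RMSE formula with Model C's fit playing
  the role of the observations. When RMSD is smaller than both models' RMSEs,
  the two functional forms are closer to each other than to the data, and the
  data cannot adjudicate between them.
- **p(β₂)** uses the two-sided t-test from the weighted-least-squares
  covariance of the quadratic fit. Note that p-values are far more sensitive
  than coefficients to rounding in the stratum means: recomputing from a
  3-dp stratum table can shift p(β₂) by ±0.01 even when every coefficient
  agrees at 4 dp, so the package asserts coefficients, not p-values, when
  checking against printed tables.

## The synthetic-cohort generator

`SimulationConfig` defaults describe a MEPS-like adult survey cohort and are
treated as fixed study conditions, not tuning knobs:

| parameter | default | rationale |
|---|---|---|
| `n_persons` | 50 000 | survey-scale; ~40k retained after thresholds |
| `nod_mean`, `nod_dispersion` | 3.3, 1.0 | negative binomial: mean ≈3.3, most mass at 0–8, tail past 20 |
| `catalog_size`, `v_code_fraction` | 200, 0.10 | few hundred distinct 3-digit codes, a tenth V-codes |
| `code_zipf_exponent` | 1.0 | heavy-tailed prevalence, so the relaxed and strict criteria genuinely differ |
| `decrement_mean`, `decrement_shape` | 0.025, 2.0 | gamma per-code severities: mean utility loss 0.025/diagnosis, CV ≈ 0.7 |
| `baseline_eq5d`, `baseline_sf6d` | 0.95, 0.86 | zero-diagnosis means of healthy adult cohorts |
| `age_effect`, `sex_effect` | −0.0007/yr, +0.0085 | magnitudes of typical adult reference surfaces |
| `age_nod_coupling` | 2.6 yr/diagnosis | reproduces a ≈37→58 year mean-age gradient across k=0..8 |
| `sex_nod_coupling` | 0.13 logit/diagnosis | male share falling ≈57%→31% across strata |
| `noise_sd` | 0.15 | person-level utility SD within strata (0.1–0.2 in survey data) |
| `floor_eq5d`, `floor_sf6d`, `ceiling` | −0.11, 0.30, 1.0 | instrument index ranges |

Observed utilities are drawn from a Beta distribution rescaled to the
instrument's [floor, ceiling] with mean equal to the generative expected
utility and SD `noise_sd`. This choice is deliberate: utility indices are
bounded and left-skewed with a mass near the ceiling, and a bounded
distribution reproduces that shape *while keeping the observed mean equal to
the generative mean*. The alternative of adding Gaussian noise and clamping
at the ceiling (available as `noise_kind="gaussian_clamped"`) censors the
upper tail, which biases stratum means downward by ≈0.04 at the top of the
scale and shrinks fitted slopes by ≈20% — a ceiling-effect artifact worth
simulating deliberately, but fatal as a default for a generator whose purpose
is to validate mean-recovery. Every stage (catalog, counts, demographics,
codes, per-instrument noise, V-records, missingness) draws from an
independent seed-derived stream, so switching one stage off regenerates all
others bit-identically.

What the generator does **not** emulate: survey design weights and panel
structure; realistic ICD-9 prevalence profiles or code–code correlation
(codes are drawn independently given the count, so there is no clustering of
related diagnoses within persons); discrete instrument scoring (observed
utilities are continuous); reporting artifacts such as digit preference.
Passing tests on synthetic cohorts therefore demonstrate that the estimators
recover a known generative structure under realistic noise, confounding, and
ceilings — not that any real cohort satisfies that structure.

## Problem sizes and tolerances in the test suite

The bundled stratum-table computations are exact and instantaneous. The
statistical validation uses cohorts of 50 000 persons × 20 replicates per
generative form for slope/ratio recovery and out-of-sample model preference
(mean recovered slope within ±0.003 of truth; the true form wins the
L1O-RMSR comparison in at least 80% of replicates), and 12 000–20 000-person
cohorts for unit tests of the adjustment and severity stages. These sizes
keep stratum-mean standard errors near 0.002 utility — small enough that the
A-versus-C distinction (≈0.002 over nine strata) is detectable but not
trivial, mirroring the regime the method is designed for. Numerical oracles
(closed-form weighted moments, literal delete-one refits) are asserted to
1e-10; the normalization invariant to 1e-9.

## Known limitations

- Only nine-ish strata enter any fit; conclusions about the functional form
  do not extend beyond the retained range of diagnosis counts.
- The severity-weight estimator uses sole-diagnosis persons only; for rare
  codes the weights are noisy, and under the relaxed criterion a single
  person can define a weight. The strict criterion trades this noise for
  cohort attrition.
- The reference-model backward elimination is a convention, not a claim of
  optimality; with `drop_alpha = 0.05` a null covariate survives 5% of the
  time by construction.
- The multiplicative model's statistics are computed on the back-transformed
  scale without bias correction; for the narrow utility ranges involved the
  retransformation bias is far below the reporting precision.
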