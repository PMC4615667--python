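# nodqol

**How fast does health-related quality of life fall as diagnoses accumulate —
linearly or multiplicatively?**

`nodqol` is an analysis pipeline for health economists and outcomes
researchers working with preference-based health-state utility values (HSUVs,
the weights in QALY calculations). Given a cohort of respondents with
pre-scored EQ-5D and SF-6D utility indices and a conditions table of
registered 3-digit ICD-9-CM codes, it:

1. applies the standard inclusion criteria (adults with valid data for both
   instruments) and computes each person's **number of diagnoses** (NoD):
   non-V-code records counted *with multiplicity*, since 3-digit truncation
   collapses distinct diagnoses onto one code;
2. stratifies the cohort by NoD, keeping the contiguous run of strata with at
   least 1000 persons each, and tabulates per-stratum descriptives plus the
   Pearson correlation of the stratum label with each column of means;
3. optionally adjusts utilities for **age and sex** (a reference OLS model
   fitted within the zero-diagnosis stratum, with backward elimination of
   non-significant covariates) and for **diagnosis severity** (per-code
   weights estimated from sole-diagnosis individuals and normalized to mean
   1, yielding the severity-weighted number of diagnoses, SWNoD);
4. fits three models to the stratum means by stratum-size-weighted least
   squares and compares them:

   | model | form | interpretation |
   |---|---|---|
   | A | u = α + β·k | additive: fixed utility decrement per diagnosis |
   | B | u = α + β·k + β₂·k² | quadratic: curvature check nested over A |
   | C | u = α·βᵏ (fit as ln u = α′ + β′·k) | multiplicative: proportional loss per diagnosis |

   using adjusted R², size-weighted RMSE, the leave-one-stratum-out RMS
   residual (L1O-RMSR, the out-of-sample analogue), and the size-weighted
   distance between the A and C fitted curves (RMSD).

A synthetic-cohort generator with a fully known ground truth (additive or
multiplicative, with demographic confounding, heterogeneous per-code
severities, heavy-tailed code prevalence, and bounded instrument noise)
supports every stage of the pipeline without access to micro-data.

## Worked example

Fitting the three models to a published stratum table (nine strata k = 0..8,
sizes 7089 … 1212, mean EQ-5D 0.948 … 0.742) takes three lines:

```python
from nodqol.fixtures import published_series
from nodqol.models import fit_all

res = fit_all(published_series("eq5d"))
```

which prints, via the fields of `res`:

```text
A: u(k) = 0.9463 -0.0260*k   adjR2=0.9972 RMSE=0.0029 L1O=0.0051
C: u(k) = 0.9487 * 0.9700^k  adjR2=0.9985 RMSE=0.0021 L1O=0.0038
RMSD(A,C) = 0.0020
```

Read: a person's expected EQ-5D index starts at ≈0.946 with no diagnoses and
loses ≈0.026 per additional diagnosis under the additive model, or ≈3.0% per
diagnosis under the multiplicative model. Both fit the nine stratum means
almost equally well (RMSE 0.003 vs 0.002), and the two fitted curves are
closer to each other (RMSD 0.002) than either is to the data — the practical
message being that the parsimonious linear model describes the trend
adequately.

On synthetic data the pipeline recovers a known truth through the full chain
(generate → include → adjust → stratify → fit):

```python
from nodqol import SimulationConfig, generate_cohort, apply_inclusion, run_analysis

cohort, truth = generate_cohort(SimulationConfig(n_persons=50_000, seed=1))
result = run_analysis(apply_inclusion(cohort), "eq5d", "age_sex")
```

```text
true slope  = -0.0219
fitted beta = -0.0219   (L1O-RMSR: A 0.0034 vs C 0.0047)
```

The age/sex adjustment removes the older-with-more-diagnoses confounding the
generator builds in, and the additive model wins the out-of-sample comparison
when the truth is additive.

There is also a CLI:

```sh
nodqol simulate --n-persons 50000 --seed 1 --out-dir data/
nodqol analyze --persons data/persons.csv --conditions data/conditions.csv --out-dir out/ --plot
nodqol acceptance          # recompute published reference values and report PASS/FAIL
```

`analyze` writes a stratum descriptives table (`strata.tsv`), a model
comparison table (`models.tsv`, 4 dp), a full-precision `results.yaml`, and
optional fitted-curve figures.

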