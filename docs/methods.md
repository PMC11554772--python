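# Methods

## Scope and design

`nrf2screen` benchmarks thresholded single-marker diagnostic tests and
two-stage screen-then-validate tests for KEAP1/NFE2L2 pathway activation
in NSCLC. Everything is organised around two objects: a cohort (samples
with histology, mutation status, marker measurements and an optional
use/validation split) and a trained cutpoint rule. The user-facing surface
follows the estimator pattern — `ThresholdTestModel(...).fit()` returns a
results object carrying the cutpoint, its operating characteristics,
bootstrap AUC uncertainty and a summary table — while the functional
modules underneath (`roc`, `composition`, `pipeline`) do the work and are
usable directly.

## Cutpoint optimisation

**Candidate set.** Midpoints between consecutive distinct observed scores,
plus −∞/+∞ sentinels. This set is finite, realises every achievable
confusion table, and is invariant (in rank terms) under strictly
increasing transforms of the scores. A positive call is `score ≥ cutpoint`
for direction `greater`; the boundary is included by convention and
documented rather than configurable per call.

**Youden objective.** `J = sensitivity + specificity − 1` is compared
across candidates in exact integer arithmetic on the common denominator
`n₊·n₋` (i.e. `tp·n₋ + tn·n₊`), so candidates whose J values are
mathematically equal are true ties even when floating-point evaluation of
`sens + spec − 1` would differ in the last ulp. Ties break toward higher
sensitivity (screening-minded), then toward the smaller cutpoint. When the
best attainable J is ≤ 0 the optimiser emits `DirectionMismatchWarning`:
the marker likely separates the classes in the opposite direction. An
auto-flip is deliberately not applied; marker direction is a modelling
statement (NFE2L2 targets rise on activation), not something to infer per
dataset.

**Screening objective.** Maximise sensitivity subject to
`specificity ≥ floor` (default floor 0.3), evaluated on training data
only — validation specificity may drop below the floor and is simply
reported. Ties break toward higher specificity, then the smaller cutpoint,
again on integer counts. The all-negative sentinel is excluded from this
optimiser's candidate set: a screen that forwards nobody to validation is
not a screening test, and excluding it gives the constraint real teeth —
data that admit no genuine cutpoint at the floor (e.g. a completely
degenerate marker with one distinct value) raise an explicit infeasibility
error naming the best achievable specificity instead of silently returning
a test with zero sensitivity.

**AUC.** Trapezoidal area under the empirical ROC over the full candidate
set; equal by construction to the Mann–Whitney estimator
`(#concordant + ½·#tied)/(n₊·n₋)` (the equality is enforced by test
against pair enumeration and scikit-learn). The confidence interval is a
stratified percentile bootstrap (positives and negatives resampled
separately, so no resample is single-class), default B = 2000 at the 95%
level, seeded. Percentile intervals of a bounded statistic may touch 0 or
1 on small or well-separated samples; that is expected behaviour, not an
error. No smoothed/binormal ROC fitting, partial AUC or DeLong variance is
provided.

## Two-stage composition and cost

The combined test is `screen AND validator`, with the validator consulted
only for screen-positives. The validator — the K1N2-style rule — is a
fixed input, either the precomputed binary call column (default) or the
continuous score with a fixed cutoff; it is never refit. Direct
consequences, asserted as invariants in the tests: the final-positive set
is contained in the screen-positive set, combined specificity ≥ screening
specificity, combined sensitivity ≤ min(screening sensitivity,
validator-alone sensitivity). The cost metric is the screen-negative
fraction of evaluated samples — the share spared the expensive multi-gene
assay — and satisfies `reduction + forwarded fraction = 1` exactly.

Suite training fits every marker × stratum (pooled, LUAD, LUSC) ×
objective on the use subset only. Histology-specific rules are evaluated
within their histology; pooled rules cohort-wide. Samples missing a marker
or label are dropped per test with counts reported (mirroring cohorts
where IHC was available for only a subset); nothing is imputed. A stratum
that cannot be fitted (single-class use subset, infeasible floor) is
recorded as a failure and the rest of the suite proceeds.

## H-score

`H = Σᵢ i·pᵢ` over intensity levels 0–3 with cell percentages `pᵢ`
summing to 100 (tolerance 1e-9 for fractional entry), rounded half-up to
an integer in [0, 300]; equivalently 100 × mean cell intensity. One
consensus score per sample is modelled; inter-rater structure is out of
scope. The reverse construction used by the simulator spreads a latent
per-sample protein level over cells as `Normal(latent, dispersion)` and
bins at three ascending thresholds; boundary mass belongs to the higher
bin (measure-zero for positive dispersion; it pins down the dispersion → 0
limit, where a population centred on a boundary splits evenly between the
adjacent bins). H-score is monotone non-decreasing in the latent.

## Synthetic cohorts

The generator emulates the structure the benchmark assumes, with defaults
fixed once as the study conditions:

| parameter | default | rationale |
|---|---|---|
| n_samples | 348 | enriched-cohort scale at which the benchmark is exercised |
| luad_fraction | 250/348 ≈ 0.72 | LUAD-majority NSCLC mix |
| mutant_prevalence | 115/232 ≈ 0.50 | mutation-enriched design, not population prevalence |
| keap1_fraction | 0.7 | *KEAP1* mutations outnumber *NFE2L2* in NSCLC |
| other_activator_fraction | 0.08 | minority of wildtypes pathway-active via CUL3/SMARCA4-like alterations |
| gene shifts (log-expression, sd 1) | TXNRD1 1.8, NQO1 1.6, TRIM16 1.4, GENE1–3 1.2/1.0/0.8 | moderate, gene-ranked separation; placeholder symbols because the full marker panel is configurable, not asserted |
| IHC channel | shift 2.0, noise sd 1.0, LUAD attenuation 0.45 | IHC noisier than RNA and weaker in LUAD |
| K1N2 score | weight 1.0, noise sd 0.18, cutoff 0.5 | a high-accuracy (≈99.7%/99.7%) reference/validator |

Mutation implies pathway activation; a further 8% of wildtypes are active
through other genes, so markers that track activation are imperfect
predictors of mutation status by construction. Expression noise is normal
on the log scale (standard for normalised panels); only relative class
separation matters downstream. The `null` scenario zeroes every marker
shift (chance-level tests); `separable` makes every channel perfectly
separating (exercising the J = 1 limit). Validation checks on the
generator are analytic: one-gene binormal AUC converges to Φ(shift/√2),
and empirical sensitivity/specificity at the true class-mean-midpoint
cutpoint converge to Φ(shift/2).

What the generator does *not* emulate: between-gene correlation (real
NFE2L2 targets are co-regulated), heavy-tailed or batch-structured
expression noise, histology-dependent RNA effects, and any calibration to
real effect sizes. Passing tests therefore demonstrate that the machinery
is correct and that the qualitative orderings (combined ≥ validator-alone
≥ noisy single test; LUSC IHC > LUAD IHC) follow from the assumed
structure — not that any specific real-cohort performance number is
reproduced.

## Splits, determinism and leakage

The default split is a seeded stratified draw (strata = histology ×
mutant-vs-WT, validation fraction 0.31, per-stratum counts within ±1 of
`round(n·fraction)`); an explicit two-column assignment file can replace
it when an external split must be honoured. RNA and IHC sub-cohorts share
the single sample-level assignment, with per-test denominators emerging
from data availability. Every random draw in the package flows through a
seeded `numpy` generator; the pipeline writes a manifest with the config
hash and seeds, and two runs of one config are byte-identical. Training
reads the use subset only; a test verifies that permuting validation
labels leaves every trained rule bit-identical.

## Problem sizes in the test suite

Oracle-equivalence checks run on 1000 random instances of n ≤ 50 with
heavy ties; closed-form AUC recovery uses one n = 20 000 cohort (±0.01);
composition laws are checked across 100 replicate 348-sample cohorts;
chance-level behaviour on an n = 1000 null cohort is asserted on the
pooled stratum, whose validation subset is large enough that the
[−0.2, 0.2] band is a many-sigma statement. These sizes were chosen so
each statistical assertion has comfortable margin while the whole suite
stays quick to run.

## Known limitations

* The screening floor (0.3) and all generator effect sizes are study
  conditions, not estimates; real-cohort performance requires real data
  read through `read_cohort`.
* Percentile bootstrap CIs are first-order only; no BCa correction.
* No OR-composition or multi-marker panels; the composition model is the
  sequential AND only.
* NanoString raw-count normalisation is out of scope; expression must
  arrive normalised.
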