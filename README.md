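# nrf2screen

Benchmarking cheap screening tests for KEAP1/NFE2L2 pathway activation in
non-small-cell lung cancer (NSCLC).

## The problem

Loss-of-function *KEAP1* or gain-of-function *NFE2L2* mutations
constitutively activate the NFE2L2 oxidative-stress program in NSCLC and
mark candidates for pathway-directed therapy. The most accurate available
readout is a multi-gene NanoString expression signature (here called the
K1N2 score), but it needs equipment and panel runs that many pathology labs
do not have. Cheaper alternatives exist: single NFE2L2 target-gene RNA
measurements (*TXNRD1*, *NQO1*, *TRIM16*) and NQO1 immunohistochemistry
scored with the H-score. `nrf2screen` provides the machinery to benchmark
those alternatives — as stand-alone tests and as first-stage screens in a
two-stage *screen → K1N2-validate* workflow — on cohorts with a training
("use") and a held-out ("validation") split, stratified by histology (LUAD
/ LUSC). Because the motivating patient data are not publicly deposited,
the package ships a synthetic cohort generator that reproduces the
statistical structure such a cohort is assumed to have, so the entire
benchmark is runnable and testable end to end.

## The model

A single-marker test is a thresholded classifier: call a sample positive
iff its marker value `x` satisfies `x ≥ c` (markers rise with pathway
activation). Training chooses `c` on the use subset under one of two
objectives:

* **stand-alone test** — maximize Youden's index
  `J = sensitivity + specificity − 1`;
* **screening test** — maximize sensitivity subject to
  `specificity ≥ 0.3`, so that nearly all true positives survive the
  screen while a useful fraction of negatives is spared the expensive
  confirmatory assay.

Candidate cutpoints are midpoints between consecutive distinct observed
values plus ±∞ sentinels; AUC is the trapezoidal area under the empirical
ROC, identical to the Mann–Whitney concordance estimator
`(#concordant + ½·#tied) / (n₊·n₋)`, with a stratified percentile
bootstrap for its confidence interval.

The two-stage test forwards only screen-positives to the fixed,
never-refit K1N2 rule; the final call is the AND of both stages. The cost
metric is the fraction of samples the screen spares from K1N2 testing
(= fraction of screen-negatives).

The H-score of an IHC stain profile with percentage `pᵢ` of cells at
intensity `i ∈ {0,1,2,3}` is `H = Σ i·pᵢ ∈ [0, 300]`.

## Worked example

```python
from nrf2screen import (ThresholdTestModel, TwoStageTestModel, default_params,
                        simulate_cohort, split_cohort)

cohort = split_cohort(simulate_cohort(default_params("paper_like", seed=7)), seed=1)
use = cohort.subset(split_group="use")
validation = cohort.subset(split_group="validation")

screen = ThresholdTestModel.from_cohort(use, "TXNRD1", "mutation_status")
fit = screen.fit(objective="screening", min_specificity=0.3)
print(fit.summary())
print(TwoStageTestModel(fit).summary(validation, "mutation_status"))
```

prints

```
Threshold test results
======================
marker:            TXNRD1
objective:         screen_sens_at_min_spec (min specificity 0.3)
direction:         greater (positive iff score >= cutpoint)
n:                 239 (122 positive / 117 negative)
cutpoint:          4.83072
sensitivity:       0.967
specificity:       0.402
Youden's J:        0.369
ROC-AUC:           0.863

Two-stage test results
======================
screen:            TXNRD1 @ 4.83072 (greater)
validator:         k1n2_call @ 0.5
n evaluated:       109
screening stage:   sens 0.964 / spec 0.370
final (AND):       sens 0.964 / spec 0.963 / J 0.927
K1N2 tests spared: 20.2% of samples
```

Read: on the 239-sample use subset the screening objective pushes the
*TXNRD1* cutpoint down until sensitivity is 0.97 while specificity (0.40)
still clears the 0.3 floor. Deployed on the 109 held-out samples, the
screen alone is sensitive but unspecific (0.96/0.37); AND-ing it with the
high-accuracy K1N2 call restores specificity (0.96) at almost no
sensitivity cost, for a final J of 0.93 — while 20.2% of samples never
needed the expensive K1N2 assay at all.

The same pipeline runs from the shell:

```sh
nrf2screen simulate --out cohort.tsv --scenario paper_like --seed 7
nrf2screen run --config config.yaml        # simulate/load → split → train → evaluate
nrf2screen report --bundle benchmark_out   # markdown summary table
```

## Layout

| module | contents |
|---|---|
| `nrf2screen.cohort` | `Sample`/`Cohort` model, TSV/CSV IO, stratified use/validation split |
| `nrf2screen.simulate` | synthetic cohort generator and scenario presets |
| `nrf2screen.ihc` | H-score arithmetic and latent-to-stain-profile discretization |
| `nrf2screen.roc` | ROC, AUC + bootstrap CI, Youden and constrained-screening cutpoint optimizers |
| `nrf2screen.composition` | test rules, two-stage evaluation, cost reduction, suite training |
| `nrf2screen.model` | `ThresholdTestModel`/`ThresholdTestResults`, `TwoStageTestModel` |
| `nrf2screen.pipeline`, `nrf2screen.cli` | configured benchmark runs and the `nrf2screen` command |

See `docs/methods.md` for the modelling assumptions, parameter choices and
limitations.
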