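"""Single-marker tests, the two-stage screen-then-validate test, and
performance accounting.

The two-stage design: every sample takes a cheap screening test (a single
gene's RNA expression or the NQO1 IHC H-score, with a sensitivity-optimised
cutpoint); only screen-positives go on to the expensive, high-accuracy K1N2
validation test, and the final call is screen-positive AND validator-positive.
Screen-negatives never consume the validator, which makes the cost metric
(:func:`k1n2_reduction`, the fraction of samples spared K1N2 testing)
well-defined.

The K1N2 validator is consumed as a fixed rule — either the precomputed
binary call column or the score column with a fixed published-style cutoff —
and is never refit here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, NamedTuple, Sequence

import numpy as np

from .cohort import Cohort, Sample
from .roc import (
    CutpointInfeasibleError,
    CutpointResult,
    ScoredLabels,
    SingleClassError,
    apply_cutpoint,
    optimize_cutpoint_screening,
    optimize_cutpoint_youden,
)

logger = logging.getLogger(__name__)

ReferenceLabel = Literal["mutation_status", "k1n2_pathway_call", "pathway_active_truth"]

REFERENCE_LABELS = ("mutation_status", "k1n2_pathway_call", "pathway_active_truth")

STRATA = ("pooled", "LUAD", "LUSC")


def youden_j(sensitivity: float, specificity: float) -> float:
    """Youden's J = sensitivity + specificity - 1, in [-1, 1]."""
    if not 0 <= sensitivity <= 1 or not 0 <= specificity <= 1:
        raise ValueError("sensitivity and specificity must be in [0, 1]")
    return sensitivity + specificity - 1.0


@dataclass(frozen=True)
class TestRule:
    """A thresholded single-marker classifier.

    ``marker`` is a panel gene symbol, ``"h_score"``, ``"k1n2_score"`` or
    ``"k1n2_call"`` (the precomputed binary pathway call, thresholded at
    0.5).  ``trained_on`` records provenance: the stratum, objective and
    constraint the cutpoint was fitted under.
    """

    marker: str
    cutpoint: float
    direction: str = "greater"
    trained_on: str = ""

    __test__ = False  # not a test class despite the name

    def to_dict(self) -> dict:
        return {
            "marker": self.marker,
            "cutpoint": float(self.cutpoint),
            "direction": self.direction,
            "trained_on": self.trained_on,
        }


#: Passthrough rule for the published binary K1N2 call.
K1N2_CALL_RULE = TestRule(
    marker="k1n2_call", cutpoint=0.5, direction="greater",
    trained_on="published call (passthrough, not refit)",
)


@dataclass(frozen=True)
class CombinedTestRule:
    """Screening rule composed with the fixed K1N2 validator by AND on
    screen-positives."""

    screen: TestRule
    validator: TestRule = K1N2_CALL_RULE

    def to_dict(self) -> dict:
        return {"screen": self.screen.to_dict(), "validator": self.validator.to_dict()}


@dataclass(frozen=True)
class PerformanceReport:
    """Confusion counts and derived metrics for one test on one stratum."""

    tp: int
    fp: int
    tn: int
    fn: int
    n_evaluated: int
    n_dropped_missing: int
    reference_label: str
    stratum: str
    test_name: str = ""
    auc: float | None = None
    auc_ci: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.tp + self.fp + self.tn + self.fn != self.n_evaluated:
            raise ValueError("confusion counts must sum to n_evaluated")

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp)

    @property
    def youden_j(self) -> float:
        return self.sensitivity + self.specificity - 1.0

    def to_dict(self) -> dict:
        return {
            "test_name": self.test_name,
            "stratum": self.stratum,
            "reference_label": self.reference_label,
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
            "n_evaluated": self.n_evaluated,
            "n_dropped_missing": self.n_dropped_missing,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "youden_j": self.youden_j,
            "auc": self.auc,
            "auc_ci_lower": None if self.auc_ci is None else self.auc_ci[0],
            "auc_ci_upper": None if self.auc_ci is None else self.auc_ci[1],
        }


def marker_value(sample: Sample, marker: str) -> float | None:
    """Resolve a marker name to a sample's score; None when missing."""
    if marker == "h_score":
        return None if sample.h_score is None else float(sample.h_score)
    if marker == "k1n2_score":
        return sample.k1n2_score
    if marker == "k1n2_call":
        return None if sample.k1n2_call is None else float(sample.k1n2_call)
    return sample.expression.get(marker)


def label_value(sample: Sample, reference_label: str) -> bool | None:
    """Resolve the chosen reference label for a sample; None when missing.

    "positive" means mutant (KEAP1mut/NFE2L2mut pooled) or pathway-active,
    depending on the reference; the label source is always explicit.
    """
    if reference_label == "mutation_status":
        return sample.is_mutant
    if reference_label == "k1n2_pathway_call":
        return sample.k1n2_call
    if reference_label == "pathway_active_truth":
        return sample.pathway_active_truth
    raise ValueError(f"unknown reference label {reference_label!r}")


def scored_labels_from_cohort(
    cohort: Cohort,
    marker: str,
    reference_label: str,
    direction: str = "greater",
) -> tuple[ScoredLabels, int]:
    """Marker scores paired with labels; samples missing either are dropped.

    Returns the scored labels and the number of dropped samples."""
    scores, labels = [], []
    dropped = 0
    for s in cohort:
        v = marker_value(s, marker)
        y = label_value(s, reference_label)
        if v is None or y is None:
            dropped += 1
            continue
        scores.append(v)
        labels.append(y)
    if dropped:
        logger.info(
            "marker %s / label %s: dropped %d sample(s) with missing values",
            marker, reference_label, dropped,
        )
    if not scores:
        raise ValueError(
            f"no sample carries both marker {marker!r} and label {reference_label!r}"
        )
    return ScoredLabels(np.array(scores), np.array(labels), direction=direction), dropped


def _confusion(calls: np.ndarray, labels: np.ndarray) -> tuple[int, int, int, int]:
    tp = int(np.sum(calls & labels))
    fp = int(np.sum(calls & ~labels))
    tn = int(np.sum(~calls & ~labels))
    fn = int(np.sum(~calls & labels))
    return tp, fp, tn, fn


def evaluate_test(
    rule: TestRule,
    cohort: Cohort,
    reference_label: str,
    stratum: str = "pooled",
    test_name: str | None = None,
) -> PerformanceReport:
    """Apply a trained rule to a cohort and tabulate its confusion matrix.

    Samples missing the marker or the label are dropped (and counted);
    a cohort left with a single label class raises, as sensitivity or
    specificity would be undefined.
    """
    data, dropped = scored_labels_from_cohort(
        cohort, rule.marker, reference_label, direction=rule.direction
    )
    data.require_both_classes()
    calls = apply_cutpoint(data.scores, rule)
    tp, fp, tn, fn = _confusion(calls, data.labels)
    return PerformanceReport(
        tp=tp, fp=fp, tn=tn, fn=fn,
        n_evaluated=len(data.scores),
        n_dropped_missing=dropped,
        reference_label=reference_label,
        stratum=stratum,
        test_name=test_name or rule.marker,
    )


class CombinedEvaluation(NamedTuple):
    final: PerformanceReport
    screening: PerformanceReport


def evaluate_combined(
    rule: CombinedTestRule,
    cohort: Cohort,
    reference_label: str,
    stratum: str = "pooled",
    test_name: str | None = None,
) -> CombinedEvaluation:
    """Evaluate the two-stage test: final call = screen AND validator.

    Screen-negatives are final-negative without ever evaluating the
    validator (the short-circuit that produces the cost saving).  Returns
    both the final report and the screening-stage report on the same
    evaluated samples.
    """
    scores, val_scores, labels = [], [], []
    dropped = 0
    for s in cohort:
        sv = marker_value(s, rule.screen.marker)
        vv = marker_value(s, rule.validator.marker)
        y = label_value(s, reference_label)
        if sv is None or vv is None or y is None:
            dropped += 1
            continue
        scores.append(sv)
        val_scores.append(vv)
        labels.append(y)
    if not scores:
        raise ValueError("no sample carries the screen marker, validator and label")
    scores = np.array(scores)
    val_scores = np.array(val_scores)
    labels = np.array(labels, dtype=bool)
    if labels.all() or not labels.any():
        raise SingleClassError(
            "combined evaluation requires both label classes after dropping"
        )
    screen_calls = apply_cutpoint(scores, rule.screen)
    final_calls = np.zeros_like(screen_calls)
    # validator consulted only where the screen is positive
    final_calls[screen_calls] = apply_cutpoint(
        val_scores[screen_calls], rule.validator
    )
    name = test_name or f"{rule.screen.marker}+{rule.validator.marker}"
    tp, fp, tn, fn = _confusion(final_calls, labels)
    final = PerformanceReport(
        tp=tp, fp=fp, tn=tn, fn=fn,
        n_evaluated=len(scores), n_dropped_missing=dropped,
        reference_label=reference_label, stratum=stratum,
        test_name=name,
    )
    tp, fp, tn, fn = _confusion(screen_calls, labels)
    screening = PerformanceReport(
        tp=tp, fp=fp, tn=tn, fn=fn,
        n_evaluated=len(scores), n_dropped_missing=dropped,
        reference_label=reference_label, stratum=stratum,
        test_name=f"{name} [screening stage]",
    )
    return CombinedEvaluation(final=final, screening=screening)


def k1n2_reduction(rule: CombinedTestRule, cohort: Cohort) -> float:
    """Fraction of samples spared K1N2 testing by the screening stage.

    Equals (number of screen-negative samples) / (number evaluated); its
    complement is the fraction forwarded to validation.
    """
    scores = [v for s in cohort if (v := marker_value(s, rule.screen.marker)) is not None]
    if not scores:
        raise ValueError("no sample carries the screen marker")
    screen_calls = apply_cutpoint(np.array(scores), rule.screen)
    return float(np.sum(~screen_calls)) / len(scores)


@dataclass(frozen=True)
class TrainingFailure:
    marker: str
    stratum: str
    objective: str
    error: str


@dataclass
class TrainedSuite:
    """All rules trained by :func:`train_test_suite`, with any per-stratum
    failures recorded rather than aborting the whole suite."""

    single_rules: list[TestRule] = field(default_factory=list)
    combined_rules: list[CombinedTestRule] = field(default_factory=list)
    failures: list[TrainingFailure] = field(default_factory=list)
    fits: dict[str, CutpointResult] = field(default_factory=dict)


def _descriptor(marker: str, stratum: str, objective: str,
                reference_label: str, min_specificity: float | None) -> str:
    parts = [f"marker={marker}", f"stratum={stratum}", f"objective={objective}",
             f"reference={reference_label}"]
    if min_specificity is not None:
        parts.append(f"min_specificity={min_specificity}")
    return "; ".join(parts)


def train_test_suite(
    cohort: Cohort,
    markers: Sequence[str],
    objectives: Sequence[str] = ("youden", "screening"),
    reference_label: str = "mutation_status",
    min_specificity: float = 0.3,
    validator: TestRule = K1N2_CALL_RULE,
    direction: str = "greater",
) -> TrainedSuite:
    """Fit cutpoints for every marker × stratum × objective on the use subset.

    Strata are the pooled cohort and each histology; training uses only the
    "use" split subset, so validation labels can never leak into a cutpoint.
    Screening-objective rules are additionally composed with the fixed K1N2
    validator into two-stage rules.  A stratum that cannot be fitted
    (single-class use subset, infeasible constraint) is recorded as a
    failure and the remaining fits proceed.
    """
    if cohort.split is None:
        raise ValueError("cohort must carry a use/validation split before training")
    suite = TrainedSuite()
    for stratum in STRATA:
        histology = None if stratum == "pooled" else stratum
        use = cohort.subset(histology=histology, split_group="use")
        for marker in markers:
            for objective in objectives:
                try:
                    data, _ = scored_labels_from_cohort(
                        use, marker, reference_label, direction=direction
                    )
                    if objective == "youden":
                        fit = optimize_cutpoint_youden(data)
                    elif objective == "screening":
                        fit = optimize_cutpoint_screening(data, min_specificity)
                    else:
                        raise ValueError(f"unknown objective {objective!r}")
                except (SingleClassError, CutpointInfeasibleError, ValueError) as exc:
                    logger.warning(
                        "training failed for marker=%s stratum=%s objective=%s: %s",
                        marker, stratum, objective, exc,
                    )
                    suite.failures.append(
                        TrainingFailure(marker, stratum, objective, str(exc))
                    )
                    continue
                desc = _descriptor(
                    marker, stratum, objective, reference_label,
                    min_specificity if objective == "screening" else None,
                )
                rule = TestRule(
                    marker=marker, cutpoint=fit.cutpoint,
                    direction=fit.direction, trained_on=desc,
                )
                suite.single_rules.append(rule)
                suite.fits[desc] = fit
                if objective == "screening":
                    suite.combined_rules.append(
                        CombinedTestRule(screen=rule, validator=validator)
                    )
    return suite


def rule_stratum(rule: TestRule | CombinedTestRule) -> str:
    """Recover the training stratum from a rule's descriptor."""
    desc = rule.screen.trained_on if isinstance(rule, CombinedTestRule) else rule.trained_on
    for part in desc.split("; "):
        if part.startswith("stratum="):
            return part.removeprefix("stratum=")
    return "pooled"
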