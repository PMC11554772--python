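"""Model/Results interface for fitting and deploying marker threshold tests.

The fitted object here is small but real: a cutpoint chosen on training
data under an explicit objective, with operating characteristics,
bootstrap AUC uncertainty, and a summary table.  The interface follows the
familiar estimator pattern: construct a model from data, call ``fit()``,
get a results object.

>>> m = ThresholdTestModel(scores, labels)
>>> res = m.fit(objective="youden")
>>> res.cutpoint, res.sensitivity, res.specificity
>>> print(res.summary())

``TwoStageTestModel`` composes a fitted screening rule with the fixed K1N2
validator and evaluates the sequential test on a cohort.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cohort import Cohort
from .composition import (
    CombinedEvaluation,
    CombinedTestRule,
    K1N2_CALL_RULE,
    PerformanceReport,
    TestRule,
    evaluate_combined,
    evaluate_test,
    k1n2_reduction,
    scored_labels_from_cohort,
)
from .roc import (
    CutpointResult,
    RocCurve,
    ScoredLabels,
    apply_cutpoint,
    auc,
    bootstrap_auc_ci,
    optimize_cutpoint_screening,
    optimize_cutpoint_youden,
    roc_curve,
)


class ThresholdTestModel:
    """A single-marker threshold test to be fitted to scored, labelled data.

    Parameters
    ----------
    scores, labels
        Continuous marker values and binary reference labels
        (True = positive class).
    direction
        "greater" if higher scores indicate the positive class (the default
        for NFE2L2 target genes, which are upregulated on activation).
    marker
        Optional marker name, carried into exported rules.
    """

    def __init__(self, scores, labels, direction: str = "greater",
                 marker: str = "score"):
        self.data = ScoredLabels(np.asarray(scores, dtype=float),
                                 np.asarray(labels, dtype=bool),
                                 direction=direction)
        self.marker = marker

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, marker: str, label: str,
                       direction: str = "greater") -> "ThresholdTestModel":
        """Build from a tidy sample table; rows missing either column are
        dropped."""
        sub = df[[marker, label]].dropna()
        return cls(sub[marker].to_numpy(dtype=float),
                   sub[label].to_numpy(dtype=bool),
                   direction=direction, marker=marker)

    @classmethod
    def from_cohort(cls, cohort: Cohort, marker: str, reference_label: str,
                    direction: str = "greater") -> "ThresholdTestModel":
        data, _ = scored_labels_from_cohort(cohort, marker, reference_label,
                                            direction=direction)
        model = cls.__new__(cls)
        model.data = data
        model.marker = marker
        return model

    def roc(self) -> RocCurve:
        return roc_curve(self.data)

    def auc(self) -> float:
        return auc(self.data)

    def fit(self, objective: str = "youden",
            min_specificity: float = 0.3) -> "ThresholdTestResults":
        """Optimise the cutpoint.

        ``objective="youden"`` maximises J; ``objective="screening"``
        maximises sensitivity subject to specificity >= ``min_specificity``.
        """
        if objective == "youden":
            fit = optimize_cutpoint_youden(self.data)
        elif objective == "screening":
            fit = optimize_cutpoint_screening(self.data, min_specificity)
        else:
            raise ValueError(f"unknown objective {objective!r}")
        return ThresholdTestResults(self, fit)


class ThresholdTestResults:
    """Results of fitting a :class:`ThresholdTestModel`."""

    def __init__(self, model: ThresholdTestModel, fit: CutpointResult):
        self.model = model
        self.fit_result = fit

    # -- point estimates ---------------------------------------------------
    @property
    def cutpoint(self) -> float:
        return self.fit_result.cutpoint

    @property
    def sensitivity(self) -> float:
        return self.fit_result.sensitivity

    @property
    def specificity(self) -> float:
        return self.fit_result.specificity

    @property
    def youden_j(self) -> float:
        return self.fit_result.youden_j

    @property
    def auc(self) -> float:
        return self.model.auc()

    # -- uncertainty and deployment ---------------------------------------
    def auc_ci(self, n_boot: int = 2000, level: float = 0.95,
               seed: int | None = None) -> tuple[float, float]:
        """Stratified percentile-bootstrap confidence interval for the AUC."""
        return bootstrap_auc_ci(self.model.data, n_boot=n_boot,
                                level=level, seed=seed)

    def predict(self, scores) -> np.ndarray:
        """Binary calls for new scores under the fitted cutpoint."""
        return apply_cutpoint(scores, self.fit_result)

    def as_rule(self, trained_on: str = "") -> TestRule:
        return TestRule(marker=self.model.marker,
                        cutpoint=self.cutpoint,
                        direction=self.fit_result.direction,
                        trained_on=trained_on)

    def evaluate(self, cohort: Cohort, reference_label: str,
                 stratum: str = "pooled") -> PerformanceReport:
        """Deploy the fitted rule on a (held-out) cohort."""
        return evaluate_test(self.as_rule(), cohort, reference_label,
                             stratum=stratum)

    def summary(self) -> str:
        f = self.fit_result
        lines = [
            "Threshold test results",
            "======================",
            f"marker:            {self.model.marker}",
            f"objective:         {f.objective}"
            + (f" (min specificity {f.min_specificity})"
               if f.min_specificity is not None else ""),
            f"direction:         {f.direction} (positive iff score "
            + (">=" if f.direction == "greater" else "<=") + " cutpoint)",
            f"n:                 {len(self.model.data.scores)} "
            f"({self.model.data.n_pos} positive / {self.model.data.n_neg} negative)",
            f"cutpoint:          {f.cutpoint:.6g}",
            f"sensitivity:       {f.sensitivity:.3f}",
            f"specificity:       {f.specificity:.3f}",
            f"Youden's J:        {f.youden_j:.3f}",
            f"ROC-AUC:           {self.auc:.3f}",
        ]
        return "\n".join(lines)

    def __repr__(self) -> str:
        return (f"<ThresholdTestResults marker={self.model.marker!r} "
                f"cutpoint={self.cutpoint:.4g} J={self.youden_j:.3f}>")


class TwoStageTestModel:
    """Screen-then-validate sequential test.

    Composes a screening rule (typically from
    ``ThresholdTestResults.as_rule()`` with the screening objective) with
    the fixed K1N2 validator.  Only screen-positives are validated; the
    final call is the AND of the two stages.
    """

    def __init__(self, screen: TestRule | ThresholdTestResults,
                 validator: TestRule = K1N2_CALL_RULE):
        if isinstance(screen, ThresholdTestResults):
            screen = screen.as_rule()
        self.rule = CombinedTestRule(screen=screen, validator=validator)

    def evaluate(self, cohort: Cohort, reference_label: str,
                 stratum: str = "pooled") -> CombinedEvaluation:
        """Final and screening-stage performance on a cohort."""
        return evaluate_combined(self.rule, cohort, reference_label,
                                 stratum=stratum)

    def reduction(self, cohort: Cohort) -> float:
        """Fraction of samples spared the K1N2 validation test."""
        return k1n2_reduction(self.rule, cohort)

    def summary(self, cohort: Cohort, reference_label: str) -> str:
        ev = self.evaluate(cohort, reference_label)
        red = self.reduction(cohort)
        s, f = ev.screening, ev.final
        return "\n".join([
            "Two-stage test results",
            "======================",
            f"screen:            {self.rule.screen.marker} "
            f"@ {self.rule.screen.cutpoint:.6g} ({self.rule.screen.direction})",
            f"validator:         {self.rule.validator.marker} "
            f"@ {self.rule.validator.cutpoint:.6g}",
            f"n evaluated:       {f.n_evaluated}",
            f"screening stage:   sens {s.sensitivity:.3f} / spec {s.specificity:.3f}",
            f"final (AND):       sens {f.sensitivity:.3f} / spec {f.specificity:.3f} "
            f"/ J {f.youden_j:.3f}",
            f"K1N2 tests spared: {red:.1%} of samples",
        ])
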