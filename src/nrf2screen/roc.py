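"""ROC curves, Mann-Whitney-consistent AUC, and cutpoint optimisation.

Two cutpoint objectives are provided, matching the two roles a thresholded
marker plays in a diagnostic workflow:

* ``optimize_cutpoint_youden`` — the stand-alone test: maximise Youden's
  J = sensitivity + specificity - 1.
* ``optimize_cutpoint_screening`` — the first stage of a screen-then-confirm
  workflow: maximise sensitivity subject to a floor on specificity
  (default floor 0.3 downstream), so that few true positives are lost while
  a useful fraction of negatives is spared the confirmatory test.

Candidate cutpoints are the midpoints between consecutive distinct observed
scores plus -inf/+inf sentinels, which is finite, covers every achievable
confusion table, and is stable under monotone transforms of the scores.
A positive call is ``score >= cutpoint`` for direction "greater"
(``score <= cutpoint`` for "less").
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.stats import rankdata

Direction = Literal["greater", "less"]


class SingleClassError(ValueError):
    """Raised when scores contain only positives or only negatives."""


class CutpointInfeasibleError(ValueError):
    """Raised when no screening cutpoint satisfies the specificity floor."""

    def __init__(self, min_specificity: float, best_specificity: float):
        self.min_specificity = min_specificity
        self.best_specificity = best_specificity
        super().__init__(
            f"no screening cutpoint reaches specificity >= {min_specificity}; "
            f"best achievable specificity is {best_specificity:.4f}"
        )


class DirectionMismatchWarning(UserWarning):
    """Best achievable Youden J is <= 0: the marker may point the wrong way."""


@dataclass(frozen=True)
class ScoredLabels:
    """Continuous scores with binary reference labels.

    ``direction="greater"`` means higher scores indicate the positive class.
    """

    scores: np.ndarray
    labels: np.ndarray
    direction: Direction = "greater"

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=float)
        labels = np.asarray(self.labels, dtype=bool)
        if scores.ndim != 1 or labels.ndim != 1:
            raise ValueError("scores and labels must be one-dimensional")
        if scores.shape != labels.shape:
            raise ValueError("scores and labels must have equal length")
        if scores.size < 1:
            raise ValueError("at least one observation is required")
        if not np.all(np.isfinite(scores)):
            raise ValueError("scores must be finite")
        if self.direction not in ("greater", "less"):
            raise ValueError(f"unknown direction {self.direction!r}")
        object.__setattr__(self, "scores", scores)
        object.__setattr__(self, "labels", labels)

    @property
    def n_pos(self) -> int:
        return int(self.labels.sum())

    @property
    def n_neg(self) -> int:
        return int((~self.labels).sum())

    def require_both_classes(self) -> None:
        if self.n_pos == 0 or self.n_neg == 0:
            raise SingleClassError(
                "ROC analysis requires at least one positive and one negative "
                f"(got {self.n_pos} positives, {self.n_neg} negatives)"
            )


@dataclass(frozen=True)
class RocCurve:
    """ROC curve: (FPR, TPR) points from (0,0) to (1,1) with the
    candidate cutpoint generating each point."""

    fpr: np.ndarray
    tpr: np.ndarray
    cutpoints: np.ndarray

    @property
    def points(self) -> np.ndarray:
        return np.column_stack([self.fpr, self.tpr])

    def to_records(self) -> list[dict]:
        return [
            {"cutpoint": float(c), "fpr": float(f), "tpr": float(t)}
            for c, f, t in zip(self.cutpoints, self.fpr, self.tpr)
        ]


@dataclass(frozen=True)
class CutpointResult:
    """A trained cutpoint with its training-set operating characteristics."""

    cutpoint: float
    direction: Direction
    sensitivity: float
    specificity: float
    youden_j: float
    objective: Literal["youden", "screen_sens_at_min_spec"]
    min_specificity: float | None = None

    def __post_init__(self) -> None:
        expected_j = self.sensitivity + self.specificity - 1.0
        if abs(self.youden_j - expected_j) > 1e-12:
            raise ValueError("youden_j must equal sensitivity + specificity - 1")

    def to_dict(self) -> dict:
        return {
            "cutpoint": float(self.cutpoint),
            "direction": self.direction,
            "sensitivity": float(self.sensitivity),
            "specificity": float(self.specificity),
            "youden_j": float(self.youden_j),
            "objective": self.objective,
            "min_specificity": self.min_specificity,
        }


def candidate_cutpoints(scores: np.ndarray) -> np.ndarray:
    """Midpoints between consecutive distinct scores, plus ±inf sentinels."""
    distinct = np.unique(np.asarray(scores, dtype=float))
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    return np.concatenate([[-np.inf], mids, [np.inf]])


def _tp_tn_at(data: ScoredLabels, cuts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Integer true-positive and true-negative counts at each cutpoint."""
    pos = np.sort(data.scores[data.labels])
    neg = np.sort(data.scores[~data.labels])
    if data.direction == "greater":
        # positive call: score >= cut
        tp = len(pos) - np.searchsorted(pos, cuts, side="left")
        tn = np.searchsorted(neg, cuts, side="left")
    else:
        # positive call: score <= cut
        tp = np.searchsorted(pos, cuts, side="right")
        tn = len(neg) - np.searchsorted(neg, cuts, side="right")
    return tp, tn


def sens_spec_at(data: ScoredLabels, cutpoints: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sensitivity and specificity at each cutpoint (vectorised)."""
    cuts = np.asarray(cutpoints, dtype=float)
    tp, tn = _tp_tn_at(data, cuts)
    sens = tp / data.n_pos if data.n_pos else np.full_like(cuts, np.nan)
    spec = tn / data.n_neg if data.n_neg else np.full_like(cuts, np.nan)
    return sens, spec


def roc_curve(data: ScoredLabels) -> RocCurve:
    """ROC curve over all candidate cutpoints.

    The curve starts at (0,0) (the all-negative rule) and ends at (1,1)
    (the all-positive rule); FPR and TPR are non-decreasing along it.
    """
    data.require_both_classes()
    cuts = candidate_cutpoints(data.scores)
    sens, spec = sens_spec_at(data, cuts)
    fpr = 1.0 - spec
    order = np.argsort(cuts)
    if data.direction == "greater":
        order = order[::-1]  # +inf (all-negative) first
    return RocCurve(fpr=fpr[order], tpr=sens[order], cutpoints=cuts[order])


def auc(data: ScoredLabels) -> float:
    """Area under the ROC curve (trapezoidal rule).

    Identical to the Mann-Whitney concordance estimator
    (#concordant + ½ #tied) / (n_pos * n_neg).
    """
    curve = roc_curve(data)
    return float(np.trapezoid(curve.tpr, curve.fpr))


def _auc_rank(pos: np.ndarray, neg: np.ndarray, direction: Direction) -> float:
    """Mann-Whitney AUC via midranks; used by the bootstrap for speed."""
    n_pos, n_neg = len(pos), len(neg)
    ranks = rankdata(np.concatenate([pos, neg]))
    a = (ranks[:n_pos].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    return float(a) if direction == "greater" else float(1.0 - a)


def bootstrap_auc_ci(
    data: ScoredLabels,
    n_boot: int = 2000,
    level: float = 0.95,
    seed: int | None = None,
) -> tuple[float, float]:
    """Stratified percentile bootstrap confidence interval for the AUC.

    Positives and negatives are resampled separately (so every resample
    retains both classes) and the percentile interval of the resampled AUCs
    is returned.
    """
    data.require_both_classes()
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    rng = np.random.default_rng(seed)
    pos = data.scores[data.labels]
    neg = data.scores[~data.labels]
    aucs = np.empty(n_boot)
    for b in range(n_boot):
        p = rng.choice(pos, size=pos.size, replace=True)
        n = rng.choice(neg, size=neg.size, replace=True)
        aucs[b] = _auc_rank(p, n, data.direction)
    alpha = (1.0 - level) / 2.0
    lower, upper = np.quantile(aucs, [alpha, 1.0 - alpha])
    return float(lower), float(upper)


def optimize_cutpoint_youden(data: ScoredLabels) -> CutpointResult:
    """Cutpoint maximising Youden's J = sensitivity + specificity - 1.

    Ties are broken toward higher sensitivity, then the smaller cutpoint.
    The objective is compared in exact integer arithmetic
    (``tp * n_neg + tn * n_pos``), so candidates whose J values are
    mathematically equal are true ties regardless of float round-off.
    Emits :class:`DirectionMismatchWarning` when the best J is <= 0, which
    happens when the marker separates the classes in the opposite direction
    (or not at all).
    """
    data.require_both_classes()
    cuts = candidate_cutpoints(data.scores)
    tp, tn = _tp_tn_at(data, cuts)
    n_pos, n_neg = data.n_pos, data.n_neg
    # J on the common denominator n_pos*n_neg: exact tie detection
    j_num = tp * n_neg + tn * n_pos
    best = j_num == j_num.max()
    best_sens = tp == tp[best].max()
    eligible = best & best_sens
    i = int(np.flatnonzero(eligible)[np.argmin(cuts[eligible])])
    sens = tp / n_pos
    spec = tn / n_neg
    j = sens + spec - 1.0
    if j_num[i] <= n_pos * n_neg:  # J <= 0
        warnings.warn(
            f"best achievable Youden J is {j[i]:.4f}; the score direction "
            f"({data.direction!r}) may be inverted for this marker",
            DirectionMismatchWarning,
            stacklevel=2,
        )
    return CutpointResult(
        cutpoint=float(cuts[i]),
        direction=data.direction,
        sensitivity=float(sens[i]),
        specificity=float(spec[i]),
        youden_j=float(j[i]),
        objective="youden",
    )


def optimize_cutpoint_screening(
    data: ScoredLabels,
    min_specificity: float = 0.3,
) -> CutpointResult:
    """Screening cutpoint: maximise sensitivity with specificity >= floor.

    Among feasible candidates with equal sensitivity the one with the
    highest specificity wins (then the smaller cutpoint).  The degenerate
    all-negative sentinel is not a candidate — a screen that forwards nobody
    to validation is not a screening test — so data in which no genuine
    cutpoint meets the floor (e.g. all scores identical with a floor > 0)
    raise :class:`CutpointInfeasibleError` naming the best achievable
    specificity.  The floor is evaluated on the training data only.
    """
    data.require_both_classes()
    if not 0 <= min_specificity < 1:
        raise ValueError("min_specificity must be in [0, 1)")
    cuts = candidate_cutpoints(data.scores)
    # drop the all-negative sentinel (+inf for "greater", -inf for "less")
    cuts = cuts[:-1] if data.direction == "greater" else cuts[1:]
    tp, tn = _tp_tn_at(data, cuts)
    sens = tp / data.n_pos
    spec = tn / data.n_neg
    feasible = spec >= min_specificity
    if not feasible.any():
        raise CutpointInfeasibleError(min_specificity, float(spec.max()))
    fc, ftp, ftn = cuts[feasible], tp[feasible], tn[feasible]
    # integer count comparisons: ties are exact
    best = ftp == ftp.max()
    best_spec = ftn == ftn[best].max()
    eligible = best & best_spec
    i = int(np.flatnonzero(eligible)[np.argmin(fc[eligible])])
    fs = ftp / data.n_pos
    fp = ftn / data.n_neg
    return CutpointResult(
        cutpoint=float(fc[i]),
        direction=data.direction,
        sensitivity=float(fs[i]),
        specificity=float(fp[i]),
        youden_j=float(fs[i] + fp[i] - 1.0),
        objective="screen_sens_at_min_spec",
        min_specificity=float(min_specificity),
    )


def apply_cutpoint(scores, rule) -> np.ndarray:
    """Binary calls for ``scores`` under a trained rule.

    ``rule`` is anything with ``cutpoint`` and ``direction`` attributes
    (:class:`CutpointResult` or a test rule).  Positive iff
    ``score >= cutpoint`` (direction "greater") or ``score <= cutpoint``
    (direction "less"); the ±inf sentinels yield all-positive/all-negative.
    """
    scores = np.asarray(scores, dtype=float)
    if rule.direction == "greater":
        return scores >= rule.cutpoint
    return scores <= rule.cutpoint
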