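import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import roc_auc_score

from nrf2screen.roc import (
    CutpointInfeasibleError,
    DirectionMismatchWarning,
    ScoredLabels,
    SingleClassError,
    apply_cutpoint,
    auc,
    bootstrap_auc_ci,
    candidate_cutpoints,
    optimize_cutpoint_screening,
    optimize_cutpoint_youden,
    roc_curve,
)

# ---------------------------------------------------------------------------
# independent oracles: exact pairwise concordance and exhaustive search
# ---------------------------------------------------------------------------


def brute_auc(scores, labels) -> Fraction:
    """Mann-Whitney estimator by enumerating all pos/neg pairs (exact)."""
    pos = [s for s, y in zip(scores, labels) if y]
    neg = [s for s, y in zip(scores, labels) if not y]
    c = Fraction(0)
    for p in pos:
        for n in neg:
            if p > n:
                c += 1
            elif p == n:
                c += Fraction(1, 2)
    return c / (len(pos) * len(neg))


def brute_sens_spec(scores, labels, cut, direction="greater"):
    calls = [(s >= cut) if direction == "greater" else (s <= cut) for s in scores]
    tp = sum(c and y for c, y in zip(calls, labels))
    fn = sum((not c) and y for c, y in zip(calls, labels))
    tn = sum((not c) and (not y) for c, y in zip(calls, labels))
    fp = sum(c and (not y) for c, y in zip(calls, labels))
    return Fraction(tp, tp + fn), Fraction(tn, tn + fp)


def brute_youden(scores, labels):
    """Exhaustive search over the candidate set with the documented
    tie-break (max J, then max sensitivity, then smallest cutpoint)."""
    best = None
    for cut in candidate_cutpoints(np.asarray(scores, float)):
        sens, spec = brute_sens_spec(scores, labels, cut)
        key = (sens + spec - 1, sens, -cut)
        if best is None or key > best[0]:
            best = (key, cut, sens, spec)
    return best[1], best[2], best[3]


def brute_screening(scores, labels, min_spec):
    best = None
    cuts = candidate_cutpoints(np.asarray(scores, float))[:-1]  # no all-negative
    for cut in cuts:
        sens, spec = brute_sens_spec(scores, labels, cut)
        # same boundary semantics as the implementation: the floor is
        # compared against the float specificity
        if float(spec) < min_spec:
            continue
        key = (sens, spec, -cut)
        if best is None or key > best[0]:
            best = (key, cut, sens, spec)
    return best


small_instances = st.integers(2, 50).flatmap(
    lambda n: st.tuples(
        st.lists(st.integers(0, 8), min_size=n, max_size=n),  # heavy ties
        st.lists(st.booleans(), min_size=n, max_size=n).filter(
            lambda y: any(y) and not all(y)
        ),
    )
)


class TestAuc:
    @pytest.mark.parametrize(
        "scores, labels, expected",
        [
            ([3, 5, 1, 4], [1, 1, 0, 0], 0.75),  # 3 concordant of 4 pairs
            ([10, 11, 1, 2], [1, 1, 0, 0], 1.0),  # perfect separation
            ([2, 2, 2, 2], [1, 1, 0, 0], 0.5),  # all tied: chance
        ],
    )
    def test_examples(self, scores, labels, expected):
        data = ScoredLabels(np.array(scores, float), np.array(labels, bool))
        assert auc(data) == pytest.approx(expected, abs=1e-12)

    @given(small_instances)
    @settings(max_examples=300, deadline=None)
    def test_trapezoid_equals_pair_counting(self, instance):
        """Trapezoidal area under our ROC equals the Mann-Whitney
        concordance estimator (and scikit-learn agrees)."""
        scores, labels = instance
        data = ScoredLabels(np.array(scores, float), np.array(labels, bool))
        expected = float(brute_auc(scores, labels))
        assert auc(data) == pytest.approx(expected, abs=1e-12)
        assert roc_auc_score(labels, scores) == pytest.approx(expected, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(SingleClassError):
            auc(ScoredLabels(np.array([1.0, 2.0]), np.array([True, True])))


class TestRocCurve:
    def test_endpoints_and_monotonicity(self):
        rng = np.random.default_rng(0)
        data = ScoredLabels(rng.normal(size=60), rng.random(60) < 0.4)
        curve = roc_curve(data)
        assert (curve.fpr[0], curve.tpr[0]) == (0.0, 0.0)
        assert (curve.fpr[-1], curve.tpr[-1]) == (1.0, 1.0)
        assert np.all(np.diff(curve.fpr) >= 0)
        assert np.all(np.diff(curve.tpr) >= 0)

    def test_perfect_separation_passes_through_0_1(self):
        data = ScoredLabels(np.array([10.0, 11, 1, 2]), np.array([1, 1, 0, 0], bool))
        curve = roc_curve(data)
        assert any(f == 0.0 and t == 1.0 for f, t in zip(curve.fpr, curve.tpr))

    def test_all_tied_degenerates_to_diagonal_jump(self):
        data = ScoredLabels(np.full(6, 2.0), np.array([1, 1, 1, 0, 0, 0], bool))
        curve = roc_curve(data)
        assert curve.points.tolist() == [[0.0, 0.0], [1.0, 1.0]]


class TestOptimizers:
    def test_youden_separable_example(self):
        data = ScoredLabels(np.array([10.0, 11, 1, 2]), np.array([1, 1, 0, 0], bool))
        res = optimize_cutpoint_youden(data)
        assert res.cutpoint == 6.0  # midpoint of 2 and 10
        assert res.youden_j == 1.0

    def test_youden_tie_break_favors_sensitivity(self):
        data = ScoredLabels(
            np.array([2.0, 3, 4, 0, 1, 2]), np.array([1, 1, 1, 0, 0, 0], bool)
        )
        res = optimize_cutpoint_youden(data)
        assert res.youden_j == pytest.approx(2 / 3)
        assert res.cutpoint == 1.5  # sensitivity-favoring of the two maximizers
        assert res.sensitivity == 1.0

    def test_inverted_labels_warn_direction_mismatch(self):
        data = ScoredLabels(np.array([10.0, 11, 1, 2]), np.array([0, 0, 1, 1], bool))
        with pytest.warns(DirectionMismatchWarning):
            res = optimize_cutpoint_youden(data)
        assert res.youden_j == 0.0
        assert np.isinf(res.cutpoint)

    def test_screening_constrained_example(self):
        data = ScoredLabels(
            np.array([1.0, 2, 3, 4, 5, 0, 1, 2, 3, 4]),
            np.array([1] * 5 + [0] * 5, bool),
        )
        res = optimize_cutpoint_screening(data, min_specificity=0.3)
        assert res.cutpoint == 1.5
        assert res.sensitivity == pytest.approx(0.8)
        assert res.specificity == pytest.approx(0.4)
        assert res.min_specificity == 0.3

    def test_screening_perfect_separation_ignores_floor(self):
        data = ScoredLabels(np.array([10.0, 11, 1, 2]), np.array([1, 1, 0, 0], bool))
        res = optimize_cutpoint_screening(data, min_specificity=0.8)
        assert res.sensitivity == 1.0 and res.specificity == 1.0

    def test_screening_vacuous_floor_returns_best_spec_at_full_sens(self):
        data = ScoredLabels(
            np.array([1.0, 2, 3, 4, 5, 0, 1, 2, 3, 4]),
            np.array([1] * 5 + [0] * 5, bool),
        )
        res = optimize_cutpoint_screening(data, min_specificity=0.0)
        assert res.sensitivity == 1.0
        assert res.specificity == pytest.approx(0.2)  # best among sens-1 rules

    def test_screening_infeasible_all_tied(self):
        data = ScoredLabels(np.full(8, 3.0), np.array([1] * 4 + [0] * 4, bool))
        with pytest.raises(CutpointInfeasibleError) as exc:
            optimize_cutpoint_screening(data, min_specificity=0.3)
        assert exc.value.best_specificity == 0.0

    @given(small_instances)
    @settings(max_examples=300, deadline=None)
    def test_youden_matches_exhaustive_search(self, instance):
        import warnings

        scores, labels = instance
        data = ScoredLabels(np.array(scores, float), np.array(labels, bool))
        cut, sens, spec = brute_youden(scores, labels)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", DirectionMismatchWarning)
            res = optimize_cutpoint_youden(data)
        assert res.youden_j == pytest.approx(float(sens + spec - 1), abs=1e-12)
        assert res.cutpoint == cut

    @given(small_instances, st.sampled_from([0.0, 0.3, 0.5, 0.8]))
    @settings(max_examples=300, deadline=None)
    def test_screening_matches_exhaustive_search(self, instance, min_spec):
        scores, labels = instance
        data = ScoredLabels(np.array(scores, float), np.array(labels, bool))
        expected = brute_screening(scores, labels, min_spec)
        if expected is None:
            with pytest.raises(CutpointInfeasibleError):
                optimize_cutpoint_screening(data, min_spec)
            return
        _, cut, sens, spec = expected
        res = optimize_cutpoint_screening(data, min_spec)
        assert res.sensitivity == pytest.approx(float(sens), abs=1e-12)
        assert res.specificity == pytest.approx(float(spec), abs=1e-12)
        assert res.cutpoint == cut

    def test_youden_beats_any_quantile_cutpoint(self):
        rng = np.random.default_rng(3)
        scores = np.concatenate([rng.normal(1, 1, 40), rng.normal(0, 1, 60)])
        labels = np.array([True] * 40 + [False] * 60)
        data = ScoredLabels(scores, labels)
        best = optimize_cutpoint_youden(data).youden_j
        for q in np.linspace(0.05, 0.95, 19):
            sens, spec = brute_sens_spec(scores, labels, np.quantile(scores, q))
            assert best >= float(sens + spec - 1) - 1e-12

    def test_monotone_transform_invariance(self):
        """Strictly increasing transforms change nothing but the cutpoint."""
        rng = np.random.default_rng(7)
        scores = rng.normal(size=80)
        labels = rng.random(80) < 0.5
        data = ScoredLabels(scores, labels)
        tdata = ScoredLabels(np.exp(scores) + scores, labels)
        assert auc(data) == pytest.approx(auc(tdata), abs=1e-12)
        r, tr = optimize_cutpoint_youden(data), optimize_cutpoint_youden(tdata)
        assert (r.sensitivity, r.specificity) == (tr.sensitivity, tr.specificity)
        rs = optimize_cutpoint_screening(data, 0.3)
        trs = optimize_cutpoint_screening(tdata, 0.3)
        assert (rs.sensitivity, rs.specificity) == (trs.sensitivity, trs.specificity)


class TestApplyCutpoint:
    def test_boundary_is_positive_for_greater(self):
        from nrf2screen.composition import TestRule

        rule = TestRule(marker="x", cutpoint=1.5, direction="greater")
        assert apply_cutpoint([1.4, 1.5, 1.6], rule).tolist() == [False, True, True]

    def test_sentinels(self):
        from nrf2screen.composition import TestRule

        scores = [0.0, 5.0, -3.0]
        all_pos = TestRule(marker="x", cutpoint=-math.inf)
        all_neg = TestRule(marker="x", cutpoint=math.inf)
        assert apply_cutpoint(scores, all_pos).all()
        assert not apply_cutpoint(scores, all_neg).any()

    def test_direction_less(self):
        from nrf2screen.composition import TestRule

        rule = TestRule(marker="x", cutpoint=2.0, direction="less")
        assert apply_cutpoint([1.0, 2.0, 3.0], rule).tolist() == [True, True, False]


class TestBootstrap:
    def test_perfect_separation_gives_degenerate_interval(self):
        data = ScoredLabels(np.array([10.0, 11, 1, 2]), np.array([1, 1, 0, 0], bool))
        assert bootstrap_auc_ci(data, n_boot=200, seed=0) == (1.0, 1.0)

    def test_seeded_determinism(self):
        rng = np.random.default_rng(5)
        data = ScoredLabels(rng.normal(size=40), rng.random(40) < 0.5)
        a = bootstrap_auc_ci(data, n_boot=300, seed=42)
        b = bootstrap_auc_ci(data, n_boot=300, seed=42)
        assert a == b

    def test_interval_covers_point_estimate_binormal(self):
        """Across replicate n=40 binormal datasets (true AUC ~0.85) the
        percentile interval covers the point estimate essentially always."""
        rng = np.random.default_rng(123)
        covered = 0
        n_rep = 100
        for _ in range(n_rep):
            scores = np.concatenate([rng.normal(1.5, 1, 20), rng.normal(0, 1, 20)])
            labels = np.array([True] * 20 + [False] * 20)
            data = ScoredLabels(scores, labels)
            lo, hi = bootstrap_auc_ci(
                data, n_boot=400, seed=int(rng.integers(2**31))
            )
            point = auc(data)
            covered += lo - 1e-12 <= point <= hi + 1e-12
        assert covered >= 99

    def test_width_shrinks_with_n(self):
        widths = []
        for i, n in enumerate((40, 400, 4000)):
            rng = np.random.default_rng(10 + i)
            scores = np.concatenate(
                [rng.normal(1, 1, n // 2), rng.normal(0, 1, n // 2)]
            )
            labels = np.array([True] * (n // 2) + [False] * (n // 2))
            lo, hi = bootstrap_auc_ci(
                ScoredLabels(scores, labels), n_boot=300, seed=9
            )
            assert 0.0 <= lo <= hi <= 1.0
            widths.append(hi - lo)
        assert widths[0] > widths[1] > widths[2]
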