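import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from _oracles import auc_pair_counting
from diastolab.algorithm import CRITERIA, lasr_criterion
from diastolab.diagnostics import (
    AlignmentError,
    ConfusionMatrix,
    IndeterminatePolicy,
    SingularityError,
    algorithm_auc,
    cohen_kappa,
    confusion,
    cutoff_table,
    delong_compare,
    kappa_band,
    pearson_r,
    performance,
    roc_auc,
    standardized_ols,
)

EXCLUDE = IndeterminatePolicy.EXCLUDE
AS_POS = IndeterminatePolicy.AS_POSITIVE


class TestConfusion:
    def _outcomes(self):
        out = {f"p{i}": "positive" for i in range(2)}
        out["p2"] = "negative"
        out["p3"] = out["p4"] = "indeterminate"
        truth = {"p0": True, "p1": True, "p2": False, "p3": True, "p4": False}
        return out, truth

    def test_exclude_policy_counts_feasibility_denominator(self):
        out, truth = self._outcomes()
        cm = confusion(out, truth, EXCLUDE)
        assert (cm.tp, cm.fp, cm.fn, cm.tn) == (2, 0, 0, 1)
        assert cm.n_indeterminate == 2
        perf = performance(cm, total_n=5)
        assert perf.feasibility == pytest.approx(3 / 5)

    def test_as_positive_policy_fills_matrix_by_truth(self):
        out, truth = self._outcomes()
        cm = confusion(out, truth, AS_POS)
        assert cm.n == 5
        assert (cm.tp, cm.fp) == (3, 1)

    def test_not_assessable_always_outside_matrix(self):
        out = {"a": "positive", "b": "not_assessable"}
        cm = confusion(out, {"a": True, "b": False}, AS_POS)
        assert cm.n == 1
        assert cm.n_not_assessable == 1

    def test_missing_reference_dropped_with_count(self):
        cm = confusion({"a": "positive", "b": "negative"}, {"a": True, "b": None})
        assert cm.n == 1
        assert cm.n_missing_reference == 1

    def test_empty_results_rejected(self):
        with pytest.raises(ValueError):
            confusion({}, {})

    def test_unaligned_ids_rejected(self):
        with pytest.raises(AlignmentError):
            confusion({"a": "positive"}, {"b": True})


class TestPerformance:
    def test_hand_computed_matrix(self):
        cm = ConfusionMatrix(tp=10, fp=7, fn=35, tn=158)
        perf = performance(cm, total_n=210)
        assert perf.sensitivity == pytest.approx(10 / 45)
        assert perf.specificity == pytest.approx(158 / 165)
        assert perf.accuracy == pytest.approx(0.8)
        assert perf.feasibility == pytest.approx(1.0)

    def test_empty_disease_class_undefined_sensitivity(self):
        perf = performance(ConfusionMatrix(tp=0, fp=5, fn=0, tn=5))
        assert perf.sensitivity is None
        assert perf.specificity == pytest.approx(0.5)

    def test_perfect_matrix_all_ones(self):
        perf = performance(ConfusionMatrix(tp=5, fp=0, fn=0, tn=5))
        for name in ("sensitivity", "specificity", "ppv", "npv", "accuracy"):
            assert getattr(perf, name) == 1.0

    def test_total_smaller_than_matrix_rejected(self):
        with pytest.raises(ValueError):
            performance(ConfusionMatrix(tp=5, fp=0, fn=0, tn=5), total_n=3)


class TestKappa:
    def test_perfect_diagonal(self):
        assert cohen_kappa(ConfusionMatrix(tp=30, fp=0, fn=0, tn=70)) == pytest.approx(1.0)

    def test_exact_marginal_independence_is_zero(self):
        # marginals 0.3/0.7 on both axes, cells = products
        assert cohen_kappa(ConfusionMatrix(tp=9, fp=21, fn=21, tn=49)) == pytest.approx(0.0)

    def test_hand_value_and_band_boundary(self):
        k = cohen_kappa(ConfusionMatrix(tp=30, fp=20, fn=20, tn=30))
        assert k == pytest.approx(0.2)
        assert kappa_band(k) == "slight"  # boundary stays in the lower band

    @pytest.mark.parametrize(
        "k,band",
        [(0.1, "slight"), (0.3, "fair"), (0.5, "moderate"), (0.7, "good"), (0.9, "excellent")],
    )
    def test_band_table(self, k, band):
        assert kappa_band(k) == band


class TestRocAuc:
    def test_perfect_separation(self):
        res = roc_auc([1, 2, 3, 10, 11], [False, False, False, True, True])
        assert res.auc == 1.0

    def test_constant_marker_all_ties(self):
        res = roc_auc([5, 5, 5, 5], [True, False, True, False])
        assert res.auc == 0.5

    def test_hand_pair_counting(self):
        # diseased {3,5}, non-diseased {1,4}: 3 of 4 pairs ordered correctly
        res = roc_auc([3, 5, 1, 4], [True, True, False, False])
        assert res.auc == pytest.approx(0.75)

    def test_lower_orientation_flips(self):
        marker = [30.0, 25.0, 14.0, 12.0]
        truth = [False, False, True, True]
        assert roc_auc(marker, truth, orientation="lower").auc == 1.0

    def test_missing_markers_excluded_and_counted(self):
        res = roc_auc([1, None, 3, 4], [False, False, True, True])
        assert res.n_excluded_missing == 1
        assert res.auc == 1.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1, 2], [True, True])

    @given(st.data())
    def test_invariant_under_strictly_increasing_transform(self, data):
        n = data.draw(st.integers(6, 30))
        marker = data.draw(
            st.lists(st.integers(0, 8), min_size=n, max_size=n)
        )
        truth = data.draw(
            st.lists(st.booleans(), min_size=n, max_size=n).filter(
                lambda t: any(t) and not all(t)
            )
        )
        a = roc_auc(marker, truth).auc
        b = roc_auc([np.expm1(m) + 3 * m for m in marker], truth).auc
        assert a == pytest.approx(b)

    def test_matches_sklearn_on_random_data(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(3)
        for _ in range(20):
            y = rng.integers(0, 2, 60).astype(bool)
            if y.all() or not y.any():
                continue
            x = rng.integers(0, 6, 60).astype(float)
            assert roc_auc(x, y).auc == pytest.approx(roc_auc_score(y, x))

    def test_matches_pair_counting_oracle(self):
        rng = np.random.default_rng(4)
        y = rng.random(50) < 0.4
        y[0], y[1] = True, False
        x = rng.integers(0, 5, 50).astype(float)
        assert roc_auc(x, y).auc == auc_pair_counting(x, y)


class TestDelong:
    def test_marker_against_itself_degenerate(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=50)
        y = np.r_[np.ones(20, bool), np.zeros(30, bool)]
        cmp = delong_compare(x, x, y)
        assert cmp.degenerate
        assert (cmp.z, cmp.p) == (0.0, 1.0)

    def test_antisymmetric_in_arguments(self):
        rng = np.random.default_rng(1)
        y = rng.random(80) < 0.35
        y[:2] = [True, False]
        a = rng.normal(size=80) + y
        b = 0.5 * a + rng.normal(size=80)
        ab = delong_compare(a, b, y)
        ba = delong_compare(b, a, y)
        assert ab.z == pytest.approx(-ba.z)
        assert ab.p == pytest.approx(ba.p)
        assert ab.diff == pytest.approx(-ba.diff)

    def test_detects_clear_superiority(self):
        rng = np.random.default_rng(2)
        y = np.r_[np.ones(80, bool), np.zeros(120, bool)]
        strong = rng.normal(size=200) + 2.0 * y
        noise = rng.normal(size=200)
        cmp = delong_compare(strong, noise, y)
        assert cmp.diff > 0.2
        assert cmp.p < 1e-4


class TestAlgorithmAuc:
    def test_binary_marker_identity_on_constructed_cohort(self):
        # sens 0.7 (7/10), spec 0.8 (16/20) by construction
        outcomes = {}
        truth = {}
        k = 0
        for flag, result, count in [
            (True, "positive", 7), (True, "negative", 3),
            (False, "negative", 16), (False, "positive", 4),
        ]:
            for _ in range(count):
                outcomes[f"p{k}"] = result
                truth[f"p{k}"] = flag
                k += 1
        res = algorithm_auc(outcomes, truth)
        assert res.auc == pytest.approx(0.75)

    def test_all_positive_classifier_is_chance(self):
        outcomes = {"a": "positive", "b": "positive"}
        truth = {"a": True, "b": False}
        assert algorithm_auc(outcomes, truth).auc == 0.5

    def test_perfect_classifier(self):
        outcomes = {"a": "positive", "b": "negative"}
        truth = {"a": True, "b": False}
        assert algorithm_auc(outcomes, truth).auc == 1.0


class TestPearson:
    def test_exact_linearity(self):
        x = [1.0, 2.0, 3.0, 4.0]
        r, p = pearson_r(x, [2 * v + 1 for v in x])
        assert r == pytest.approx(1.0)

    def test_hand_pairs(self):
        r, _ = pearson_r([1, 2, 3], [2, 1, 3])
        assert r == pytest.approx(0.5)

    def test_pairwise_deletion(self):
        r, _ = pearson_r([1, 2, None, 3, 4], [2, 4, 100.0, 6, None])
        assert r == pytest.approx(1.0)

    def test_zero_variance_flagged(self):
        with pytest.raises(ValueError):
            pearson_r([1, 1, 1], [1, 2, 3])

    def test_independent_noise_near_zero(self):
        rng = np.random.default_rng(8)
        r, _ = pearson_r(rng.normal(size=10000), rng.normal(size=10000))
        assert abs(r) < 0.03


class TestStandardizedOls:
    def test_single_predictor_equals_pearson_r(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=200)
        y = 0.4 * x + rng.normal(size=200)
        betas, r2, n = standardized_ols(y, pd.DataFrame({"x": x}))
        r, _ = pearson_r(x, y)
        assert abs(betas["x"] - r) < 1e-12
        assert n == 200

    def test_duplicated_predictor_is_singular(self):
        rng = np.random.default_rng(10)
        x = rng.normal(size=50)
        with pytest.raises(SingularityError, match="x2"):
            standardized_ols(x, pd.DataFrame({"x1": x, "x2": x}))

    def test_complete_case_deletion(self):
        x = pd.DataFrame({"x": [1.0, 2, 3, 4, 5, np.nan, 7, 8, 9, 10]})
        y = 2 * x["x"]
        betas, _, n = standardized_ols(y, x)
        assert n == 9
        assert betas["x"] == pytest.approx(1.0)


class TestCutoffTable:
    def test_always_satisfied_criterion(self, default_cohort_2k):
        crit = lasr_criterion(1e6)  # every strain value is below this
        table = cutoff_table(default_cohort_2k, [crit])
        row = table.iloc[0]
        assert row.sensitivity == pytest.approx(1.0)
        assert row.specificity == pytest.approx(0.0)

    def test_strain_cutoff_monotonicity(self, default_cohort_2k):
        table = cutoff_table(
            default_cohort_2k, [lasr_criterion(c) for c in (23, 21, 18)]
        )
        sens = table.sensitivity.tolist()
        spec = table.specificity.tolist()
        assert sens[0] >= sens[1] >= sens[2]
        assert spec[0] <= spec[1] <= spec[2]

    def test_subgroup_predicate(self, default_cohort_2k):
        full = cutoff_table(default_cohort_2k, [CRITERIA["lavi_high"]])
        sub = cutoff_table(
            default_cohort_2k, [CRITERIA["lavi_high"]], subgroup="lv_gls_pct >= 16"
        )
        assert 0 < sub.iloc[0].n < full.iloc[0].n

    def test_empty_criteria_rejected(self, default_cohort_2k):
        with pytest.raises(ValueError):
            cutoff_table(default_cohort_2k, [])
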