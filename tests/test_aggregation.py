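import itertools
from collections import Counter

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sxc.aggregation import (
    PATTERN_CATEGORIES,
    FeatureCumulative,
    InstanceCumulative,
    classify_fc_pattern,
    classify_prediction_pattern,
    combined_pcc,
    feature_contribution_score,
    feature_cumulative,
    instance_cumulative,
    pattern_tabulate,
    pearson_cc,
    top_k_feature_intersection,
    top_k_features,
)
from sxc.shapley import ShapleyExplanation


def expl(values, base=0.0, cid="c", orientation="A", kind="probability"):
    values = np.asarray(values, dtype=float)
    return ShapleyExplanation(cid, values, base, base + values.sum(), orientation, kind)


class TestClassifyPredictionPattern:
    def test_all_correct(self):
        assert classify_prediction_pattern([1] * 12) == "consistently_correct"

    def test_all_incorrect(self):
        assert classify_prediction_pattern([0] * 12) == "consistently_incorrect"

    def test_start_incorrect_end_correct(self):
        bits = (0, 0, 0, 1, 1, 1, 1, 1, 1, 1, 1, 1)
        assert classify_prediction_pattern(bits) == "start_incorrect_end_correct"

    def test_start_correct_end_incorrect(self):
        assert classify_prediction_pattern((1, 1, 0, 0)) == "start_correct_end_incorrect"

    def test_alternating_is_variable(self):
        assert classify_prediction_pattern((1, 0, 1, 0, 1)) == "variable"

    def test_exhaustive_partition_of_12_bit_vectors(self):
        # oracle: exhaustive enumeration of all 4096 vectors
        counts = Counter(
            classify_prediction_pattern(bits)
            for bits in itertools.product((0, 1), repeat=12)
        )
        assert counts == {
            "consistently_correct": 1,
            "consistently_incorrect": 1,
            "start_correct_end_incorrect": 11,
            "start_incorrect_end_correct": 11,
            "variable": 4072,
        }

    def test_nonbinary_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            classify_prediction_pattern([1, 2, 0])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            classify_prediction_pattern([])

    @given(st.lists(st.integers(0, 1), min_size=1, max_size=16))
    @settings(max_examples=100, deadline=None)
    def test_every_vector_gets_exactly_one_category(self, bits):
        assert classify_prediction_pattern(bits) in PATTERN_CATEGORIES


def pattern_frame(rows):
    return pd.DataFrame(rows, columns=["compound_id", "pair", "trial", "algorithm", "category"])


class TestPatternTabulate:
    def test_identical_logs_give_full_intersection(self):
        rows = []
        for algo in ("RF", "SVM"):
            rows += [
                ("c1", "p", 0, algo, "consistently_correct"),
                ("c2", "p", 0, algo, "variable"),
            ]
        table = pattern_tabulate(pattern_frame(rows)).set_index("category")
        for cat in ("consistently_correct", "variable"):
            assert table.loc[cat, "intersection_pct"] == 100.0

    def test_disjoint_categories_give_zero_intersection(self):
        rows = [
            ("c1", "p", 0, "RF", "variable"),
            ("c1", "p", 0, "SVM", "consistently_correct"),
        ]
        table = pattern_tabulate(pattern_frame(rows)).set_index("category")
        assert table.loc["variable", "intersection_patterns"] == 0
        assert table.loc["consistently_correct", "intersection_patterns"] == 0

    def test_hand_enumerated_three_compound_fixture(self):
        rows = [
            ("c1", "p", 0, "RF", "consistently_correct"),
            ("c2", "p", 0, "RF", "consistently_correct"),
            ("c3", "p", 0, "RF", "variable"),
            ("c1", "p", 1, "RF", "consistently_correct"),
            ("c1", "p", 0, "SVM", "consistently_correct"),
            ("c2", "p", 0, "SVM", "variable"),
            ("c3", "p", 0, "SVM", "variable"),
            ("c1", "p", 1, "SVM", "consistently_correct"),
        ]
        table = pattern_tabulate(pattern_frame(rows)).set_index("category")
        cc = table.loc["consistently_correct"]
        assert cc["rf_patterns"] == 3 and cc["svm_patterns"] == 2
        assert cc["rf_compounds"] == 2
        assert cc["intersection_patterns"] == 2
        assert cc["intersection_pct"] == pytest.approx(100 * 2 / 3)
        var = table.loc["variable"]
        assert var["rf_patterns"] == 1 and var["svm_patterns"] == 2
        assert var["intersection_patterns"] == 1

    def test_conservation_per_algorithm(self):
        rng = np.random.default_rng(0)
        rows = []
        for algo in ("RF", "SVM"):
            for i in range(30):
                cat = PATTERN_CATEGORIES[rng.integers(len(PATTERN_CATEGORIES))]
                rows.append((f"c{i}", "p", int(i % 3), algo, cat))
        table = pattern_tabulate(pattern_frame(rows))
        assert table["rf_patterns"].sum() == 30
        assert table["svm_patterns"].sum() == 30

    def test_key_mismatch_rejected(self):
        rows = [
            ("c1", "p", 0, "RF", "variable"),
            ("c2", "p", 0, "SVM", "variable"),
        ]
        with pytest.raises(ValueError, match="identical"):
            pattern_tabulate(pattern_frame(rows))


class TestInstanceCumulative:
    def test_all_zero_fingerprint_gives_zero_present(self):
        c = instance_cumulative(expl([0.3, -0.2]), np.zeros(2, dtype=int))
        assert c.cs_present == 0.0
        assert c.cs_absent == pytest.approx(0.1)

    def test_hand_fixture(self):
        c = instance_cumulative(expl([0.2, -0.1, 0.3]), np.array([1, 0, 1]))
        assert c.cs_present == pytest.approx(0.5)
        assert c.cs_absent == pytest.approx(-0.1)

    def test_efficiency_partition(self):
        rng = np.random.default_rng(1)
        values = rng.normal(size=10)
        e = expl(values, base=0.3)
        c = instance_cumulative(e, rng.integers(0, 2, 10))
        assert c.cs_present + c.cs_absent == pytest.approx(e.model_output - e.base_value)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            instance_cumulative(expl([0.1]), np.array([1, 0]))


class TestFeatureContributionScore:
    def test_median_difference(self):
        cums = [InstanceCumulative("a", 0.4, 0.1)]
        assert feature_contribution_score(cums) == pytest.approx(0.3)

    def test_identical_distributions_give_zero(self):
        cums = [InstanceCumulative(str(i), v, v) for i, v in enumerate((0.1, 0.5, 0.9))]
        assert feature_contribution_score(cums) == 0.0

    def test_five_compound_fixture_matches_hand_medians(self):
        pres = (0.1, 0.2, 0.3, 0.8, 0.9)
        absn = (-0.3, -0.1, 0.0, 0.1, 0.2)
        cums = [InstanceCumulative(str(i), p, a) for i, (p, a) in enumerate(zip(pres, absn))]
        assert feature_contribution_score(cums) == pytest.approx(0.3 - 0.0)

    def test_empty_returns_none(self):
        assert feature_contribution_score([]) is None

    def test_positive_score_means_present_dominates(self):
        cums = [InstanceCumulative("a", 0.9, 0.1), InstanceCumulative("b", 0.8, 0.0)]
        assert feature_contribution_score(cums) > 0


class TestPearsonCC:
    def test_perfect_linearity(self):
        xs = np.array([0.1, 0.4, 0.9])
        assert pearson_cc(xs, 2 * xs + 1) == pytest.approx(1.0)

    def test_constant_ys_undefined(self):
        assert pearson_cc([1.0, 2.0, 3.0], [5.0, 5.0, 5.0]) is None

    def test_hand_computed_value(self):
        # oracle: product-moment formula, cross-checked with np.corrcoef and
        # scipy.stats.pearsonr (both give 0.654653670707977)
        assert pearson_cc([1, 2, 3], [2, 1, 4]) == pytest.approx(0.654653670707977, abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            pearson_cc([1, 2], [1, 2, 3])


class TestCombinedPcc:
    def test_rf_absolute_sum(self):
        assert combined_pcc(0.7, -0.6, "RF") == pytest.approx(1.3)

    def test_svm_signed_sum(self):
        assert combined_pcc(0.7, -0.6, "SVM") == pytest.approx(0.1)

    def test_zero_case(self):
        assert combined_pcc(0.0, 0.0, "RF") == 0.0
        assert combined_pcc(0.0, 0.0, "SVM") == 0.0

    def test_undefined_propagates(self):
        assert combined_pcc(None, 0.5, "RF") is None


class TestClassifyFcPattern:
    def test_rf_opposing_strong_pccs_pattern_1(self):
        comb = combined_pcc(0.6, -0.6, "RF")
        assert classify_fc_pattern(0.6, -0.6, comb, "RF") == 1

    def test_svm_two_strong_positive_pccs_pattern_3(self):
        comb = combined_pcc(0.6, 0.6, "SVM")
        assert classify_fc_pattern(0.6, 0.6, comb, "SVM") == 3

    def test_rf_one_weak_pcc_pattern_2(self):
        comb = combined_pcc(0.55, 0.02, "RF")
        assert classify_fc_pattern(0.55, 0.02, comb, "RF") == 2

    def test_pattern_3_never_for_rf_and_1_never_for_svm(self):
        for p1, p2 in [(0.9, 0.9), (0.9, -0.9), (0.1, 0.0)]:
            for algo in ("RF", "SVM"):
                pat = classify_fc_pattern(p1, p2, combined_pcc(p1, p2, algo), algo)
                assert (algo, pat) not in {("RF", 3), ("SVM", 1)}

    def test_invert_flag_flips_threshold(self):
        comb = combined_pcc(0.6, -0.6, "RF")
        assert classify_fc_pattern(0.6, -0.6, comb, "RF", invert=True) == 2

    def test_undefined_combined_rejected(self):
        with pytest.raises(ValueError):
            classify_fc_pattern(0.5, 0.5, None, "RF")


class TestFeatureCumulative:
    def test_normalization_example(self):
        # phi = (0.6, -0.2): abs sum 0.8 -> normalized (0.75, -0.25)
        table = feature_cumulative([expl([0.6, -0.2])], np.array([[1, 0]]), [True], ["A"])
        assert table.present_sum["A"][0] == pytest.approx(0.75)
        assert table.absent_sum["A"][1] == pytest.approx(-0.25)
        assert table.present_count["A"][0] == 1
        assert table.n_instances["A"] == 1

    def test_unit_abs_sum_after_normalization(self):
        rng = np.random.default_rng(3)
        explanations = [expl(rng.normal(size=6), cid=str(i)) for i in range(10)]
        fps = rng.integers(0, 2, (10, 6))
        table = feature_cumulative(explanations, fps, [True] * 10, ["A"] * 10)
        total = np.abs(table.present_sum["A"]).sum() + np.abs(table.absent_sum["A"]).sum()
        # each instance contributes exactly abs-sum 1 (signs cannot cancel
        # within a (feature, status) cell only across instances), so the sum
        # of per-instance abs sums bounds the aggregate
        assert total <= 10 + 1e-9
        per_instance = [np.abs(e.values / np.abs(e.values).sum()).sum() for e in explanations]
        assert np.allclose(per_instance, 1.0, atol=1e-12)

    def test_two_identical_instances_double_the_sums(self):
        e = expl([0.5, -0.5])
        x = np.array([[1, 0], [1, 0]])
        one = feature_cumulative([e], x[:1], [True], ["A"])
        two = feature_cumulative([e, e], x, [True, True], ["A", "A"])
        assert two.present_sum["A"][0] == pytest.approx(2 * one.present_sum["A"][0])
        assert two.absent_sum["A"][1] == pytest.approx(2 * one.absent_sum["A"][1])

    def test_incorrect_instances_excluded(self):
        e = expl([1.0, 0.0])
        table = feature_cumulative([e, e], np.array([[1, 0], [1, 0]]), [True, False], ["A", "A"])
        assert table.n_instances["A"] == 1

    def test_zero_abs_sum_skipped_and_counted(self):
        e = expl([0.0, 0.0])
        table = feature_cumulative([e], np.array([[1, 0]]), [True], ["A"])
        assert table.n_skipped == 1 and "A" not in table.n_instances


class TestTopK:
    def test_identical_rankings_full_intersection(self):
        values = np.arange(20.0) + 1
        per_model = {m: {("A", "present"): values} for m in range(3)}
        inter = top_k_feature_intersection(per_model, k=15)
        assert len(inter[("A", "present")]) == 15

    def test_disjoint_rankings_empty_intersection(self):
        v1 = np.array([5.0, 4.0, 0.0, 0.0])
        v2 = np.array([0.0, 0.0, 5.0, 4.0])
        inter = top_k_feature_intersection(
            {0: {("A", "present"): v1}, 1: {("A", "present"): v2}}, k=2
        )
        assert inter[("A", "present")] == set()

    def test_ties_broken_by_feature_index(self):
        assert top_k_features(np.array([1.0, 2.0, 2.0, 1.0]), 2) == [1, 2]
        assert top_k_features(np.array([1.0, 1.0, 1.0]), 2) == [0, 1]

    def test_fewer_than_k_nonzero_uses_all_nonzero(self):
        v = np.array([3.0, 0.0, 1.0, 0.0])
        per_model = {0: {("A", "present"): v}, 1: {("A", "present"): v}}
        inter = top_k_feature_intersection(per_model, k=15)
        assert inter[("A", "present")] == {0, 2}

    def test_single_model_rejected(self):
        with pytest.raises(ValueError):
            top_k_feature_intersection({0: {}}, k=5)


class TestFeatureCumulativeMerge:
    def test_add_accumulates(self):
        a = feature_cumulative([expl([0.6, -0.2])], np.array([[1, 0]]), [True], ["A"])
        b = feature_cumulative([expl([0.2, -0.2])], np.array([[1, 0]]), [True], ["A"])
        merged = FeatureCumulative(n_features=2)
        merged.add(a)
        merged.add(b)
        assert merged.present_sum["A"][0] == pytest.approx(0.75 + 0.5)
        assert merged.n_instances["A"] == 2
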