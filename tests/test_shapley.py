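import numpy as np
import pytest
from sklearn.ensemble import RandomForestClassifier

from sxc.models import train_model_with_search
from sxc.shapley import (
    RFExplainer,
    ShapleyExplanation,
    brute_force_shapley,
    interventional_game,
    orient_explanation,
    restricted_tanimoto_game,
    rf_tree_shapley,
    svm_tanimoto_shapley,
    tanimoto_decision_shapley,
)
from sxc.shapley.brute import additive_game
from sxc.shapley.svm import pair_class_shapley_values


class TestBruteForce:
    def test_constant_game_all_zero(self):
        phi = brute_force_shapley(lambda s: 3.7, 6)
        assert np.allclose(phi, 0.0)

    def test_additive_game_recovers_weights(self):
        w = [0.5, -1.25, 2.0, 0.0, 3.5]
        phi = brute_force_shapley(additive_game(w), 5)
        assert np.allclose(phi, w, atol=1e-12)

    def test_restricted_tanimoto_self_game(self):
        # x == s, m = 4: only the empty coalition yields a nonzero marginal,
        # so every player gets weight 1/m
        x = np.ones(4, dtype=np.int8)
        phi = brute_force_shapley(restricted_tanimoto_game(x, x), 4)
        assert np.allclose(phi, 0.25, atol=1e-12)

    def test_efficiency(self):
        rng = np.random.default_rng(5)
        x = rng.integers(0, 2, 8)
        s = rng.integers(0, 2, 8)
        game = restricted_tanimoto_game(x, s)
        phi = brute_force_shapley(game, 8)
        assert phi.sum() == pytest.approx(game(tuple(range(8))) - game(()), abs=1e-12)

    def test_enumeration_bound_enforced(self):
        with pytest.raises(ValueError, match="enumeration bound"):
            brute_force_shapley(lambda s: 0.0, 16)


class TestSvmShapley:
    def test_all_dummy_features_give_intercept_only(self):
        x = np.zeros(6, dtype=np.int8)
        s = np.zeros(6, dtype=np.int8)
        values, base, out = tanimoto_decision_shapley(x, s[None, :], np.array([1.0]), 0.3)
        assert np.allclose(values, 0.0)
        assert out == pytest.approx(0.3)

    def test_single_support_vector_equal_to_x(self):
        m = 7
        x = np.ones(m, dtype=np.int8)
        values, base, out = tanimoto_decision_shapley(x, x[None, :], np.array([1.0]), 0.0)
        assert np.allclose(values, 1.0 / m, atol=1e-12)
        assert out == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        m = int(rng.integers(2, 11))
        x = rng.integers(0, 2, m)
        sv = rng.integers(0, 2, (3, m))
        w = rng.normal(size=3)
        b = float(rng.normal())
        values, base, out = tanimoto_decision_shapley(x, sv, w, b)
        games = [restricted_tanimoto_game(x, s) for s in sv]
        phi_ref = brute_force_shapley(
            lambda subset: float(sum(wi * g(subset) for wi, g in zip(w, games))), m
        )
        assert np.allclose(values, phi_ref, atol=1e-10)
        assert base + values.sum() == pytest.approx(out, abs=1e-10)

    def test_symmetry_within_equivalence_classes(self):
        x = np.array([1, 1, 1, 0, 0, 1, 0, 0], dtype=np.int8)
        s = np.array([1, 1, 0, 1, 1, 0, 0, 0], dtype=np.int8)
        values, _, _ = tanimoto_decision_shapley(x, s[None, :], np.array([2.0]), 0.0)
        assert values[0] == values[1]          # shared (1,1) bits
        assert values[2] == values[3] == values[4] == values[5]  # mismatches
        assert values[6] == values[7] == 0.0   # dummies

    def test_class_value_efficiency_identity(self):
        # n11*phi_shared + M*phi_mismatch == Tanimoto(x, s)
        for n11, mism in [(0, 0), (1, 0), (0, 3), (4, 2), (10, 25), (64, 64)]:
            phi_s, phi_m = pair_class_shapley_values(n11, mism)
            expected = n11 / (n11 + mism) if n11 + mism else 0.0
            assert n11 * phi_s + mism * phi_m == pytest.approx(expected, abs=1e-12)

    def test_logspace_fallback_matches_exact(self):
        from sxc.shapley import svm as svm_mod

        exact = svm_mod._values_exact(30, 40)
        logsp = svm_mod._values_logspace(30, 40)
        assert logsp[0] == pytest.approx(exact[0], rel=1e-10)
        assert logsp[1] == pytest.approx(exact[1], rel=1e-10)

    def test_nonbinary_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            tanimoto_decision_shapley(np.array([0, 2]), np.array([[1, 0]]), np.array([1.0]), 0.0)

    def test_requires_svm_model(self):
        class Fake:
            algorithm = "RF"

        with pytest.raises(ValueError, match="SVM"):
            svm_tanimoto_shapley(Fake(), np.zeros(4))


def fit_forest(X, y, n_estimators=3, max_depth=3, seed=0):
    return RandomForestClassifier(
        n_estimators=n_estimators, max_depth=max_depth, random_state=seed, bootstrap=False
    ).fit(X, y)


class TestRfShapley:
    def test_stump_with_everything_on_same_side(self):
        # x and all background fall in the same leaf: no feature has a marginal
        X = np.array([[0, 0], [0, 1], [1, 0], [1, 1]] * 5)
        y = (X[:, 0] == 1).astype(int)
        forest = fit_forest(X, y, n_estimators=1, max_depth=1)
        x = np.array([1, 0])
        bg = np.array([[1, 1], [1, 0]])
        phi = RFExplainer(forest, bg).shapley_values(x[None, :])[0]
        assert np.allclose(phi, 0.0, atol=1e-12)

    def test_stump_split_feature_carries_full_difference(self):
        # leaves with class-0 probability 0.2 / 0.8, balanced background
        X = np.array([[0, 0]] * 10 + [[1, 0]] * 10)
        y = np.array([0] * 2 + [1] * 8 + [0] * 8 + [1] * 2)
        forest = fit_forest(X, y, n_estimators=1, max_depth=1)
        x = np.array([1, 0])
        bg = np.array([[0, 0], [1, 0]])  # one row per side of the split
        explainer = RFExplainer(forest, bg)
        phi = explainer.shapley_values(x[None, :])[0]
        out = forest.predict_proba(x[None, :])[0, 0]
        assert phi[0] == pytest.approx(out - explainer.base_value, abs=1e-12)
        assert phi[1] == 0.0
        # oracle confirmation
        ref = brute_force_shapley(interventional_game(forest, x, bg), 2)
        assert np.allclose(phi, ref, atol=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        m = int(rng.integers(3, 9))
        X = rng.integers(0, 2, (40, m))
        y = rng.integers(0, 2, 40)
        y[0], y[1] = 0, 1  # both classes present
        forest = fit_forest(X, y, n_estimators=int(rng.integers(1, 6)), max_depth=3, seed=seed)
        x = rng.integers(0, 2, m)
        bg = rng.integers(0, 2, (4, m))
        phi = RFExplainer(forest, bg).shapley_values(x[None, :])[0]
        ref = brute_force_shapley(interventional_game(forest, x, bg), m)
        assert np.allclose(phi, ref, atol=1e-10)

    def test_local_accuracy(self):
        rng = np.random.default_rng(42)
        X = rng.integers(0, 2, (60, 12))
        y = rng.integers(0, 2, 60)
        y[:2] = [0, 1]
        forest = fit_forest(X, y, n_estimators=10, max_depth=None)
        bg = X[:20]
        explainer = RFExplainer(forest, bg)
        xs = rng.integers(0, 2, (5, 12))
        phi = explainer.shapley_values(xs)
        outs = forest.predict_proba(xs)[:, 0]
        assert np.allclose(explainer.base_value + phi.sum(axis=1), outs, atol=1e-8)

    def test_empty_background_rejected(self):
        X = np.array([[0], [1]] * 3)
        forest = fit_forest(X, np.array([0, 1] * 3), n_estimators=1, max_depth=1)
        with pytest.raises(ValueError, match="background"):
            RFExplainer(forest, np.zeros((0, 1)))


@pytest.fixture(scope="module")
def trained_models(separable_pair):
    fps = separable_pair.fingerprint_matrix()
    labels = separable_pair.labels()
    train = np.r_[0:40, 80:120]
    val = np.r_[40:50, 120:130]
    rf_grid = {"n_estimators": [20], "criterion": ["gini"], "min_samples_split": [2],
               "max_features": ["sqrt"], "bootstrap": [False]}
    rf = train_model_with_search(fps[train], labels[train].tolist(), fps[val],
                                 labels[val].tolist(), "RF", grid=rf_grid, seed=0)
    svm = train_model_with_search(fps[train], labels[train].tolist(), fps[val],
                                  labels[val].tolist(), "SVM",
                                  grid={"C": [10], "tol": [1e-3]}, seed=0)
    return separable_pair, rf, svm


class TestModelExplanations:
    def test_svm_explanation_local_accuracy_and_output(self, trained_models):
        pair, _, svm = trained_models
        x = pair.fingerprint_matrix()[60]
        expl = svm_tanimoto_shapley(svm, x, "cpd")
        assert expl.local_accuracy_error() < 1e-8
        # oriented to class A: output is the negated decision value
        d = svm.decision_function(x[None, :])[0]
        assert expl.model_output == pytest.approx(-d, abs=1e-10)

    def test_rf_explanation_local_accuracy(self, trained_models):
        pair, rf, _ = trained_models
        x = pair.fingerprint_matrix()[60]
        expl = rf_tree_shapley(rf, x, background=rf.x_train[:16], compound_id="cpd")
        assert expl.local_accuracy_error() < 1e-8
        assert expl.model_output == pytest.approx(rf.predict_proba(x[None, :])[0, 0])


class TestOrientExplanation:
    def make(self, kind="probability"):
        return ShapleyExplanation("c", np.array([0.2, -0.1]), 0.4, 0.5, "A", kind)

    def test_identity_when_reference_equals_true_class(self):
        expl = self.make()
        assert orient_explanation(expl, "A", ("A", "B")) is expl

    def test_probability_flip(self):
        flipped = orient_explanation(self.make(), "B", ("A", "B"))
        assert np.allclose(flipped.values, [-0.2, 0.1])
        assert flipped.base_value == pytest.approx(0.6)
        assert flipped.model_output == pytest.approx(0.5)
        assert flipped.orientation == "B"
        assert flipped.local_accuracy_error() < 1e-12

    def test_decision_flip(self):
        flipped = orient_explanation(self.make(kind="decision"), "B", ("A", "B"))
        assert flipped.base_value == pytest.approx(-0.4)
        assert flipped.model_output == pytest.approx(-0.5)

    def test_unknown_class_rejected(self):
        with pytest.raises(ValueError, match="unknown class"):
            orient_explanation(self.make(), "Z", ("A", "B"))

    def test_correct_prediction_exceeds_threshold_after_orientation(self, trained_models):
        pair, rf, svm = trained_models
        fps = pair.fingerprint_matrix()
        labels = pair.labels()
        for i in (55, 70, 150):
            true = labels[i]
            if rf.decode_labels(rf.predict(fps[i][None, :]))[0] == true:
                expl = orient_explanation(
                    rf_tree_shapley(rf, fps[i], rf.x_train[:16], "c"), true, rf.classes
                )
                assert expl.base_value + expl.values.sum() > 0.5
            if svm.decode_labels(svm.predict(fps[i][None, :]))[0] == true:
                expl = orient_explanation(svm_tanimoto_shapley(svm, fps[i], "c"), true, svm.classes)
                assert expl.base_value + expl.values.sum() > 0.0
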