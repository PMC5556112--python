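import numpy as np
import pytest
from sklearn.metrics.pairwise import rbf_kernel

from pudti.svm_sw import (
    SVMSWModel,
    build_augmented_set,
    grid_search,
    penalty_grid,
    train,
    train_svm_sw,
)

from qp_reference import random_weighted_instance, solve_weighted_svm_qp


class TestAugmentedSet:
    def test_no_ambiguous_degenerates_to_two_class(self):
        aug = build_augmented_set(
            np.ones((2, 3)), -np.ones((4, 3)), None, None, c1=2.0, c4=0.5
        )
        assert len(aug) == 6
        np.testing.assert_array_equal(aug.y, [1, 1, -1, -1, -1, -1])
        np.testing.assert_allclose(aug.penalties, [2, 2, 0.5, 0.5, 0.5, 0.5])

    def test_pure_positive_weight_drops_negative_row(self):
        aug = build_augmented_set(
            np.ones((1, 2)), -np.ones((1, 2)),
            np.zeros((1, 2)), np.array([[1.0, 0.0]]), c2=1.5,
        )
        # 1 P + 1 RN + only the (+1, C2) row of the ambiguous sample
        assert len(aug) == 3
        assert aug.y[-1] == 1 and aug.penalties[-1] == 1.5

    def test_row_enumeration_with_weights(self):
        W = np.array([[0.25, 0.75], [0.5, 0.5]])
        aug = build_augmented_set(
            np.ones((2, 2)), -np.ones((3, 2)), np.zeros((2, 2)), W,
            c1=1.0, c2=2.0, c3=4.0, c4=0.5,
        )
        assert len(aug) == 2 + 3 + 2 * 2
        np.testing.assert_allclose(
            aug.penalties, [1, 1, 0.5, 0.5, 0.5, 0.5, 1.0, 3.0, 2.0]
        )

    def test_missing_weights_rejected(self):
        with pytest.raises(ValueError, match="weight"):
            build_augmented_set(
                np.ones((1, 2)), -np.ones((1, 2)), np.zeros((2, 2)),
                np.array([[0.5, 0.5]]),
            )


class TestTrain:
    def test_separable_toy_matches_generic_qp(self):
        X_p = np.array([[2.0, 2.0], [2.5, 1.5]])
        X_rn = np.array([[-2.0, -2.0], [-1.5, -2.5]])
        aug = build_augmented_set(X_p, X_rn, None, None, c1=100.0, c4=100.0)
        model = train(aug, gamma=0.5, tol=1e-8)
        ref = solve_weighted_svm_qp(aug.X, aug.y, aug.penalties, gamma=0.5)
        assert model.objective == pytest.approx(ref["objective"], abs=1e-6)
        grid = np.array([[0.0, 0.0], [1.0, 1.0], [-1.0, 0.5]])
        np.testing.assert_allclose(
            model.decision_function(grid), ref["decision"](grid), atol=1e-6
        )

    def test_fully_positive_ambiguous_equals_plain_positive(self):
        rng = np.random.default_rng(0)
        X_p = rng.normal(1, 1, (5, 3))
        X_rn = rng.normal(-1, 1, (5, 3))
        dup = X_p[[0]]
        as_amb = train_svm_sw(
            X_p, X_rn, dup, np.array([[1.0, 0.0]]), c1=1.0, c2=1.0, gamma=0.3
        )
        as_pos = train_svm_sw(np.vstack([X_p, dup]), X_rn, gamma=0.3)
        grid = rng.normal(size=(12, 3))
        np.testing.assert_allclose(
            as_amb.decision_function(grid), as_pos.decision_function(grid),
            atol=1e-5,
        )

    def test_fully_negative_ambiguous_merges_into_negatives(self):
        rng = np.random.default_rng(1)
        X_p = rng.normal(1, 1, (5, 3))
        X_rn = rng.normal(-1, 1, (4, 3))
        X_a = rng.normal(-1, 1, (3, 3))
        W = np.tile([0.0, 1.0], (3, 1))
        sw = train_svm_sw(X_p, X_rn, X_a, W, c3=0.7, c4=0.7, gamma=0.3)
        merged = train_svm_sw(X_p, np.vstack([X_rn, X_a]), c4=0.7, gamma=0.3)
        grid = rng.normal(size=(12, 3))
        np.testing.assert_allclose(
            sw.decision_function(grid), merged.decision_function(grid),
            atol=1e-5,
        )

    def test_single_class_rejected(self):
        aug = build_augmented_set(np.ones((3, 2)), np.empty((0, 2)), None, None)
        with pytest.raises(ValueError, match="both roles"):
            train(aug)

    def test_monotone_influence_of_positive_weight(self):
        """Raising the ambiguous sample's positive penalty never lowers
        its decision score."""
        rng = np.random.default_rng(2)
        X_p = rng.normal(1, 1, (4, 2))
        X_rn = rng.normal(-1, 1, (4, 2))
        x = np.array([[0.2, -0.1]])
        scores = []
        for c2 in [0.1, 0.5, 1.0, 2.0, 4.0]:
            m = train_svm_sw(
                X_p, X_rn, x, np.array([[1.0, 0.5]]), c2=c2, gamma=0.5
            )
            scores.append(m.decision_function(x)[0])
        assert np.all(np.diff(scores) >= -1e-8)


class TestPredict:
    def test_score_zero_is_negative(self):
        # symmetric construction puts the midpoint exactly on the plane
        model = SVMSWModel(
            support_vectors=np.array([[1.0, 0.0], [-1.0, 0.0]]),
            dual_coef=np.array([0.5, -0.5]),
            intercept=0.0,
            gamma=1.0,
        )
        mid = np.array([[0.0, 0.0]])
        assert model.decision_function(mid)[0] == pytest.approx(0.0)
        assert model.predict(mid)[0] == -1

    def test_hand_evaluated_kernel_sum(self):
        sv = np.array([[1.0, 0.0], [0.0, 1.0]])
        model = SVMSWModel(
            support_vectors=sv,
            dual_coef=np.array([0.7, -0.2]),
            intercept=0.1,
            gamma=2.0,
        )
        x = np.array([[0.5, 0.5]])
        k = np.exp(-2.0 * ((x - sv) ** 2).sum(axis=1))
        expected = 0.7 * k[0] - 0.2 * k[1] + 0.1
        assert model.decision_function(x)[0] == pytest.approx(expected)

    def test_interior_positive_point(self):
        rng = np.random.default_rng(3)
        X_p = rng.normal(2, 0.3, (5, 2))
        X_rn = rng.normal(-2, 0.3, (5, 2))
        model = train_svm_sw(X_p, X_rn, gamma=0.5)
        assert model.predict(np.array([[2.0, 2.0]]))[0] == 1

    def test_json_round_trip(self):
        rng = np.random.default_rng(4)
        model = train_svm_sw(
            rng.normal(1, 1, (4, 2)), rng.normal(-1, 1, (4, 2)), gamma=0.4
        )
        clone = SVMSWModel.from_json(model.to_json())
        grid = rng.normal(size=(6, 2))
        np.testing.assert_allclose(
            model.decision_function(grid), clone.decision_function(grid)
        )


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(6))
    def test_random_instances_match_generic_qp(self, seed):
        X_p, X_rn, X_a, W, cs, gamma = random_weighted_instance(2000 + seed)
        aug = build_augmented_set(X_p, X_rn, X_a, W, *cs)
        model = train(aug, gamma=gamma, tol=1e-8)
        ref = solve_weighted_svm_qp(aug.X, aug.y, aug.penalties, gamma=gamma)
        assert model.objective == pytest.approx(ref["objective"], abs=1e-5)
        rng = np.random.default_rng(seed)
        grid = rng.normal(0, 1.5, (10, X_p.shape[1]))
        np.testing.assert_allclose(
            model.decision_function(grid), ref["decision"](grid), atol=1e-5
        )


class TestGridSearch:
    def test_single_point_grid_returns_it(self):
        rng = np.random.default_rng(5)
        best, score = grid_search(
            rng.normal(1, 1, (6, 2)), rng.normal(-1, 1, (6, 2)), None, None,
            c_grid=np.array([2.0]), gamma_grid=np.array([0.25]), seed=0,
        )
        assert best == {"c1": 2.0, "c2": 2.0, "c3": 2.0, "c4": 2.0,
                        "gamma": 0.25}

    def test_separating_configuration_wins(self):
        rng = np.random.default_rng(6)
        X_p = rng.normal(3, 0.3, (10, 2))
        X_rn = rng.normal(-3, 0.3, (10, 2))
        best, score = grid_search(
            X_p, X_rn, None, None,
            c_grid=np.array([1e-6, 1.0]), gamma_grid=np.array([0.5]), seed=0,
        )
        assert score > 0.9

    def test_same_seed_same_selection(self):
        rng = np.random.default_rng(7)
        args = (rng.normal(1, 1, (8, 2)), rng.normal(-1, 1, (8, 2)), None, None)
        kw = dict(c_grid=penalty_grid(-2, 2, 1.0),
                  gamma_grid=np.array([0.1, 1.0]), seed=3)
        assert grid_search(*args, **kw) == grid_search(*args, **kw)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            grid_search(
                np.ones((3, 2)), -np.ones((3, 2)), None, None,
                c_grid=np.array([]), gamma_grid=np.array([1.0]),
            )
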