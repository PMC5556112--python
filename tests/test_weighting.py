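import logging

import numpy as np
import pytest

from pudti import fig11_fixture
from pudti.weighting import (
    PrototypeSet,
    cluster_count,
    combine_weights,
    compute_prototypes,
    cosine,
    global_weights,
    local_weights,
    similarity_weights,
)


class TestCosine:
    def test_self_similarity_is_one(self):
        v = np.array([0.3, -1.2, 4.0])
        assert cosine(v, v) == pytest.approx(1.0)

    def test_orthogonal_unit_vectors(self):
        assert cosine(np.array([1.0, 0.0]), np.array([0.0, 1.0])) == 0.0

    def test_hand_dot_product(self):
        assert cosine(np.array([1.0, 2.0]), np.array([2.0, 1.0])) == pytest.approx(0.8)


class TestPrototypes:
    def test_cluster_count_matches_printed_formula(self):
        assert cluster_count(30, 40, 100) == 12

    def test_cluster_count_floors_at_one(self, caplog):
        with caplog.at_level(logging.WARNING):
            assert cluster_count(30, 1, 1000) == 1

    def test_single_cluster_closed_form(self):
        X_pos = np.array([[1.0, 0.0]])
        X_rn = np.array([[0.0, 1.0], [0.0, 3.0], [0.2, 2.0]])
        protos = compute_prototypes(
            X_pos, X_rn, u_size=100, t=30, alpha=16, beta=4, seed=0
        )
        assert protos.a == 1
        norm = np.linalg.norm
        rn_dir = np.mean([r / norm(r) for r in X_rn], axis=0)
        np.testing.assert_allclose(
            protos.negatives[0], 16 * rn_dir - 4 * np.array([1.0, 0.0])
        )
        np.testing.assert_allclose(
            protos.positives[0], 16 * np.array([1.0, 0.0]) - 4 * rn_dir
        )

    def test_same_seed_gives_identical_prototypes(self):
        rng = np.random.default_rng(4)
        X_pos, X_rn = rng.normal(size=(10, 3)), rng.normal(size=(40, 3))
        a = compute_prototypes(X_pos, X_rn, u_size=60, seed=11)
        b = compute_prototypes(X_pos, X_rn, u_size=60, seed=11)
        np.testing.assert_array_equal(a.negatives, b.negatives)


class TestLocalWeights:
    def test_worked_fixture_recovers_all_four_clusters(self):
        fx = fig11_fixture()
        weights, clustering = local_weights(
            fx.points, fx.prototypes, rn_size=fx.rn_size, t=fx.t, seed=0
        )
        assert clustering.n_clusters == 4
        for cid, expected in fx.expected.items():
            got = weights[fx.cluster_of == cid]
            np.testing.assert_allclose(got, np.tile(expected, (len(got), 1)))

    def test_three_to_one_cluster_fraction(self):
        protos = PrototypeSet(np.array([[1.0, 0.0]]), np.array([[0.0, 1.0]]))
        pts = np.array([[0.9, 0.1]] * 3 + [[0.1, 0.9]])
        weights, _ = local_weights(
            pts, protos, rn_size=10, seed=0, n_clusters=1
        )
        np.testing.assert_allclose(weights, np.tile([0.75, 0.25], (4, 1)))

    def test_equal_cosines_tag_negative(self):
        protos = PrototypeSet(np.array([[1.0, 0.0]]), np.array([[0.0, 1.0]]))
        weights, clustering = local_weights(
            np.array([[1.0, 1.0]]), protos, rn_size=1, seed=0, n_clusters=1
        )
        assert clustering.tags[0] == -1
        np.testing.assert_allclose(weights[0], [0.0, 1.0])

    def test_members_of_a_cluster_share_local_weights(self):
        fx = fig11_fixture()
        weights, clustering = local_weights(
            fx.points, fx.prototypes, rn_size=fx.rn_size, t=fx.t, seed=0
        )
        for c in range(clustering.n_clusters):
            rows = weights[clustering.labels == c]
            assert np.ptp(rows, axis=0).max() == 0.0


class TestGlobalWeights:
    def test_symmetric_similarities_split_evenly(self):
        protos = PrototypeSet(np.array([[1.0, 1.0]]), np.array([[1.0, 1.0]]))
        w = global_weights(np.array([[2.0, 2.0]]), protos)
        np.testing.assert_allclose(w[0], [0.5, 0.5])

    def test_single_prototype_ratio(self):
        # sims 0.9 and 0.3 -> (0.75, 0.25); realized with unit vectors
        theta_p, theta_n = np.arccos(0.9), np.arccos(0.3)
        protos = PrototypeSet(
            np.array([[np.cos(theta_p), np.sin(theta_p)]]),
            np.array([[np.cos(theta_n), np.sin(theta_n)]]),
        )
        w = global_weights(np.array([[1.0, 0.0]]), protos)
        np.testing.assert_allclose(w[0], [0.75, 0.25], atol=1e-12)

    def test_two_prototype_sums(self):
        def unit(c):
            return np.array([c, np.sqrt(1 - c**2)])

        protos = PrototypeSet(
            np.array([unit(0.8), unit(0.6)]), np.array([unit(0.2), unit(0.4)])
        )
        w = global_weights(np.array([[1.0, 0.0]]), protos)
        np.testing.assert_allclose(w[0], [0.7, 0.3], atol=1e-12)

    def test_all_negative_similarity_falls_back_to_half(self, caplog):
        protos = PrototypeSet(np.array([[-1.0, 0.0]]), np.array([[0.0, -1.0]]))
        with caplog.at_level(logging.WARNING):
            w = global_weights(np.array([[1.0, 1.0]]), protos)
        np.testing.assert_allclose(w[0], [0.5, 0.5])


class TestCombine:
    def test_alpha_zero_is_local(self):
        loc, glo = np.array([[0.4, 0.6]]), np.array([[0.9, 0.1]])
        np.testing.assert_allclose(combine_weights(loc, glo, 0.0), loc)

    def test_alpha_one_is_global(self):
        loc, glo = np.array([[0.4, 0.6]]), np.array([[0.9, 0.1]])
        np.testing.assert_allclose(combine_weights(loc, glo, 1.0), glo)

    def test_worked_arithmetic(self):
        w = combine_weights(
            np.array([[5 / 12, 7 / 12]]), np.array([[0.75, 0.25]]), 0.6
        )
        assert w[0, 0] == pytest.approx(0.4 * 5 / 12 + 0.6 * 0.75)

    def test_alpha_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            combine_weights(np.zeros((1, 2)), np.zeros((1, 2)), 1.2)

    def test_monotone_in_each_argument(self):
        base = combine_weights(np.array([[0.4, 0.6]]), np.array([[0.5, 0.5]]), 0.6)
        up_loc = combine_weights(np.array([[0.5, 0.5]]), np.array([[0.5, 0.5]]), 0.6)
        up_glo = combine_weights(np.array([[0.4, 0.6]]), np.array([[0.6, 0.4]]), 0.6)
        assert up_loc[0, 0] > base[0, 0] and up_glo[0, 0] > base[0, 0]


class TestSimilarityWeights:
    def test_all_pairs_sum_to_one_and_differ_globally(self):
        rng = np.random.default_rng(8)
        protos = PrototypeSet(
            positives=rng.normal([1, 0, 0, 0], 0.15, (3, 4)),
            negatives=rng.normal([0, 1, 0, 0], 0.15, (3, 4)),
        )
        X = np.abs(rng.normal(0.5, 0.5, (30, 4)))
        out = similarity_weights(X, protos, rn_size=50, t=30, seed=1)
        for key in ("local", "global", "combined"):
            np.testing.assert_allclose(out[key].sum(axis=1), 1.0, atol=1e-9)
        # same cluster shares local weights but global weights vary
        labels = out["clustering"].labels
        for c in np.unique(labels):
            rows = labels == c
            if rows.sum() > 1:
                assert np.ptp(out["local"][rows], axis=0).max() == 0.0
        assert np.ptp(out["global"], axis=0).max() > 0.0
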