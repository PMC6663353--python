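import networkx as nx
import numpy as np
import pytest

from ndikit.ndi_core import (
    cohort_i_max,
    information_measure,
    ndi_scores,
    removal_loss,
    topological_distances,
)
from conftest import make_connectome, random_connected_weighted
from oracles import brute_distance_matrix, brute_ndi


class TestTopologicalDistances:
    def test_unit_triangle(self, triangle):
        d = topological_distances(triangle)
        off = d[~np.eye(3, dtype=bool)]
        np.testing.assert_allclose(off, 1.0)

    def test_inverse_weight_path(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 0.5
        w[1, 2] = w[2, 1] = 0.5
        d = topological_distances(make_connectome(w))
        assert d[0, 2] == pytest.approx(4.0)  # 1/0.5 + 1/0.5

    def test_disconnected_pairs_infinite(self):
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = 1.0
        w[2, 3] = w[3, 2] = 1.0
        d = topological_distances(make_connectome(w))
        assert np.isinf(d[0, 2]) and np.isinf(d[1, 3])

    def test_matches_path_enumeration(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            n = int(rng.integers(3, 7))
            w = random_connected_weighted(n, rng)
            d = topological_distances(make_connectome(w))
            np.testing.assert_allclose(d, brute_distance_matrix(w), atol=1e-12)


class TestInformationMeasure:
    def test_direct_substitution(self):
        d = np.array([[0.0, 4.0], [4.0, 0.0]])
        info = information_measure(d, 1.0)
        assert info[0, 1] == pytest.approx(0.25)

    def test_imax_scaling_and_infinite(self):
        d = np.array([[0.0, 1.0, np.inf], [1.0, 0.0, 2.0], [np.inf, 2.0, 0.0]])
        info = information_measure(d, 2.0)
        assert info[0, 1] == pytest.approx(0.5)
        assert info[0, 2] == 0.0
        assert np.all(np.diag(info) == 0)

    def test_nonpositive_imax_rejected(self):
        with pytest.raises(ValueError):
            information_measure(np.zeros((2, 2)), 0.0)


class TestCohortImax:
    def test_normalized_cohort_gives_one(self):
        c = make_connectome([[0, 1, 0.3], [1, 0, 0], [0.3, 0, 0]])
        assert cohort_i_max([c, c]) == 1.0

    def test_mixed_maxima(self):
        a = make_connectome([[0, 0.7], [0.7, 0]])
        b = make_connectome([[0, 1.0], [1.0, 0]])
        assert cohort_i_max([a]) == pytest.approx(0.7)
        assert cohort_i_max([a, b]) == 1.0


class TestNDI:
    def test_path3_center_is_cut_vertex(self, path3):
        np.testing.assert_allclose(ndi_scores(path3).ndi, [0, 1, 0])

    def test_star_hub_maximal(self, star4):
        np.testing.assert_allclose(ndi_scores(star4).ndi, [1, 0, 0, 0])

    def test_triangle_fully_redundant(self, triangle):
        np.testing.assert_allclose(ndi_scores(triangle).ndi, 0.0)

    def test_isolated_node_scores_zero(self):
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = 1.0
        w[1, 2] = w[2, 1] = 1.0
        assert ndi_scores(make_connectome(w)).ndi[3] == 0.0

    def test_removal_loss_disconnection_capped_at_one(self, path3):
        loss = removal_loss(path3, 1)
        np.testing.assert_allclose(loss, [1.0, 1.0])

    def test_removal_loss_redundant_node_zero(self, triangle):
        np.testing.assert_allclose(removal_loss(triangle, 0), 0.0)

    def test_too_small_graph_rejected(self):
        with pytest.raises(ValueError):
            ndi_scores(make_connectome([[0, 1], [1, 0]]))

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(5)
        w = random_connected_weighted(6, rng)
        perm = rng.permutation(6)
        base = ndi_scores(make_connectome(w)).ndi
        permuted = ndi_scores(make_connectome(w[np.ix_(perm, perm)])).ndi
        np.testing.assert_allclose(permuted, base[perm], atol=1e-12)

    def test_scores_bounded(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            w = random_connected_weighted(6, rng, p=0.4)
            s = ndi_scores(make_connectome(w / w.max())).ndi
            assert np.all(s >= 0) and np.all(s <= 1)

    def test_matches_brute_force_oracle_small(self):
        # deeper sweep lives in the acceptance suite; spot-check here
        rng = np.random.default_rng(21)
        for _ in range(10):
            n = int(rng.integers(4, 7))
            w = random_connected_weighted(n, rng)
            w = w / w.max()
            fast = ndi_scores(make_connectome(w)).ndi
            np.testing.assert_allclose(fast, brute_ndi(w), atol=1e-9)

    def test_sum_aggregate_unbounded_variant(self, star4):
        # the sum variant accumulates raw per-pair losses per partner node
        s = ndi_scores(star4, aggregate="sum").ndi
        assert s[0] == pytest.approx(2.0)  # each survivor loses 2 partners

    def test_cut_vertices_outrank_equal_degree_peers(self):
        # two dense cliques joined by a bridge node: the bridge is an
        # articulation point and must dominate same-degree clique members
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n_half = 5
            w = np.zeros((2 * n_half + 1, 2 * n_half + 1))
            bridge = 2 * n_half
            for block in (range(n_half), range(n_half, 2 * n_half)):
                for i in block:
                    for j in block:
                        if i < j:
                            w[i, j] = w[j, i] = rng.uniform(0.5, 1.0)
            # bridge connects to a few nodes of each clique
            for i in (0, 1, n_half, n_half + 1):
                w[bridge, i] = w[i, bridge] = rng.uniform(0.5, 1.0)
            s = ndi_scores(make_connectome(w / w.max())).ndi
            g = nx.from_numpy_array(w)
            cuts = set(nx.articulation_points(g))
            if bridge in cuts and s[bridge] > s[:bridge].max():
                hits += 1
        assert hits >= 19  # >= 95% of sampled instances
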