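import warnings

import networkx as nx
import numpy as np
import pytest

from myovis import (UndefinedMeasureWarning, assortativity, average_clustering,
                    average_degree, betweenness_cpd, build_weighted_adjacency,
                    closeness, compute_all, degree_vector, density,
                    distance_matrix, path_summaries, transitivity,
                    transitivity_from_counts, weight_moments)
from myovis.measures import MEASURE_NAMES, n_links
from oracles import (assortativity_direct, betweenness_path_enumeration,
                     clustering_pair_enumeration, floyd_warshall, random_epoch,
                     transitivity_triple_loop)

CHAIN3 = np.array([[0.0, 1.0, 0.0], [1.0, 0.0, 1.0], [0.0, 1.0, 0.0]])
K3 = np.ones((3, 3)) - np.eye(3)


def star(n):
    W = np.zeros((n, n))
    W[0, 1:] = W[1:, 0] = 1.0
    return W


class TestDegreeAndDensity:
    def test_chain_degrees(self):
        np.testing.assert_array_equal(degree_vector(CHAIN3), [1, 2, 1])

    def test_degree_sum_is_twice_links(self, random_graphs):
        for W in random_graphs[:30]:
            k = degree_vector(W)
            assert k.sum() == 2 * n_links(W)
            np.testing.assert_array_equal(
                k, [np.count_nonzero(W[i]) for i in range(W.shape[0])])

    def test_average_degree_examples(self):
        n = 6
        assert average_degree(np.ones((n, n)) - np.eye(n)) == n - 1
        assert average_degree(CHAIN3) == pytest.approx(4 / 3)

    def test_density_examples(self):
        n = 5
        chain5 = np.diag(np.ones(4), 1) + np.diag(np.ones(4), -1)
        assert density(chain5) == pytest.approx(0.4)
        assert density(np.ones((n, n)) - np.eye(n)) == 1.0

    def test_ad_equals_density_times_nm1(self, random_graphs):
        for W in random_graphs[:30]:
            n = W.shape[0]
            assert average_degree(W) == pytest.approx(density(W) * (n - 1))


class TestClustering:
    def test_unit_triangle_unweighted(self):
        C, acc = average_clustering(K3, weighted=False)
        np.testing.assert_array_equal(C, [1.0, 1.0, 1.0])
        assert acc == 1.0

    @pytest.mark.parametrize("weighted", [True, False])
    def test_matches_pair_enumeration(self, random_graphs, weighted):
        for W in random_graphs[:100]:
            C, acc = average_clustering(W, weighted=weighted)
            expected = clustering_pair_enumeration(W, weighted)
            np.testing.assert_allclose(C, expected, atol=1e-12)
            assert acc == pytest.approx(expected.mean())

    def test_unweighted_bounded_by_one(self, random_graphs):
        for W in random_graphs[:30]:
            _, acc = average_clustering(W, weighted=False)
            assert 0.0 <= acc <= 1.0

    def test_weighted_bounded_by_two(self, random_graphs):
        # nonzero weights lie in [1, 2], so weighted C_i <= 2
        for W in random_graphs[:30]:
            C, _ = average_clustering(W, weighted=True)
            assert np.all((C >= 0) & (C <= 2))


class TestTransitivity:
    def test_triangle(self):
        assert transitivity(K3) == 1.0

    def test_chain_has_no_triangles(self):
        assert transitivity(CHAIN3) == 0.0

    def test_isolated_pairs_undefined(self):
        W = np.array([[0.0, 1.0], [1.0, 0.0]])
        with pytest.warns(UndefinedMeasureWarning):
            assert np.isnan(transitivity(W))

    def test_ratio_form(self):
        assert transitivity_from_counts(74.73, 92) == pytest.approx(0.81, abs=0.005)

    def test_matches_triple_loop(self, random_graphs):
        for W in random_graphs[:100]:
            assert transitivity(W) == pytest.approx(transitivity_triple_loop(W))


class TestAssortativity:
    def test_regular_ring_undefined(self):
        ring = np.roll(np.eye(5), 1, axis=1) + np.roll(np.eye(5), -1, axis=1)
        with pytest.warns(UndefinedMeasureWarning):
            assert np.isnan(assortativity(ring))

    def test_star_matches_direct_sums(self):
        W = star(5)
        assert assortativity(W) == pytest.approx(assortativity_direct(W))

    def test_matches_direct_sums_on_random_graphs(self, random_graphs):
        for W in random_graphs[:100]:
            expected = assortativity_direct(W)
            if np.isnan(expected):
                continue
            assert assortativity(W) == pytest.approx(expected)

    def test_unit_weight_graph_matches_networkx(self):
        # binary graphs reduce to Newman's degree assortativity
        rng = np.random.default_rng(4)
        for _ in range(10):
            A = (build_weighted_adjacency(random_epoch(rng, 12)) > 0).astype(float)
            G = nx.from_numpy_array(A)
            expected = nx.degree_pearson_correlation_coefficient(G)
            assert assortativity(A) == pytest.approx(expected, abs=1e-8)


class TestDistances:
    def test_two_nodes(self):
        W = np.array([[0.0, 1.5], [1.5, 0.0]])
        d = distance_matrix(W)
        assert d[0, 1] == 1.5

    def test_direct_mode_is_the_matrix(self, random_graphs):
        W = random_graphs[0]
        np.testing.assert_array_equal(distance_matrix(W, mode="direct"), W)

    def test_matches_floyd_warshall(self, random_graphs):
        for W in random_graphs[:100]:
            np.testing.assert_allclose(distance_matrix(W), floyd_warshall(W),
                                       atol=1e-12)

    def test_shortest_never_longer_than_edge(self, random_graphs):
        for W in random_graphs[:30]:
            d = distance_matrix(W)
            mask = W > 0
            assert np.all(d[mask] <= W[mask] + 1e-12)

    def test_triangle_inequality(self, random_graphs):
        for W in random_graphs[:20]:
            d = distance_matrix(W)
            n = d.shape[0]
            for k in range(n):
                assert np.all(d <= d[:, [k]] + d[[k], :] + 1e-12)


class TestPathSummaries:
    def test_unit_chain_diameter(self):
        n = 7
        W = np.diag(np.ones(n - 1), 1) + np.diag(np.ones(n - 1), -1)
        asp, e, diam = path_summaries(distance_matrix(W))
        assert diam == n - 1

    def test_matches_double_loop(self, random_graphs):
        for W in random_graphs[:50]:
            d = distance_matrix(W)
            n = d.shape[0]
            s = se = 0.0
            for i in range(n):
                for j in range(n):
                    if i != j:
                        s += d[i, j]
                        if d[i, j] > 0:
                            se += 1.0 / d[i, j]
            asp, e, diam = path_summaries(d)
            assert asp == pytest.approx(s / (n * (n - 1)))
            assert e == pytest.approx(se / (n * (n - 1)))
            assert diam == pytest.approx(d.max())

    def test_all_zero_off_diagonal_efficiency_undefined(self):
        with pytest.warns(UndefinedMeasureWarning):
            asp, e, diam = path_summaries(np.zeros((3, 3)))
        assert asp == 0.0 and np.isnan(e)


class TestBetweenness:
    def test_star_center(self):
        n = 6
        B, cpd = betweenness_cpd(star(n))
        assert B[0] == pytest.approx((n - 1) * (n - 2) / 2)
        np.testing.assert_allclose(B[1:], 0.0)
        assert cpd == pytest.approx(B[0] * (n - 1) / (n - 1))

    def test_matches_path_enumeration(self, rng):
        for _ in range(30):
            W = build_weighted_adjacency(random_epoch(rng, int(rng.integers(4, 9))))
            B, _ = betweenness_cpd(W)
            np.testing.assert_allclose(B, betweenness_path_enumeration(W),
                                       atol=1e-9)

    def test_matches_networkx_on_binary_graphs(self, random_graphs):
        # unit weights make path-length ties exact, so the library's
        # exact-equality tie handling and ours must coincide
        for W in random_graphs[:20]:
            A = (W > 0).astype(float)
            G = nx.from_numpy_array(A)
            expected = nx.betweenness_centrality(G, normalized=False,
                                                 weight="weight")
            B, _ = betweenness_cpd(A)
            np.testing.assert_allclose(
                B, [expected[i] for i in range(A.shape[0])], atol=1e-8)

    def test_direct_mode_is_zero(self):
        B, cpd = betweenness_cpd(star(5), d_mode="direct")
        assert np.all(B == 0) and cpd == 0.0


class TestCloseness:
    def test_two_nodes(self):
        d = np.array([[0.0, 1.0], [1.0, 0.0]])
        np.testing.assert_allclose(closeness(d), [2.0, 2.0])

    def test_constant_matrix(self):
        n, c = 5, 0.3
        d = c * (np.ones((n, n)) - np.eye(n))
        np.testing.assert_allclose(closeness(d), n / ((n - 1) * c))

    def test_matches_row_sums(self, random_graphs):
        for W in random_graphs[:30]:
            d = distance_matrix(W)
            np.testing.assert_allclose(closeness(d), d.shape[0] / d.sum(axis=1))


class TestWeightMoments:
    def test_matches_flat_accumulation(self, random_graphs):
        for W in random_graphs[:50]:
            aw, mu, s, skew, kurt = weight_moments(W)
            flat = W.ravel()
            n2 = flat.size
            m = flat.sum() / n2
            sd = np.sqrt(((flat - m) ** 2).sum() / n2)
            assert aw == pytest.approx(flat.sum() / W.shape[0])
            assert mu == pytest.approx(m)
            assert s == pytest.approx(sd)
            assert skew == pytest.approx(((flat - m) ** 3).sum() / n2 / sd ** 3)
            assert kurt == pytest.approx(((flat - m) ** 4).sum() / n2 / sd ** 4)

    def test_constant_matrix_moments_undefined(self):
        with pytest.warns(UndefinedMeasureWarning):
            aw, mu, s, skew, kurt = weight_moments(np.zeros((4, 4)))
        assert np.isnan(skew) and np.isnan(kurt)


class TestComputeAll:
    def test_chain_of_three(self):
        out = compute_all(CHAIN3)
        assert out["AD"] == pytest.approx(4 / 3)
        assert out["Den"] == pytest.approx(2 / 3)
        assert out["ACC"] == 0.0
        assert out["T"] == 0.0          # one connected triple, no triangle

    def test_all_names_present(self, random_graphs):
        out = compute_all(random_graphs[0])
        assert list(out) == MEASURE_NAMES

    def test_subset_skips_path_measures(self, random_graphs):
        out = compute_all(random_graphs[0], measures=["AD", "AW"])
        assert list(out) == ["AD", "AW"]

    def test_unknown_measure_rejected(self, random_graphs):
        with pytest.raises(ValueError, match="unknown measure"):
            compute_all(random_graphs[0], measures=["AD", "motif"])

    def test_permutation_invariance(self, rng, random_graphs):
        for W in random_graphs[:10]:
            n = W.shape[0]
            perm = rng.permutation(n)
            Wp = W[np.ix_(perm, perm)]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", UndefinedMeasureWarning)
                a, b = compute_all(W), compute_all(Wp)
            for name in MEASURE_NAMES:
                if np.isnan(a[name]):
                    assert np.isnan(b[name])
                else:
                    assert a[name] == pytest.approx(b[name]), name
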