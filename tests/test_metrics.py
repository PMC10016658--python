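import numpy as np
import pytest

import _oracles as oracle
from caninet.connectivity import DensityGrid, build_connectivity
from caninet.metrics import (
    characteristic_path_length,
    clustering_coefficient,
    degree_strength,
    global_efficiency,
    local_efficiency,
    metrics_over_densities,
    shortest_path_distances,
    small_worldness,
)


def _complete(n, w=1.0):
    m = np.full((n, n), w)
    np.fill_diagonal(m, 0.0)
    return m


class TestDistances:
    def test_inverse_weight_lengths(self):
        w = np.array([[0.0, 2.0], [2.0, 0.0]])
        d = shortest_path_distances(w)
        assert d[0, 1] == pytest.approx(0.5)

    def test_two_hop_path(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 1.0
        w[1, 2] = w[2, 1] = 1.0
        d = shortest_path_distances(w)
        assert d[0, 2] == pytest.approx(2.0)
        assert np.isinf(shortest_path_distances(np.zeros((3, 3)))[0, 2])

    def test_matches_scipy_dijkstra(self, rng):
        from scipy.sparse import csr_matrix
        from scipy.sparse.csgraph import dijkstra

        for _ in range(25):
            w = oracle.random_graph(rng, n_max=12)
            lengths = np.where(w > 0, 1.0 / np.where(w > 0, w, 1.0), 0.0)
            ref = dijkstra(csr_matrix(lengths), directed=False)
            assert np.allclose(shortest_path_distances(w), ref)


class TestMetricExamples:
    def test_complete_graph_values(self):
        w = _complete(5)
        assert characteristic_path_length(w)[0] == pytest.approx(1.0)
        assert global_efficiency(w)[0] == pytest.approx(1.0)
        assert clustering_coefficient(w)[0] == pytest.approx(1.0)
        assert degree_strength(w)[1][0] == pytest.approx(4.0)

    def test_three_node_line(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 1.0
        w[1, 2] = w[2, 1] = 1.0
        assert characteristic_path_length(w)[0] == pytest.approx(4.0 / 3.0)

    def test_star_graph_has_no_clustering(self):
        w = np.zeros((5, 5))
        w[0, 1:] = w[1:, 0] = 1.0
        assert clustering_coefficient(w)[0] == 0.0
        assert local_efficiency(w)[0] == 0.0

    def test_complete_graph_local_efficiency(self):
        assert local_efficiency(_complete(4))[0] == pytest.approx(1.0)

    def test_empty_graph(self):
        w = np.zeros((4, 4))
        assert global_efficiency(w)[0] == 0.0
        assert np.isnan(characteristic_path_length(w)[0])
        assert degree_strength(w)[0] == 0.0

    def test_handshake_identity(self, rng):
        w = oracle.random_graph(rng, n_max=10)
        total, nodal = degree_strength(w)
        assert nodal.sum() == pytest.approx(2 * np.triu(w, 1).sum())

    def test_uniform_weights_reduce_to_binary_clustering(self, rng):
        import networkx as nx

        for _ in range(20):
            w = (oracle.random_graph(rng, n_max=8) > 0) * 0.7
            g = nx.from_numpy_array(w)
            ref = nx.clustering(g)  # binary on uniform weights
            _, nodal = clustering_coefficient(w)
            assert np.allclose(nodal, [ref[i] for i in range(w.shape[0])])

    def test_edge_addition_never_lengthens_paths(self, rng):
        w = oracle.random_graph(rng, n_max=8)
        d0 = shortest_path_distances(w)
        zeros = np.argwhere(np.triu(w == 0, 1))
        if len(zeros):
            i, j = zeros[0]
            w2 = w.copy()
            w2[i, j] = w2[j, i] = 0.5
            d1 = shortest_path_distances(w2)
            assert np.all(d1 <= d0 + 1e-12)


class TestOracleEquivalence:
    def test_all_metrics_match_brute_force_small_graphs(self):
        """Every metric equals exhaustive path enumeration on <=6 nodes."""
        rng = np.random.default_rng(2024)
        pairs = [
            (characteristic_path_length, oracle.brute_lp),
            (global_efficiency, oracle.brute_eglob),
            (clustering_coefficient, oracle.brute_onnela_cp),
            (local_efficiency, oracle.brute_eloc),
            (degree_strength, oracle.brute_strength),
        ]
        for _ in range(200):
            w = oracle.random_graph(rng, n_max=6)
            for fast, brute in pairs:
                g_fast, n_fast = fast(w)
                g_brute, n_brute = brute(w)
                assert np.allclose(n_fast, n_brute, equal_nan=True), fast.__name__
                if np.isnan(g_brute):
                    assert np.isnan(g_fast)
                else:
                    assert g_fast == pytest.approx(g_brute), fast.__name__


class TestInvariances:
    def test_normalised_metrics_bounded(self, rng):
        for _ in range(20):
            w = oracle.random_graph(rng, n_max=8)
            if w.max() > 0:
                w = w / w.max()
            assert np.all(clustering_coefficient(w)[1] <= 1.0 + 1e-12)
            assert np.all(global_efficiency(w)[1] <= 1.0 + 1e-12)
            assert np.all(local_efficiency(w)[1] <= 1.0 + 1e-12)

    def test_isomorphism_invariance(self, rng):
        w = oracle.random_graph(rng, n_max=8)
        perm = rng.permutation(w.shape[0])
        wp = w[np.ix_(perm, perm)]
        for fn in (
            characteristic_path_length,
            global_efficiency,
            clustering_coefficient,
            local_efficiency,
            degree_strength,
        ):
            a, b = fn(w)[0], fn(wp)[0]
            assert (np.isnan(a) and np.isnan(b)) or a == pytest.approx(b)


class TestSmallWorldness:
    def test_random_network_sigma_near_one(self, rng):
        n = 30
        k = 131  # density 0.3
        iu, ju = np.triu_indices(n, 1)
        pick = rng.choice(iu.size, size=k, replace=False)
        w = np.zeros((n, n))
        w[iu[pick], ju[pick]] = rng.uniform(0.1, 1.0, k)
        w = w + w.T
        sigma = small_worldness(w, n_nulls=100, seed=7)
        assert 0.8 <= sigma <= 1.2

    def test_lattice_with_shortcuts_is_small_world(self, rng):
        # Watts-Strogatz regime: ring lattice (4 neighbours) + a few shortcuts
        n = 30
        w = np.zeros((n, n))
        for i in range(n):
            for step in (1, 2):
                j = (i + step) % n
                w[i, j] = w[j, i] = 1.0
        for _ in range(6):
            i, j = rng.integers(0, n, 2)
            if i != j:
                w[i, j] = w[j, i] = 1.0
        assert small_worldness(w, n_nulls=50, seed=3) > 1.0

    def test_scale_invariance(self, rng):
        w = oracle.random_graph(rng, n_max=10)
        if np.count_nonzero(w) < 8:
            w = _complete(6, 0.5)
        a = small_worldness(w, n_nulls=20, seed=5)
        b = small_worldness(3.7 * w, n_nulls=20, seed=5)
        assert a == pytest.approx(b, rel=1e-9)

    def test_sigma_on_own_null_ensemble_concentrates_near_one(self):
        """Generating networks from the null model itself must give
        sigma ~ 1 on average."""
        rng = np.random.default_rng(77)
        n, k = 30, 131
        iu, ju = np.triu_indices(n, 1)
        sigmas = []
        for _ in range(50):
            pick = rng.choice(iu.size, size=k, replace=False)
            w = np.zeros((n, n))
            w[iu[pick], ju[pick]] = rng.uniform(0.1, 1.0, k)
            w = w + w.T
            sigmas.append(small_worldness(w, n_nulls=30, seed=rng))
        assert 0.9 <= np.mean(sigmas) <= 1.1

    def test_rejects_too_few_nulls(self):
        with pytest.raises(ValueError):
            small_worldness(_complete(5), n_nulls=5)


class TestMetricsOverDensities:
    def test_averaging_and_monotonicity(self, default_cohort):
        subjects, _ = default_cohort
        conn = build_connectivity(subjects[0].data, "s1")
        sm = metrics_over_densities(conn, include_sigma=False)
        # density average is the arithmetic mean of the per-level values
        assert np.allclose(
            sm.global_avg.values, sm.global_per_density.mean(axis=0).values
        )
        # nested edge sets: Eglob and mean degree rise with density
        eglob = sm.global_per_density["Eglob"].values
        deg = sm.global_per_density["degree"].values
        assert np.all(np.diff(eglob) >= -1e-12)
        assert np.all(np.diff(deg) >= -1e-12)

    def test_constant_metric_average(self):
        data = np.random.default_rng(0).standard_normal((100, 6))
        conn = build_connectivity(data, "x", DensityGrid((0.4, 0.5)))
        sm = metrics_over_densities(conn, include_sigma=False)
        manual = sm.global_per_density["Cp"].mean()
        assert sm.global_avg["Cp"] == pytest.approx(manual)
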