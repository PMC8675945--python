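import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from chronosoil.network import (
    build_network,
    classify_role,
    detect_modules,
    positive_link_fraction,
    rmt_threshold,
    sample_subnetwork,
    sparcc,
    topology,
    zi_pi,
)
from chronosoil.simulate import (
    NetworkTruth,
    block_correlation_truth,
    simulate_compositional_counts,
)


def _corr_frames(c, p=None):
    ids = [f"O{i}" for i in range(c.shape[0])]
    cf = pd.DataFrame(c, index=ids, columns=ids)
    if p is None:
        p = np.full_like(c, 0.01, dtype=float)
    pf = pd.DataFrame(p, index=ids, columns=ids)
    return cf, pf


class TestSparcc:
    def test_independent_taxa_estimated_near_zero(self):
        truth = NetworkTruth(np.eye(20))
        table = simulate_compositional_counts(truth, 50, depth=5000, seed=3)
        corr, _ = sparcc(table, n_bootstrap=20, seed=4)
        off = corr.values[np.triu_indices(20, 1)]
        assert np.abs(off).mean() < 0.15

    def test_planted_strong_pair_recovered_and_significant(self):
        c = np.eye(20)
        c[0, 1] = c[1, 0] = 0.9
        table = simulate_compositional_counts(NetworkTruth(c), 50,
                                              depth=5000, seed=5)
        corr, pvals = sparcc(table, n_bootstrap=60, seed=6)
        assert corr.iloc[0, 1] > 0.6
        assert pvals.iloc[0, 1] < 0.05

    def test_sample_order_invariance(self):
        truth = NetworkTruth(np.eye(8))
        table = simulate_compositional_counts(truth, 12, depth=500, seed=7)
        corr, _ = sparcc(table, n_bootstrap=5, seed=8)
        perm = np.random.default_rng(0).permutation(12)
        corr2, _ = sparcc(table.iloc[perm], n_bootstrap=5, seed=8)
        assert np.allclose(corr.values, corr2.values)

    def test_input_floor_errors(self):
        truth = NetworkTruth(np.eye(8))
        table = simulate_compositional_counts(truth, 12, depth=500, seed=9)
        with pytest.raises(ValueError, match="10 samples"):
            sparcc(table.iloc[:5])
        with pytest.raises(ValueError, match="4 OTUs"):
            sparcc(table.iloc[:, :3])


class TestRmtThreshold:
    def _block_matrix(self, seed=1):
        rng = np.random.default_rng(seed)
        truth = block_correlation_truth(30, [15, 15], within=0.8,
                                        jitter=0.15, seed=2)
        c = truth.correlation.copy()
        off = truth.modules[:, None] != truth.modules[None, :]
        noise = rng.uniform(-0.3, 0.3, size=c.shape)
        noise = (noise + noise.T) / 2
        c[off] = noise[off]
        np.fill_diagonal(c, 1.0)
        return c

    def test_block_structure_threshold_between_noise_and_signal(self):
        thr, scan = rmt_threshold(self._block_matrix())
        assert 0.3 < thr <= 0.8

    def test_edge_count_monotone_in_cutoff(self):
        _, scan = rmt_threshold(self._block_matrix())
        assert (np.diff(scan["n_edges"]) <= 0).all()

    def test_small_matrix_rejected(self):
        with pytest.raises(ValueError, match="small"):
            rmt_threshold(np.eye(10))

    def test_no_transition_raises(self):
        # constant strong correlations: degenerate spectrum at every cutoff
        c = np.full((25, 25), 0.95)
        np.fill_diagonal(c, 1.0)
        with pytest.raises(ValueError, match="scan range"):
            rmt_threshold(c, scan_range=(0.3, 0.9))


class TestBuildNetwork:
    def test_threshold_and_alpha_conjunction(self):
        c = np.eye(3)
        c[0, 1] = c[1, 0] = 0.7
        c[0, 2] = c[2, 0] = 0.5
        cf, pf = _corr_frames(c)
        g = build_network(cf, pf, threshold=0.5924)
        assert g.number_of_edges() == 1
        assert g.number_of_nodes() == 2
        assert g.has_edge("O0", "O1")

    def test_all_below_threshold_gives_empty_network(self):
        cf, pf = _corr_frames(np.eye(4) * 1.0)
        g = build_network(cf, pf, threshold=0.5)
        assert g.number_of_edges() == 0

    def test_significance_required_even_for_strong_correlation(self):
        c = np.eye(3)
        c[0, 1] = c[1, 0] = 0.99
        p = np.full((3, 3), 0.2)
        cf, pf = _corr_frames(c, p)
        g = build_network(cf, pf, threshold=0.5)
        assert g.number_of_edges() == 0

    def test_signs_and_positive_fraction(self):
        c = np.eye(4)
        c[0, 1] = c[1, 0] = 0.9
        c[2, 3] = c[3, 2] = -0.8
        cf, pf = _corr_frames(c)
        g = build_network(cf, pf, threshold=0.5)
        assert positive_link_fraction(g) == pytest.approx(0.5)

    def test_raising_cutoff_never_adds_edges(self):
        rng = np.random.default_rng(0)
        c = rng.uniform(-1, 1, size=(12, 12))
        c = (c + c.T) / 2
        np.fill_diagonal(c, 1.0)
        cf, pf = _corr_frames(c)
        prev = None
        for thr in np.linspace(0.1, 0.95, 12):
            edges = set(map(frozenset, build_network(cf, pf, thr).edges))
            if prev is not None:
                assert edges <= prev
            prev = edges


class TestSampleSubnetwork:
    def _triangle(self):
        cf, pf = _corr_frames(np.array(
            [[1, .8, .8], [.8, 1, .8], [.8, .8, 1.0]]))
        return build_network(cf, pf, 0.5)

    def test_full_sample_reproduces_global(self):
        g = self._triangle()
        sub = sample_subnetwork(g, ["O0", "O1", "O2"])
        assert set(sub.edges) == set(g.edges)

    def test_two_of_three_nodes_leaves_single_edge(self):
        sub = sample_subnetwork(self._triangle(), ["O0", "O1"])
        assert sub.number_of_edges() == 1

    def test_disjoint_sample_gives_empty_subnetwork(self):
        sub = sample_subnetwork(self._triangle(), ["X1", "X2"])
        assert sub.number_of_nodes() == 0


class TestTopology:
    def test_triangle_complete_graph(self):
        g = nx.Graph([("a", "b"), ("b", "c"), ("a", "c")])
        t = topology(g)
        assert t.transitivity == pytest.approx(1.0)
        assert t.density == pytest.approx(1.0)
        assert t.average_degree == pytest.approx(2.0)
        assert t.average_path_length == pytest.approx(1.0)

    def test_path_graph_hand_values(self):
        g = nx.Graph([("a", "b"), ("b", "c")])
        t = topology(g)
        assert t.transitivity == 0.0
        assert t.density == pytest.approx(2 / 3)
        assert t.average_path_length == pytest.approx(4 / 3)
        # normalized betweenness: b carries the single a-c path
        assert t.mean_betweenness == pytest.approx(1 / 3)

    def test_disconnected_pairs_use_reachable_pairs_only(self):
        g = nx.Graph([("a", "b"), ("c", "d")])
        assert topology(g).average_path_length == pytest.approx(1.0)

    def test_tiny_graph_gives_nan(self):
        g = nx.Graph()
        g.add_node("a")
        t = topology(g)
        assert np.isnan(t.density)


def _brute_force_metrics(g: nx.Graph):
    """Independent small-graph oracle via adjacency powers and BFS."""
    nodes = sorted(g.nodes)
    n = len(nodes)
    a = nx.to_numpy_array(g, nodelist=nodes, weight=None)
    # triangles and connected triples
    tri = np.trace(a @ a @ a) / 6
    deg = a.sum(axis=1)
    triples = (deg * (deg - 1) / 2).sum()
    transitivity = 3 * tri / triples if triples else 0.0
    # shortest-path lengths via successive powers
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0)
    power = np.eye(n)
    powers = [power]
    for d in range(1, n):
        power = power @ a
        powers.append(power)
        newly = (power > 0) & np.isinf(dist)
        dist[newly] = d
    finite = np.isfinite(dist) & ~np.eye(n, dtype=bool)
    apl = dist[finite].mean() if finite.any() else np.nan
    # betweenness via shortest-path counts from adjacency powers
    bc = np.zeros(n)
    for s, t in itertools.combinations(range(n), 2):
        d = dist[s, t]
        if not np.isfinite(d) or d < 2:
            continue
        sigma = powers[int(d)][s, t]
        for v in range(n):
            if v in (s, t) or not np.isfinite(dist[s, v]) or not np.isfinite(dist[v, t]):
                continue
            if dist[s, v] + dist[v, t] == d:
                bc[v] += powers[int(dist[s, v])][s, v] * powers[int(dist[v, t])][v, t] / sigma
    norm = (n - 1) * (n - 2) / 2
    bc = bc / norm if norm > 0 else bc
    e = g.number_of_edges()
    return {
        "transitivity": transitivity,
        "average_degree": 2 * e / n,
        "mean_betweenness": bc.mean(),
        "average_path_length": apl,
        "density": 2 * e / (n * (n - 1)),
    }


class TestTopologyAgainstBruteForce:
    def test_all_five_node_graphs(self):
        nodes = list(range(5))
        pairs = list(itertools.combinations(nodes, 2))
        for mask in range(1, 2 ** len(pairs)):
            g = nx.Graph()
            g.add_nodes_from(nodes)
            for k, (i, j) in enumerate(pairs):
                if mask >> k & 1:
                    g.add_edge(i, j)
            expected = _brute_force_metrics(g)
            got = topology(g)
            for key, val in expected.items():
                actual = getattr(got, key)
                if np.isnan(val):
                    assert np.isnan(actual)
                else:
                    assert actual == pytest.approx(val, abs=1e-9), (mask, key)


class TestModulesAndRoles:
    def test_disconnected_cliques_form_two_modules(self):
        g = nx.Graph()
        for offset in (0, 10):
            for i, j in itertools.combinations(range(offset, offset + 4), 2):
                g.add_edge(i, j, weight=0.9)
        modules, q = detect_modules(g)
        assert len(set(modules.values())) == 2
        assert len({modules[i] for i in range(4)}) == 1

    def test_weakly_bridged_cliques_split_at_bridge(self):
        g = nx.Graph()
        for offset in (0, 10):
            for i, j in itertools.combinations(range(offset, offset + 5), 2):
                g.add_edge(i, j, weight=0.9)
        g.add_edge(0, 10, weight=0.1)
        modules, q = detect_modules(g)
        assert len(set(modules.values())) == 2
        assert modules[0] != modules[10]

    def test_deterministic(self):
        g = nx.Graph([("a", "b", {"weight": 0.5})])
        m1, q1 = detect_modules(g, seed=1)
        m2, q2 = detect_modules(g, seed=2)
        assert m1 == m2 and q1 == q2

    def test_pi_zero_for_fully_internal_node(self):
        g = nx.Graph()
        g.add_edges_from([("a", "b"), ("a", "c"), ("b", "c")])
        roles = zi_pi(g, {"a": 0, "b": 0, "c": 0})
        assert (roles["Pi"] == 0.0).all()
        assert (roles["role"] == "peripheral").all()

    def test_even_split_participation(self):
        g = nx.Graph()
        g.add_edges_from([("x", "a1"), ("x", "a2"), ("x", "b1"), ("x", "b2")])
        modules = {"x": 0, "a1": 0, "a2": 0, "b1": 1, "b2": 1}
        roles = zi_pi(g, modules)
        assert roles.loc["x", "Pi"] == pytest.approx(0.5)

    def test_constructed_module_hub_and_network_hub(self):
        g = nx.Graph()
        modules = {}
        # module 0: hub h0 wired to 12 leaves; modules 1 and 2: 6-cliques
        for i in range(12):
            g.add_edge("h0", f"m0_{i}")
            modules[f"m0_{i}"] = 0
        modules["h0"] = 0
        for m in (1, 2):
            for i, j in itertools.combinations(range(6), 2):
                g.add_edge(f"m{m}_{i}", f"m{m}_{j}")
            for i in range(6):
                modules[f"m{m}_{i}"] = m
        roles = zi_pi(g, modules)
        assert roles.loc["h0", "Zi"] > 2.5
        assert roles.loc["h0", "role"] == "module_hub"
        assert roles.loc["h0", "keystone"]
        # wire h0 evenly into modules 1 and 2: participation rises past 0.62
        for m in (1, 2):
            for i in range(6):
                g.add_edge("h0", f"m{m}_{i}")
        roles2 = zi_pi(g, modules)
        k = 24
        expected_pi = 1 - ((12 / k) ** 2 + (6 / k) ** 2 + (6 / k) ** 2)
        assert roles2.loc["h0", "Pi"] == pytest.approx(expected_pi)
        assert expected_pi > 0.62
        assert roles2.loc["h0", "role"] == "network_hub"

    def test_missing_module_assignment_rejected(self):
        g = nx.Graph([("a", "b")])
        with pytest.raises(ValueError, match="module"):
            zi_pi(g, {"a": 0})

    def test_degree_conservation_and_pi_range(self, rng):
        g = nx.gnp_random_graph(30, 0.2, seed=3)
        modules, _ = detect_modules(g)
        roles = zi_pi(g, modules)
        assert ((roles["Pi"] >= 0) & (roles["Pi"] <= 1)).all()


class TestRolePartition:
    def test_exhaustive_and_exclusive_over_grid(self):
        zi_grid = np.concatenate([np.linspace(-3, 5, 30), [2.5]])
        pi_grid = np.concatenate([np.linspace(0, 1, 30), [0.62]])
        valid = {"peripheral", "connector", "module_hub", "network_hub"}
        for zi, pi in itertools.product(zi_grid, pi_grid):
            assert classify_role(zi, pi) in valid

    def test_boundaries_fall_to_lower_role(self):
        assert classify_role(2.5, 0.62) == "peripheral"
        assert classify_role(2.5, 0.9) == "connector"
        assert classify_role(3.0, 0.62) == "module_hub"
        assert classify_role(3.0, 0.63) == "network_hub"
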