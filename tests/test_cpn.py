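import itertools

import numpy as np
import pytest
from scipy import stats

from mgx.cpn import (
    cpn_objective,
    cpn_properties,
    detect_core,
    ideal_pattern,
    shared_core_observed,
    shared_core_permutated,
    shared_node_sets_observed,
)
from mgx.io import OTUTableError
from mgx.synthetic import PlantedNetworkSpec, generate_planted_network_cohort

from test_network import net_from_edges


def perfect_cpn(k, n_per):
    """Ideal core/periphery graph: K_k core, periphery tied to every core node."""
    edges = list(itertools.combinations(range(k), 2))
    edges += [(c, k + p) for c in range(k) for p in range(n_per)]
    return net_from_edges(k + n_per, edges)


def brute_force_max(adj):
    n = adj.shape[0]
    best = -1
    for bits in range(1, 2**n - 1):
        delta = np.array([(bits >> i) & 1 for i in range(n)], dtype=bool)
        best = max(best, cpn_objective(adj, delta))
    return best


class TestObjective:
    def test_perfect_graph_attains_ordered_edge_count(self):
        net = perfect_cpn(3, 4)
        delta = np.array([1, 1, 1] + [0] * 4, dtype=bool)
        assert cpn_objective(net.adjacency(), delta) == 2 * net.n_edges

    def test_empty_graph_zero(self):
        adj = np.zeros((4, 4), dtype=int)
        assert cpn_objective(adj, np.array([1, 0, 0, 1], dtype=bool)) == 0

    def test_periphery_edge_contributes_nothing(self):
        net = net_from_edges(4, [(2, 3)])
        delta = np.array([1, 1, 0, 0], dtype=bool)
        assert cpn_objective(net.adjacency(), delta) == 0

    def test_all_core_rejected(self):
        adj = np.zeros((3, 3), dtype=int)
        with pytest.raises(OTUTableError):
            cpn_objective(adj, np.ones(3, dtype=bool))

    def test_ideal_pattern_shape(self):
        P = ideal_pattern([1, 0, 0])
        assert np.array_equal(P, P.T)
        assert np.all(np.diag(P) == 0)
        assert P[1, 2] == 0 and P[0, 1] == 1 and P[0, 2] == 1


class TestDetectCore:
    def test_planted_perfect_cpn_recovered(self):
        net = perfect_cpn(4, 8)
        part = detect_core(net, n_restarts=20, seed=0)
        assert part.core == [f"n{i}" for i in range(4)]
        assert part.rho == 2 * net.n_edges

    def test_matches_exhaustive_search(self):
        rng = np.random.default_rng(1)
        for trial in range(20):
            n = int(rng.integers(4, 11))
            pairs = [p for p in itertools.combinations(range(n), 2) if rng.random() < 0.35]
            if not pairs:
                continue
            net = net_from_edges(n, pairs)
            part = detect_core(net, n_restarts=20, seed=trial)
            assert part.rho == brute_force_max(net.adjacency().astype(int))

    def test_seed_determinism(self):
        t = generate_planted_network_cohort(PlantedNetworkSpec(seed=3), 100)
        from mgx.network import build_scn

        net = build_scn(t, min_total=0)
        p1 = detect_core(net, n_restarts=10, seed=5)
        p2 = detect_core(net, n_restarts=10, seed=5)
        assert p1.core == p2.core and p1.rho == p2.rho

    def test_label_symmetry(self):
        """Relabeling nodes permutes the membership vector; rho is unchanged."""
        net = perfect_cpn(3, 5)
        part = detect_core(net, n_restarts=10, seed=0)
        perm = np.array([5, 2, 7, 0, 1, 3, 4, 6])
        remapped_edges = [(int(perm[i]), int(perm[j])) for i, j in net.edges]
        net2 = net_from_edges(8, remapped_edges)
        part2 = detect_core(net2, n_restarts=10, seed=0)
        assert part2.rho == part.rho
        assert set(part2.core) == {f"n{perm[int(i)]}" for i, d in enumerate(part.delta) if d}

    def test_rho_consistent_with_objective(self):
        net = perfect_cpn(4, 4)
        part = detect_core(net, n_restarts=5, seed=0)
        assert part.rho == cpn_objective(net.adjacency(), part.delta)


class TestSharedObserved:
    def test_identical_cores_p_near_one(self):
        res = shared_node_sets_observed(list("abcde"), list("abcde"),
                                        universe=list("abcdefghij"), n_perm=200, seed=0)
        assert res.p_value > 0.9

    def test_disjoint_cores_match_hypergeometric(self):
        universe = list("abcdefghij")
        res = shared_node_sets_observed(list("abcde"), list("fghij"), universe,
                                        n_perm=2000, seed=1)
        # overlap of two random 5-subsets of 10: P(overlap == 0) from the
        # hypergeometric distribution
        p_exact = stats.hypergeom.cdf(0, 10, 5, 5)
        assert res.p_value == pytest.approx(p_exact, abs=0.02)

    def test_empty_core_rejected(self):
        with pytest.raises(OTUTableError):
            shared_node_sets_observed([], ["a"], ["a", "b"], n_perm=10, seed=0)

    def test_detects_from_networks(self):
        net = perfect_cpn(4, 8)
        res = shared_core_observed(net, net, n_perm=100, seed=0)
        assert res.p_value > 0.9
        assert res.extra["partitionA"].core == res.extra["partitionB"].core


class TestSharedPermutated:
    def test_seed_determinism(self):
        spec = PlantedNetworkSpec(n_taxa=25, core_size=5, n_periphery=10,
                                  core_strength=0.98, periphery_strength=0.95, seed=8)
        t = generate_planted_network_cohort(spec, 80)
        a = t.select_samples(t.sample_ids[:40])
        b = t.select_samples(t.sample_ids[40:])
        r1 = shared_core_permutated(a, b, n_perm=30, seed=2, n_restarts=3)
        r2 = shared_core_permutated(a, b, n_perm=30, seed=2, n_restarts=3)
        assert np.array_equal(r1.null_values, r2.null_values)
        assert r1.observed == r2.observed


class TestCPNProperties:
    def test_perfect_graph_densities(self):
        net = perfect_cpn(4, 6)
        part = detect_core(net, n_restarts=10, seed=0)
        props = cpn_properties(net, part)
        assert props["core_density"] == pytest.approx(1.0)
        assert props["periphery_density"] == pytest.approx(0.0)
        assert props["core_periphery_density"] == pytest.approx(1.0)

    def test_densities_bounded(self):
        rng = np.random.default_rng(4)
        pairs = [p for p in itertools.combinations(range(12), 2) if rng.random() < 0.4]
        net = net_from_edges(12, pairs)
        part = detect_core(net, n_restarts=10, seed=0)
        props = cpn_properties(net, part)
        for key in ("core_density", "periphery_density", "core_periphery_density"):
            assert 0.0 <= props[key] <= 1.0
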