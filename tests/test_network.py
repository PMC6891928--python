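import itertools

import numpy as np
import pytest
from scipy import stats
from statsmodels.stats.multitest import multipletests

from mgx.io import OTUTableError
from mgx.network import (
    SignedNetwork,
    build_scn,
    compare_network_stat,
    permutated_pairs,
    properties,
    read_edgelist,
    spearman_edges,
    trio_census,
    write_edgelist,
)
from mgx.synthetic import PlantedNetworkSpec, generate_planted_network_cohort

from conftest import make_table


def net_from_edges(n, edges, rho=None):
    """Hand-built SignedNetwork over nodes n0..n(n-1)."""
    nodes = [f"n{i}" for i in range(n)]
    e = np.asarray(sorted(tuple(sorted(p)) for p in edges), dtype=int).reshape(-1, 2)
    r = np.ones(len(e)) if rho is None else np.asarray(rho, dtype=float)
    return SignedNetwork(nodes, e, r, np.zeros(len(e)))


class TestBuildSCN:
    def test_planted_pair_is_only_edge(self):
        # constant column totals so the relative-abundance transform keeps
        # the planted pair's ranks aligned
        rng = np.random.default_rng(0)
        x = rng.random(50) + 1.0
        rows = [x, x**2]  # perfectly rank-correlated pair
        rows += [rng.uniform(0, 100, 50) for _ in range(8)]
        mat = np.array(rows)
        filler = mat.sum(axis=0).max() + 10 - mat.sum(axis=0)
        t = make_table(np.vstack([mat, filler]))
        net = build_scn(t, fdr_alpha=0.001, min_total=0)
        edge_ids = net.edge_ids()
        assert ("otu0", "otu1") in edge_ids
        assert len(edge_ids) == 1
        rho = {tuple(sorted((net.nodes[i], net.nodes[j]))): r
               for (i, j), r in zip(net.edges, net.rho)}
        assert rho[("otu0", "otu1")] == pytest.approx(1.0)

    def test_anticorrelated_pair_negative_edge(self):
        rng = np.random.default_rng(1)
        x = np.arange(50, dtype=float)
        rows = [x + 1, 100 - x] + [rng.random(50) * 50 for _ in range(5)]
        t = make_table(np.array(rows))
        net = build_scn(t, min_total=0)
        signs = {tuple(sorted((net.nodes[i], net.nodes[j]))): r for (i, j), r in zip(net.edges, net.rho)}
        assert signs[("otu0", "otu1")] < 0

    def test_independent_taxa_fdr_controls_edges(self):
        counts = []
        for seed in range(25):
            rng = np.random.default_rng(100 + seed)
            t = make_table(rng.random((30, 60)) * 100 + 1)
            counts.append(build_scn(t, min_total=0).n_edges)
        assert np.mean(counts) < 1.0

    def test_too_few_samples_rejected(self):
        t = make_table(np.ones((5, 4)))
        with pytest.raises(OTUTableError):
            build_scn(t)

    def test_invariant_to_sample_order(self):
        spec = PlantedNetworkSpec(seed=5)
        t = generate_planted_network_cohort(spec, 80)
        net1 = build_scn(t, min_total=0)
        shuffled = t.select_samples(list(np.array(t.sample_ids)[np.random.default_rng(0).permutation(80)]))
        net2 = build_scn(shuffled, min_total=0)
        assert net1.edge_ids() == net2.edge_ids()

    def test_matches_scipy_spearman(self):
        """The vectorized rank-correlation screen equals scipy's tie-corrected
        Spearman coefficient and t-approximation p-values."""
        rng = np.random.default_rng(2)
        rel = rng.integers(0, 8, size=(6, 25)).astype(float)  # many ties
        rel = rel / rel.sum(axis=0)
        edges, rho, padj = spearman_edges(rel, fdr_alpha=1.0, raw_p=True)
        for (i, j), r, p in zip(edges, rho, padj):
            sr = stats.spearmanr(rel[i], rel[j])
            assert r == pytest.approx(sr.statistic, abs=1e-12)
            assert p == pytest.approx(sr.pvalue, rel=1e-6)


class TestProperties:
    def test_complete_graph(self):
        net = net_from_edges(5, itertools.combinations(range(5), 2))
        p = properties(net)
        assert p.density == pytest.approx(1.0)
        assert p.clustering_coefficient == pytest.approx(1.0)
        assert p.pn_ratio == float("inf")

    def test_five_cycle(self):
        net = net_from_edges(5, [(i, (i + 1) % 5) for i in range(5)])
        p = properties(net)
        assert p.density == pytest.approx(0.5)
        assert p.clustering_coefficient == 0.0
        assert p.diameter_of_largest_component == 2

    def test_balanced_signs_unit_pn(self):
        net = net_from_edges(4, [(0, 1), (1, 2), (2, 3), (3, 0)], rho=[0.5, -0.5, 0.9, -0.9])
        assert properties(net).pn_ratio == pytest.approx(1.0)

    def test_empty_graph_sentinels(self):
        net = net_from_edges(3, [])
        p = properties(net)
        assert p.n_edges == 0 and p.density == 0.0

    def test_round_trip_edgelist(self, tmp_path):
        net = net_from_edges(6, [(0, 1), (2, 3), (1, 4)], rho=[0.9, -0.4, 0.7])
        path = tmp_path / "net.tsv"
        write_edgelist(net, str(path))
        back = read_edgelist(str(path))
        assert back.nodes == net.nodes
        assert back.edge_ids() == net.edge_ids()
        np.testing.assert_allclose(back.rho, net.rho)


class TestTrioCensus:
    def test_star_dlm_count(self):
        # MAO at center of a 4-leaf star: every leaf pair is a DLM
        net = net_from_edges(5, [(0, i) for i in range(1, 5)])
        t = make_table(np.array([[100], [1], [1], [1], [1]]), otu_ids=net.nodes)
        census = trio_census(net, t)
        assert census.mao_id == "n0"
        assert census.dlm == 6
        assert census.n_pairs == 6

    def test_triangle_not_dlm(self):
        net = net_from_edges(3, [(0, 1), (0, 2), (1, 2)])
        t = make_table(np.array([[9], [1], [1]]), otu_ids=net.nodes)
        census = trio_census(net, t)
        assert census.dlm == 0
        assert sum(census.counts.values()) == 1

    def test_matches_bruteforce_enumeration(self):
        rng = np.random.default_rng(3)
        for trial in range(5):
            n = int(rng.integers(8, 25))
            pairs = [p for p in itertools.combinations(range(n), 2) if rng.random() < 0.2]
            rho = rng.uniform(-1, 1, len(pairs))
            rho[rho == 0] = 0.5
            net = net_from_edges(n, pairs, rho=[r for _, r in sorted(zip(
                [tuple(sorted(p)) for p in pairs], rho))])
            tot = rng.integers(1, 1000, n).astype(float)
            t = make_table(tot[:, None], otu_ids=net.nodes)
            census = trio_census(net, t)
            # brute force: inspect all trios containing the MAO
            sign = {tuple(sorted((net.nodes[i], net.nodes[j]))): ("+" if r > 0 else "-")
                    for (i, j), r in zip(net.edges, net.rho)}
            mao = census.mao_id
            others = [v for v in net.nodes if v != mao]
            dlm = 0
            total = 0
            for u, v in itertools.combinations(others, 2):
                total += 1
                su = sign.get(tuple(sorted((mao, u))))
                sv = sign.get(tuple(sorted((mao, v))))
                suv = sign.get(tuple(sorted((u, v))))
                if (su is not None) and (sv is not None) and suv is None:
                    dlm += 1
            assert census.dlm == dlm
            assert census.n_pairs == total
            assert sum(census.counts.values()) == total


class TestPermutatedPairs:
    def test_sizes_and_determinism(self):
        spec = PlantedNetworkSpec(n_taxa=15, core_size=4, n_periphery=4, seed=0)
        t = generate_planted_network_cohort(spec, 40)
        a = t.select_samples(t.sample_ids[:25])
        b = t.select_samples(t.sample_ids[25:])
        run1 = list(permutated_pairs(a, b, n=5, seed=4, min_total=0))
        run2 = list(permutated_pairs(a, b, n=5, seed=4, min_total=0))
        for (p1, q1), (p2, q2) in zip(run1, run2):
            assert p1.n_nodes == 15 and q1.n_nodes == 15
            assert p1.edge_ids() == p2.edge_ids()
            assert q1.edge_ids() == q2.edge_ids()


class TestCompareNetworkStat:
    def test_equal_stats_p_one(self):
        null = [(0.5, 0.4)] * 120
        res = compare_network_stat(2.0, 2.0, null)
        assert res.p_value == pytest.approx(1.0)

    def test_p_floor(self):
        null = [(0.5, 0.5)] * 200
        res = compare_network_stat(10.0, 0.0, null)
        assert res.p_value == pytest.approx(1 / 201)

    def test_undefined_stats_rejected(self):
        null = [(float("inf"), 1.0)] * 60 + [(1.0, 1.0)] * 60
        with pytest.raises(OTUTableError, match="undefined"):
            compare_network_stat(1.0, 2.0, null)


def test_bh_adjustment_matches_stepup_oracle():
    """statsmodels' fdr_bh equals the direct step-up procedure."""
    rng = np.random.default_rng(6)
    for _ in range(5):
        p = rng.random(200)
        adj = multipletests(p, method="fdr_bh")[1]
        m = len(p)
        order = np.argsort(p)
        stepup = np.empty(m)
        running = 1.0
        for rank in range(m, 0, -1):
            idx = order[rank - 1]
            running = min(running, p[idx] * m / rank)
            stepup[idx] = running
        np.testing.assert_allclose(adj, stepup, atol=1e-12)
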