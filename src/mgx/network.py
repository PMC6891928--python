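"""Species co-occurrence networks (SCN) from Spearman correlations.

Nodes are OTUs; an edge joins two OTUs whose relative abundances across
samples are rank-correlated with a Benjamini-Hochberg adjusted p-value at or
below a (stringent) threshold, 0.001 by default.  Edges are signed by the
correlation.  The module also computes basic network properties, the
positive-to-negative edge ratio, the census of trio motifs anchored at the
most abundant OTU (MAO), and the pooled-and-resplit permutated network
pairs on which every network-level null model in the package rests.

Correlation is Pearson-on-ranks, which equals the tie-corrected Spearman
coefficient; p-values come from the t-distribution approximation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import networkx as nx
import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import OTUTable, OTUTableError, filter_min_total, to_relative
from .permtest import PermutationResult, child_rng, perm_pvalue

__all__ = [
    "SignedNetwork",
    "NetworkProperties",
    "TrioCensus",
    "build_scn",
    "properties",
    "trio_census",
    "permutated_pairs",
    "compare_network_stat",
    "write_edgelist",
    "read_edgelist",
]


@dataclass
class SignedNetwork:
    """Undirected OTU graph with signed Spearman weights.

    ``edges`` holds index pairs into ``nodes`` with i < j; ``rho`` and
    ``p_adj`` are aligned per-edge arrays.
    """

    nodes: list[str]
    edges: np.ndarray  # (E, 2) int
    rho: np.ndarray  # (E,)
    p_adj: np.ndarray  # (E,)
    alpha: float = 0.001

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return int(self.edges.shape[0])

    def edge_ids(self) -> set[tuple[str, str]]:
        """Edges as unordered (sorted) taxon-id pairs."""
        out = set()
        for i, j in self.edges:
            u, v = self.nodes[int(i)], self.nodes[int(j)]
            out.add((u, v) if u <= v else (v, u))
        return out

    def adjacency(self) -> np.ndarray:
        """Unsigned binary adjacency matrix (n x n)."""
        n = self.n_nodes
        A = np.zeros((n, n), dtype=np.int8)
        if self.n_edges:
            i, j = self.edges[:, 0], self.edges[:, 1]
            A[i, j] = 1
            A[j, i] = 1
        return A

    def weight_matrix(self) -> np.ndarray:
        """Signed correlation weights w_ij (0 where no edge)."""
        n = self.n_nodes
        W = np.zeros((n, n))
        if self.n_edges:
            i, j = self.edges[:, 0], self.edges[:, 1]
            W[i, j] = self.rho
            W[j, i] = self.rho
        return W

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for (i, j), r, p in zip(self.edges, self.rho, self.p_adj):
            g.add_edge(self.nodes[int(i)], self.nodes[int(j)], rho=float(r), p_adj=float(p))
        return g


@dataclass
class NetworkProperties:
    n_nodes: int
    n_edges: int
    density: float
    mean_degree: float
    clustering_coefficient: float
    n_components: int
    diameter_of_largest_component: int
    degree_skewness: float
    pn_ratio: float  # +inf sentinel when there are no negative edges

    def as_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class TrioCensus:
    """Census of MAO-anchored trios by edge configuration and sign pattern.

    Every unordered pair {u, v} of non-MAO nodes defines one trio
    {MAO, u, v}; its class records how many of the two MAO-incident edges
    and the u-v edge are present, and their signs.  ``dlm`` counts the
    double-link MAO trios: exactly two edges, both incident to the MAO.
    """

    mao_id: str
    counts: dict[str, int] = field(default_factory=dict)
    dlm: int = 0
    n_pairs: int = 0


# ---------------------------------------------------------------------------
# construction


def spearman_edges(
    rel: np.ndarray,
    fdr_alpha: float = 0.001,
    raw_p: bool = False,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """All-pairs tie-corrected Spearman screen on a taxa-x-samples matrix.

    Returns (edge index pairs, rho, adjusted p) for pairs passing the FDR
    threshold.  Taxa with zero rank variance never form edges.
    """
    k, n = rel.shape
    ranks = stats.rankdata(rel, axis=1)
    sd = ranks.std(axis=1)
    ok = sd > 0
    ranks = ranks - ranks.mean(axis=1, keepdims=True)
    norm = np.sqrt((ranks**2).sum(axis=1))
    norm[norm == 0] = 1.0
    ranks /= norm[:, None]
    rho = ranks @ ranks.T
    np.clip(rho, -1.0, 1.0, out=rho)
    iu, ju = np.triu_indices(k, 1)
    valid = ok[iu] & ok[ju]
    iu, ju = iu[valid], ju[valid]
    r = rho[iu, ju]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r**2, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    if p.size == 0:
        return np.empty((0, 2), dtype=int), np.empty(0), np.empty(0)
    if raw_p:
        padj = p
    else:
        padj = multipletests(p, method="fdr_bh")[1]
    keep = (padj <= fdr_alpha) & (r != 0)
    return np.column_stack([iu[keep], ju[keep]]), r[keep], padj[keep]


def _scn_from_matrix(
    counts: np.ndarray,
    ids: Sequence[str],
    fdr_alpha: float,
    min_total: float,
    raw_p: bool = False,
) -> SignedNetwork | None:
    """numpy-only SCN construction (prefilter + normalize + screen).

    Returns None when fewer than 2 taxa survive or a sample has zero total;
    the matrix path and the public :func:`build_scn` are equivalent.
    """
    keep = counts.sum(axis=1) >= min_total
    sub = counts[keep]
    if sub.shape[0] < 2:
        return None
    totals = sub.sum(axis=0)
    if np.any(totals <= 0):
        return None
    rel = sub / totals
    edges, rho, padj = spearman_edges(rel, fdr_alpha, raw_p)
    nodes = [i for i, k in zip(ids, keep) if k]
    return SignedNetwork(nodes, edges, rho, padj, fdr_alpha)


def build_scn(
    table: OTUTable,
    fdr_alpha: float = 0.001,
    min_total: int = 80,
    raw_p: bool = False,
) -> SignedNetwork:
    """Build the species co-occurrence network of one cohort.

    Applies the minimum-total-reads prefilter, converts to relative
    abundance, screens all OTU pairs by Spearman correlation and keeps
    edges whose BH-adjusted p-value is at most ``fdr_alpha`` (set
    ``raw_p=True`` to threshold the unadjusted p-values instead).
    """
    if table.n_samples < 10:
        raise OTUTableError("co-occurrence networks need at least 10 samples")
    if table.mode == "relative":
        edges, rho, padj = spearman_edges(table.counts, fdr_alpha, raw_p)
        return SignedNetwork(list(table.otu_ids), edges, rho, padj, fdr_alpha)
    # validate the zero-total-sample contract through the public transforms
    filtered = filter_min_total(table, min_total)
    if filtered.n_taxa < 2:
        raise OTUTableError("fewer than 2 taxa survive the read-count prefilter")
    to_relative(filtered)
    net = _scn_from_matrix(table.counts, table.otu_ids, fdr_alpha, min_total, raw_p)
    assert net is not None
    return net


# ---------------------------------------------------------------------------
# properties


def properties(net: SignedNetwork) -> NetworkProperties:
    """Basic properties of the unsigned graph, plus the P/N edge ratio."""
    g = nx.Graph()
    g.add_nodes_from(range(net.n_nodes))
    g.add_edges_from((int(i), int(j)) for i, j in net.edges)
    n, m = net.n_nodes, net.n_edges
    if n == 0:
        return NetworkProperties(0, 0, 0.0, 0.0, 0.0, 0, 0, 0.0, float("inf"))
    density = nx.density(g)
    degrees = np.array([d for _, d in g.degree()], dtype=float)
    clustering = float(nx.average_clustering(g)) if n > 0 else 0.0
    comps = list(nx.connected_components(g))
    largest = max(comps, key=len)
    diameter = int(nx.diameter(g.subgraph(largest))) if len(largest) > 1 else 0
    skew = float(stats.skew(degrees)) if n > 2 and degrees.std() > 0 else 0.0
    pos = int(np.count_nonzero(net.rho > 0))
    neg = int(np.count_nonzero(net.rho < 0))
    pn = float(pos) / neg if neg > 0 else float("inf")
    return NetworkProperties(n, m, float(density), float(degrees.mean()) if n else 0.0,
                             clustering, len(comps), diameter, skew, pn)


def trio_census(net: SignedNetwork, table: OTUTable) -> TrioCensus:
    """Classify every MAO-anchored trio by edge configuration and signs.

    The MAO is the network node with the greatest total reads in ``table``
    (ties broken by lexicographic taxon id).  Class labels look like
    ``"2L-MAO:++"`` (a DLM with two positive MAO edges) or
    ``"1L-MAO+UV:+/-"``; unconnected trios are counted under ``"0L"`` so
    the class counts sum to C(n-1, 2).
    """
    node_set = set(net.nodes)
    totals = {o: t for o, t in zip(table.otu_ids, table.counts.sum(axis=1)) if o in node_set}
    if not totals:
        raise OTUTableError("no network node found in the abundance table")
    mao = min(totals, key=lambda o: (-totals[o], o))
    idx = {o: i for i, o in enumerate(net.nodes)}
    m_i = idx[mao]
    sign = {}
    for (i, j), r in zip(net.edges, net.rho):
        key = (int(i), int(j)) if i < j else (int(j), int(i))
        sign[key] = "+" if r > 0 else "-"

    def edge_sign(a: int, b: int) -> str | None:
        return sign.get((a, b) if a < b else (b, a))

    others = [i for i in range(net.n_nodes) if i != m_i]
    counts: dict[str, int] = {}
    dlm = 0
    n_pairs = 0
    for ai in range(len(others)):
        u = others[ai]
        su = edge_sign(m_i, u)
        for bi in range(ai + 1, len(others)):
            v = others[bi]
            n_pairs += 1
            sv = edge_sign(m_i, v)
            suv = edge_sign(u, v)
            n_mao = (su is not None) + (sv is not None)
            mao_signs = "".join(sorted(s for s in (su, sv) if s is not None))
            if n_mao == 0 and suv is None:
                label = "0L"
            else:
                label = f"{n_mao}L-MAO" + ("+UV" if suv is not None else "")
                sig = mao_signs + (f"/{suv}" if suv is not None else "")
                label = f"{label}:{sig}" if sig else label
                if label.endswith(":"):
                    label = label[:-1]
            counts[label] = counts.get(label, 0) + 1
            if n_mao == 2 and suv is None:
                dlm += 1
    return TrioCensus(mao, counts, dlm, n_pairs)


# ---------------------------------------------------------------------------
# permutated network pairs and property comparison


def permutated_pairs(
    tableA: OTUTable,
    tableB: OTUTable,
    n: int = 1000,
    seed: int | None = None,
    fdr_alpha: float = 0.001,
    min_total: int = 80,
) -> Iterator[tuple[SignedNetwork, SignedNetwork]]:
    """Yield network pairs built from pooled-and-resplit sample columns.

    Each pair pools all samples of both cohorts, reassigns them at random
    to two groups of the original sizes, and builds one SCN per group.
    Pairs where a network cannot be built (too few surviving taxa) yield
    ``(None, None)``; callers decide how many failures to tolerate.
    """
    if tableA.otu_ids != tableB.otu_ids:
        raise OTUTableError("cohort tables must be row-aligned")
    pooled = np.hstack([tableA.counts, tableB.counts])
    ids = list(tableA.otu_ids)
    nA = tableA.n_samples
    ncol = pooled.shape[1]
    rng = child_rng(seed)
    for _ in range(n):
        perm = rng.permutation(ncol)
        netA = _scn_from_matrix(pooled[:, perm[:nA]], ids, fdr_alpha, min_total)
        netB = _scn_from_matrix(pooled[:, perm[nA:]], ids, fdr_alpha, min_total)
        if netA is None or netB is None:
            yield (None, None)
        else:
            yield (netA, netB)


def compare_network_stat(
    statA: float,
    statB: float,
    null_pairs_stats: Sequence[tuple[float, float]],
    max_undefined_rate: float = 0.05,
    seed: int | None = None,
) -> PermutationResult:
    """Permutation test of |statA - statB| against permutated-pair nulls.

    ``null_pairs_stats`` holds the same statistic evaluated on each
    permutated network pair.  Non-finite values (e.g. the P/N-ratio
    sentinel) are dropped; more than 5% undefined is an error.
    """
    pairs = list(null_pairs_stats)
    if len(pairs) < 100:
        raise OTUTableError("need at least 100 permutated pairs")
    diffs = np.array([abs(a - b) for a, b in pairs], dtype=float)
    bad = ~np.isfinite(diffs)
    observed = abs(statA - statB)
    if not np.isfinite(observed):
        raise OTUTableError("observed statistic is undefined")
    if np.count_nonzero(bad) > max_undefined_rate * len(pairs):
        raise OTUTableError(
            f"statistic undefined in {np.count_nonzero(bad)}/{len(pairs)} permutated pairs"
        )
    null = diffs[~bad]
    p = perm_pvalue(observed, null, tail="upper")
    return PermutationResult(observed, null, p, "upper", len(null), seed)


# ---------------------------------------------------------------------------
# export


def write_edgelist(net: SignedNetwork, path: str) -> None:
    """Edge-list TSV: u, v, rho, p_adj, sign (isolated nodes listed at top)."""
    with open(path, "w") as fh:
        fh.write("# nodes: " + ",".join(net.nodes) + "\n")
        fh.write("u\tv\trho\tp_adj\tsign\n")
        for (i, j), r, p in zip(net.edges, net.rho, net.p_adj):
            u, v = net.nodes[int(i)], net.nodes[int(j)]
            fh.write(f"{u}\t{v}\t{float(r)!r}\t{float(p)!r}\t{'+' if r > 0 else '-'}\n")


def read_edgelist(path: str, alpha: float = 0.001) -> SignedNetwork:
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines or not lines[0].startswith("# nodes:"):
        raise OTUTableError(f"{path}: not an mgx edge-list file")
    nodes = lines[0].split(":", 1)[1].strip().split(",") if lines[0].split(":", 1)[1].strip() else []
    idx = {o: i for i, o in enumerate(nodes)}
    edges, rho, padj = [], [], []
    for line in lines[2:]:
        if not line.strip():
            continue
        u, v, r, p, _sign = line.split("\t")
        i, j = idx[u], idx[v]
        edges.append((min(i, j), max(i, j)))
        rho.append(float(r))
        padj.append(float(p))
    return SignedNetwork(
        nodes,
        np.asarray(edges, dtype=int).reshape(-1, 2),
        np.asarray(rho),
        np.asarray(padj),
        alpha,
    )


def write_graphml(net: SignedNetwork, path: str) -> None:
    nx.write_graphml(net.graph(), path)
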