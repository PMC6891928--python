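"""Link salience and high-salience skeleton networks (HSN).

For a weighted network, the shortest-path tree T(x) rooted at node x marks
every edge that lies on at least one shortest path from x to any reachable
node.  The salience of an edge is the fraction of roots whose tree contains
it,

    s_ij = (1/N) * sum_x T_ij(x),

with N the number of network nodes (isolated nodes contribute empty trees).
Edge lengths are the inverse absolute correlation 1/|rho|, so the shortest
path is the strongest chain of associations.  The high-salience skeleton at
threshold s* keeps the edges with s >= s* while preserving all nodes;
skeletons are nested in s*.

An edge (u, v) of weight w lies on a shortest path from root x iff
d(x, u) + w = d(x, v) or d(x, v) + w = d(x, u), which is how the tree
membership is evaluated (exactly, up to floating tolerance) from the
all-sources distance matrix — this is the "at least one shortest path"
reading and needs no tie-break.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra

from .io import OTUTable, OTUTableError
from .network import NetworkProperties, SignedNetwork, build_scn, permutated_pairs, properties
from .permtest import PermutationResult, perm_pvalue

__all__ = [
    "SalienceMap",
    "Skeleton",
    "shortest_path_tree",
    "link_salience",
    "extract_skeleton",
    "shared_skeleton_analysis",
    "hsn_properties",
]

_RTOL = 1e-9
_ATOL = 1e-12


@dataclass
class SalienceMap:
    """Per-edge link salience for a source network."""

    network: SignedNetwork
    salience: np.ndarray  # aligned with network.edges, values in [0, 1]
    n_roots: int


@dataclass
class Skeleton:
    """Edges at or above a salience threshold; node set preserved."""

    network: SignedNetwork
    threshold: float
    edge_mask: np.ndarray  # bool over source edges

    @property
    def nodes(self) -> list[str]:
        return self.network.nodes

    @property
    def edges(self) -> np.ndarray:
        return self.network.edges[self.edge_mask]

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(self.edge_mask))

    def edge_ids(self) -> set[tuple[str, str]]:
        out = set()
        for i, j in self.edges:
            u, v = self.network.nodes[int(i)], self.network.nodes[int(j)]
            out.add((u, v) if u <= v else (v, u))
        return out

    def as_network(self) -> SignedNetwork:
        return SignedNetwork(
            list(self.network.nodes),
            self.network.edges[self.edge_mask],
            self.network.rho[self.edge_mask],
            self.network.p_adj[self.edge_mask],
            self.network.alpha,
        )


def _length_matrix(net: SignedNetwork) -> csr_matrix:
    """Sparse edge-length matrix with lengths 1/|rho|."""
    n = net.n_nodes
    if net.n_edges == 0:
        return csr_matrix((n, n))
    i = net.edges[:, 0]
    j = net.edges[:, 1]
    w = 1.0 / np.abs(net.rho)
    rows = np.concatenate([i, j])
    cols = np.concatenate([j, i])
    vals = np.concatenate([w, w])
    return csr_matrix((vals, (rows, cols)), shape=(n, n))


def _distance_matrix(net: SignedNetwork) -> np.ndarray:
    return dijkstra(_length_matrix(net), directed=False)


def _tree_membership(net: SignedNetwork, dist: np.ndarray) -> np.ndarray:
    """T[x, e] = 1 iff edge e lies on some shortest path from root x."""
    n_edges = net.n_edges
    n = net.n_nodes
    if n_edges == 0:
        return np.zeros((n, 0), dtype=bool)
    u = net.edges[:, 0]
    v = net.edges[:, 1]
    w = 1.0 / np.abs(net.rho)
    du = dist[:, u]  # (n_roots, n_edges)
    dv = dist[:, v]
    with np.errstate(invalid="ignore"):
        fwd = np.isclose(du + w[None, :], dv, rtol=_RTOL, atol=_ATOL)
        bwd = np.isclose(dv + w[None, :], du, rtol=_RTOL, atol=_ATOL)
    reach = np.isfinite(du) & np.isfinite(dv)
    return (fwd | bwd) & reach


def shortest_path_tree(net: SignedNetwork, root: str) -> set[tuple[str, str]]:
    """Edges of T(root): every edge on at least one shortest path from root."""
    if root not in net.nodes:
        raise OTUTableError(f"root {root!r} not in network")
    r = net.nodes.index(root)
    dist = _distance_matrix(net)
    T = _tree_membership(net, dist)
    out = set()
    for e in np.flatnonzero(T[r]):
        i, j = net.edges[e]
        a, b = net.nodes[int(i)], net.nodes[int(j)]
        out.add((a, b) if a <= b else (b, a))
    return out


def link_salience(net: SignedNetwork) -> SalienceMap:
    """Salience of every edge: mean tree membership over all N node roots."""
    if net.n_nodes == 0:
        raise OTUTableError("empty network")
    dist = _distance_matrix(net)
    T = _tree_membership(net, dist)
    sal = T.mean(axis=0) if net.n_edges else np.empty(0)
    return SalienceMap(net, np.asarray(sal, dtype=float), net.n_nodes)


def extract_skeleton(sal: SalienceMap, s_star: float) -> Skeleton:
    """Skeleton at threshold s*: edges with salience >= s*, all nodes kept."""
    if not 0.0 <= s_star <= 1.0:
        raise OTUTableError("salience threshold must lie in [0, 1]")
    mask = sal.salience >= s_star if sal.salience.size else np.zeros(0, dtype=bool)
    return Skeleton(sal.network, s_star, mask)


def skeleton_of_table(
    table: OTUTable, s_star: float, fdr_alpha: float = 0.001, min_total: int = 80
) -> Skeleton:
    net = build_scn(table, fdr_alpha, min_total)
    return extract_skeleton(link_salience(net), s_star)


def shared_skeleton_analysis(
    tableA: OTUTable,
    tableB: OTUTable,
    s_star: float = 0.25,
    n_perm: int = 1000,
    seed: int | None = None,
    fdr_alpha: float = 0.001,
    min_total: int = 80,
    max_failure_rate: float = 0.05,
    tail: str = "lower",
) -> PermutationResult:
    """Shared-skeleton permutation test (permutated-network strategy only).

    The observed statistic counts skeleton edges (as unordered taxon pairs)
    common to the two cohorts' skeletons at threshold ``s_star``; the null
    recomputes the count on pooled-and-resplit network pairs with salience
    re-evaluated per pair.
    """
    skelA = skeleton_of_table(tableA, s_star, fdr_alpha, min_total)
    skelB = skeleton_of_table(tableB, s_star, fdr_alpha, min_total)
    observed = len(skelA.edge_ids() & skelB.edge_ids())
    null: list[int] = []
    failures = 0
    for pA, pB in permutated_pairs(tableA, tableB, n_perm, seed, fdr_alpha, min_total):
        if pA is None:
            failures += 1
            continue
        sA = extract_skeleton(link_salience(pA), s_star)
        sB = extract_skeleton(link_salience(pB), s_star)
        null.append(len(sA.edge_ids() & sB.edge_ids()))
    if failures > max_failure_rate * n_perm:
        raise OTUTableError(f"network build failed in {failures}/{n_perm} permutated pairs")
    p = perm_pvalue(observed, null, tail=tail)
    res = PermutationResult(float(observed), np.asarray(null, dtype=float), p, tail,
                            len(null), seed)
    res.extra = {"s_star": s_star, "skeletonA": skelA, "skeletonB": skelB,
                 "failures": failures}
    return res


def hsn_properties(skeleton: Skeleton) -> NetworkProperties:
    """Basic network properties of the skeleton graph."""
    return properties(skeleton.as_network())
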