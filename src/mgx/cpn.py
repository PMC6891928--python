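"""Core/periphery structure in co-occurrence networks.

The ideal core/periphery network has a fully linked core and a periphery
connected only to the core.  Given a binary membership vector delta
(1 = core) the ideal pattern P has p_ij = 1 unless both i and j are
periphery, and the match between the observed adjacency A and the pattern is

    rho = sum_ij a_ij p_ij    (over ordered pairs, zero diagonal),

i.e. twice the number of edges touching the core.  Detection maximizes rho
over delta by greedy single-node label switching from random restarts plus
a degree-ranked start.  Because the objective as stated never penalizes a
too-large core, ties in rho are broken toward the smaller core (then
lexicographically), which recovers the minimal ideal core on planted
core/periphery graphs.

Shared-core (and shared-periphery) species between two cohorts are tested
under two strategies: permuting the detected node sets themselves
(observed-network strategy) or re-detecting cores on pooled-and-resplit
permutated network pairs (permutated-network strategy).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import OTUTable, OTUTableError
from .network import SignedNetwork, build_scn, permutated_pairs, properties
from .permtest import PermutationResult, child_rng, perm_pvalue

__all__ = [
    "CorePartition",
    "cpn_objective",
    "ideal_pattern",
    "detect_core",
    "shared_core_observed",
    "shared_core_permutated",
    "cpn_properties",
]


@dataclass
class CorePartition:
    """A core/periphery split of a network's nodes."""

    nodes: list[str]
    delta: np.ndarray  # bool, True = core
    rho: float

    @property
    def core(self) -> list[str]:
        return [n for n, d in zip(self.nodes, self.delta) if d]

    @property
    def periphery(self) -> list[str]:
        return [n for n, d in zip(self.nodes, self.delta) if not d]

    @property
    def n_core(self) -> int:
        return int(np.count_nonzero(self.delta))

    @property
    def n_periphery(self) -> int:
        return len(self.nodes) - self.n_core


def ideal_pattern(delta) -> np.ndarray:
    """Pattern matrix P implied by delta: p_ij = 0 only for periphery pairs."""
    d = np.asarray(delta, dtype=bool)
    P = np.ones((d.size, d.size), dtype=np.int8)
    pp = ~d
    P[np.ix_(pp, pp)] = 0
    P[np.ix_(d, d)] = 1
    np.fill_diagonal(P, 0)
    return P


def cpn_objective(adjacency, delta) -> int:
    """rho = sum over ordered pairs of a_ij * p_ij (symmetric double count)."""
    A = np.asarray(adjacency)
    d = np.asarray(delta, dtype=bool)
    if A.shape[0] != A.shape[1] or A.shape[0] != d.size:
        raise OTUTableError("adjacency and delta sizes disagree")
    if not np.array_equal(A, A.T) or np.any(np.diag(A) != 0):
        raise OTUTableError("adjacency must be symmetric with zero diagonal")
    if d.all() or not d.any():
        raise OTUTableError("delta must name at least one core and one periphery node")
    total_twice = int(A.sum())  # ordered-pair edge count
    pp = ~d
    periph_edges_twice = int(A[np.ix_(pp, pp)].sum())
    return total_twice - periph_edges_twice


def _greedy(A: np.ndarray, delta: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Label switching to a local optimum; equal-rho flips shrink the core."""
    n = A.shape[0]
    delta = delta.copy()
    changed = True
    while changed:
        changed = False
        for v in rng.permutation(n):
            periph_nb = int(A[v] @ (~delta))  # edges from v to periphery
            if delta[v]:
                if periph_nb == 0 and delta.sum() > 1:
                    # flipping out loses nothing and shrinks the core
                    delta[v] = False
                    changed = True
            else:
                nb_periph = periph_nb  # v itself is periphery, A[v,v]=0
                if nb_periph > 0:
                    delta[v] = True
                    changed = True
    if not delta.any():
        # edgeless graph: nominate the lexicographically first node
        delta[0] = True
    if delta.all():
        # keep the contract 1 <= n_core < n: demote a zero-loss node
        loss = A @ (~delta)  # all zeros here
        delta[int(np.argmin(loss))] = False
    return delta


def detect_core(net: SignedNetwork, n_restarts: int = 50, seed: int | None = None) -> CorePartition:
    """Maximize the core/periphery objective by greedy switching with restarts.

    Runs ``n_restarts`` random initializations plus one degree-ranked start;
    the best rho wins, ties broken by smaller core and then lexicographic
    membership vector.  Deterministic for a fixed seed.
    """
    if net.n_nodes < 3:
        raise OTUTableError("core/periphery detection needs at least 3 nodes")
    if net.n_edges < 1:
        raise OTUTableError("core/periphery detection needs at least 1 edge")
    A = net.adjacency().astype(np.int64)
    n = net.n_nodes
    rng = child_rng(seed)
    deg = A.sum(axis=1)
    starts = []
    top = deg > deg.mean()
    if not top.any():
        top = np.zeros(n, dtype=bool)
        top[int(np.argmax(deg))] = True
    if top.all():
        top[int(np.argmin(deg))] = False
    starts.append(top)
    for _ in range(n_restarts):
        init = rng.random(n) < 0.5
        if init.all():
            init[int(rng.integers(n))] = False
        if not init.any():
            init[int(rng.integers(n))] = True
        starts.append(init)
    best: tuple[int, int, tuple] | None = None
    best_delta = None
    for init in starts:
        delta = _greedy(A, init, rng)
        rho = cpn_objective(A, delta)
        key = (-rho, int(delta.sum()), tuple(delta.astype(int)))
        if best is None or key < best:
            best = key
            best_delta = delta
    return CorePartition(list(net.nodes), best_delta, float(-best[0]))


# ---------------------------------------------------------------------------
# shared core/periphery analyses


def shared_node_sets_observed(
    setA,
    setB,
    universe,
    n_perm: int = 1000,
    seed: int | None = None,
    tail: str = "lower",
) -> PermutationResult:
    """Overlap of two node sets vs random same-size subsets of the universe."""
    sA, sB, uni = set(setA), set(setB), list(universe)
    if not sA or not sB:
        raise OTUTableError("empty node set in shared-node analysis")
    observed = len(sA & sB)
    rng = child_rng(seed)
    uni_arr = np.asarray(uni, dtype=object)
    nA, nB = len(sA), len(sB)
    null = np.empty(n_perm, dtype=np.int64)
    for i in range(n_perm):
        a = set(rng.choice(uni_arr, size=nA, replace=False))
        b = set(rng.choice(uni_arr, size=nB, replace=False))
        null[i] = len(a & b)
    p = perm_pvalue(observed, null, tail=tail)
    return PermutationResult(float(observed), null.astype(float), p, tail, n_perm, seed)


def shared_core_observed(
    netA: SignedNetwork,
    netB: SignedNetwork,
    n_perm: int = 1000,
    seed: int | None = None,
    which: str = "core",
    n_restarts: int = 50,
) -> PermutationResult:
    """Observed-network strategy: permute the detected core (or periphery) sets.

    Cores are detected once on each observed network; the null redraws
    node subsets of the same sizes from the union of the two node sets.
    """
    partA = detect_core(netA, n_restarts, seed=None if seed is None else seed + 1)
    partB = detect_core(netB, n_restarts, seed=None if seed is None else seed + 2)
    sA = partA.core if which == "core" else partA.periphery
    sB = partB.core if which == "core" else partB.periphery
    universe = sorted(set(netA.nodes) | set(netB.nodes))
    res = shared_node_sets_observed(sA, sB, universe, n_perm, seed)
    res.extra = {"partitionA": partA, "partitionB": partB, "which": which}
    return res


def shared_core_permutated(
    tableA: OTUTable,
    tableB: OTUTable,
    n_perm: int = 1000,
    seed: int | None = None,
    which: str = "core",
    n_restarts: int = 10,
    fdr_alpha: float = 0.001,
    min_total: int = 80,
    max_failure_rate: float = 0.05,
    tail: str = "lower",
) -> PermutationResult:
    """Permutated-network strategy for shared core (or periphery) species.

    The observed statistic counts taxa in both cohorts' detected sets; the
    null re-splits the pooled samples, rebuilds both networks and
    re-detects their cores for every permutation.
    """
    netA = build_scn(tableA, fdr_alpha, min_total)
    netB = build_scn(tableB, fdr_alpha, min_total)
    partA = detect_core(netA, n_restarts, seed=None if seed is None else seed + 1)
    partB = detect_core(netB, n_restarts, seed=None if seed is None else seed + 2)
    sA = set(partA.core if which == "core" else partA.periphery)
    sB = set(partB.core if which == "core" else partB.periphery)
    observed = len(sA & sB)
    null: list[int] = []
    failures = 0
    rng = child_rng(seed, 3)
    for pA, pB in permutated_pairs(tableA, tableB, n_perm, seed, fdr_alpha, min_total):
        if pA is None:
            failures += 1
            continue
        try:
            cA = detect_core(pA, n_restarts, seed=int(rng.integers(2**31)))
            cB = detect_core(pB, n_restarts, seed=int(rng.integers(2**31)))
        except OTUTableError:
            failures += 1
            continue
        a = set(cA.core if which == "core" else cA.periphery)
        b = set(cB.core if which == "core" else cB.periphery)
        null.append(len(a & b))
    if failures > max_failure_rate * n_perm:
        raise OTUTableError(
            f"core detection failed in {failures}/{n_perm} permutated pairs"
        )
    p = perm_pvalue(observed, null, tail=tail)
    res = PermutationResult(float(observed), np.asarray(null, dtype=float), p, tail,
                            len(null), seed)
    res.extra = {"partitionA": partA, "partitionB": partB, "which": which,
                 "failures": failures}
    return res


def cpn_properties(net: SignedNetwork, partition: CorePartition) -> dict:
    """Densities of the core, periphery and core-periphery blocks, plus the
    basic properties of the core-induced subgraph."""
    A = net.adjacency()
    d = np.asarray(partition.delta, dtype=bool)
    k = int(d.sum())
    npq = int((~d).sum())

    def block_density(mask_i, mask_j, same: bool) -> float:
        sub = A[np.ix_(mask_i, mask_j)]
        if same:
            ni = int(mask_i.sum())
            possible = ni * (ni - 1)
            return float(sub.sum() / possible) if possible else 0.0
        possible = int(mask_i.sum()) * int(mask_j.sum())
        return float(sub.sum() / possible) if possible else 0.0

    core_idx = np.flatnonzero(d)
    sub_edges = []
    remap = {int(i): r for r, i in enumerate(core_idx)}
    for i, j in net.edges:
        if d[int(i)] and d[int(j)]:
            sub_edges.append((remap[int(i)], remap[int(j)]))
    core_net = SignedNetwork(
        [net.nodes[int(i)] for i in core_idx],
        np.asarray(sub_edges, dtype=int).reshape(-1, 2),
        np.ones(len(sub_edges)),
        np.zeros(len(sub_edges)),
        net.alpha,
    )
    return {
        "rho": partition.rho,
        "n_core": k,
        "n_periphery": npq,
        "core_density": block_density(d, d, same=True),
        "periphery_density": block_density(~d, ~d, same=True),
        "core_periphery_density": block_density(d, ~d, same=False),
        "core_subgraph": properties(core_net),
    }
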