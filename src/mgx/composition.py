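"""Shared-species analysis between two cohorts with A1/A2 permutation nulls.

If each cohort carries its own specific species, the observed number of
species shared by the two cohorts falls below what random sampling from a
common community would produce.  Two null models test this:

* **A1** reshuffles reads: all pooled reads are reallocated at random
  between the cohorts, preserving each cohort's total read count.  This is
  realized exactly as a joint multivariate-hypergeometric split of each
  taxon's pooled reads (equivalent to labelling every read and shuffling).
* **A2** reshuffles samples: whole sample columns are reassigned to two
  groups of the original sizes.  A2 preserves within-sample structure and
  is the more conservative of the two.

Both report the add-one permutation p-value for the one-sided
"fewer shared species than chance" alternative by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import OTUTable, OTUTableError
from .permtest import PermutationResult, child_rng, perm_pvalue

__all__ = ["SharedSpeciesResult", "observed_shared", "shared_null_A1", "shared_null_A2"]


@dataclass
class SharedSpeciesResult:
    """Observed shared-species count, its permutation null, and species lists."""

    observed_shared: int
    null_samples: np.ndarray
    p_value: float
    algorithm: str  # 'A1' or 'A2'
    shared: list[str] = field(default_factory=list)
    specificA: list[str] = field(default_factory=list)
    specificB: list[str] = field(default_factory=list)
    tail: str = "lower"
    n_perm: int = 0
    seed: int | None = None

    @property
    def null_mean(self) -> float:
        return float(np.mean(self.null_samples))

    @property
    def null_sd(self) -> float:
        return float(np.std(self.null_samples, ddof=1))

    def as_permutation_result(self) -> PermutationResult:
        return PermutationResult(
            float(self.observed_shared), self.null_samples, self.p_value,
            self.tail, self.n_perm, self.seed,
        )


def _check_aligned(tableA: OTUTable, tableB: OTUTable) -> None:
    if tableA.otu_ids != tableB.otu_ids:
        raise OTUTableError("cohort tables must share an aligned taxon universe")


def observed_shared(tableA: OTUTable, tableB: OTUTable) -> tuple[list[str], list[str], list[str]]:
    """Shared and cohort-specific species by presence (total reads >= 1).

    Returns (shared, specificA, specificB); taxa absent from both cohorts
    are excluded entirely.
    """
    _check_aligned(tableA, tableB)
    totA = tableA.counts.sum(axis=1)
    totB = tableB.counts.sum(axis=1)
    ids = np.asarray(tableA.otu_ids, dtype=object)
    inA, inB = totA > 0, totB > 0
    shared = list(ids[inA & inB])
    specificA = list(ids[inA & ~inB])
    specificB = list(ids[~inA & inB])
    return shared, specificA, specificB


def shared_null_A1(
    tableA: OTUTable,
    tableB: OTUTable,
    n_perm: int = 1000,
    seed: int | None = None,
    tail: str = "lower",
) -> SharedSpeciesResult:
    """Read-reshuffling null for the shared-species count.

    Each permutation reallocates every pooled read to one of the two
    cohorts uniformly without replacement, preserving each cohort's total
    read count, then recounts species present (>= 1 read) in both.
    """
    if tableA.mode != "counts" or tableB.mode != "counts":
        raise OTUTableError("A1 reshuffles reads and requires counts-mode tables")
    _check_aligned(tableA, tableB)
    shared, specA, specB = observed_shared(tableA, tableB)
    totA = np.rint(tableA.counts.sum(axis=1)).astype(np.int64)
    totB = np.rint(tableB.counts.sum(axis=1)).astype(np.int64)
    pooled = totA + totB
    present = pooled > 0
    pooled = pooled[present]
    readsA = int(totA.sum())
    rng = child_rng(seed)
    null = np.empty(n_perm, dtype=np.int64)
    for i in range(n_perm):
        allocA = rng.multivariate_hypergeometric(pooled, readsA)
        null[i] = int(np.count_nonzero((allocA > 0) & (pooled - allocA > 0)))
    observed = len(shared)
    p = perm_pvalue(observed, null, tail=tail)
    return SharedSpeciesResult(observed, null, p, "A1", shared, specA, specB, tail, n_perm, seed)


def shared_null_A2(
    tableA: OTUTable,
    tableB: OTUTable,
    n_perm: int = 1000,
    seed: int | None = None,
    tail: str = "lower",
) -> SharedSpeciesResult:
    """Sample-reshuffling null for the shared-species count.

    Each permutation pools all sample columns and reassigns whole samples
    to two groups of the original sizes.  More conservative than A1 because
    within-sample co-occurrence structure is preserved.
    """
    if tableA.mode != "counts" or tableB.mode != "counts":
        raise OTUTableError("A2 reshuffles samples and requires counts-mode tables")
    _check_aligned(tableA, tableB)
    if tableA.n_samples < 2 or tableB.n_samples < 2:
        raise OTUTableError("A2 needs at least two samples per cohort")
    shared, specA, specB = observed_shared(tableA, tableB)
    pooled = np.hstack([tableA.counts, tableB.counts])
    nA = tableA.n_samples
    n = pooled.shape[1]
    rng = child_rng(seed)
    null = np.empty(n_perm, dtype=np.int64)
    for i in range(n_perm):
        perm = rng.permutation(n)
        sumA = pooled[:, perm[:nA]].sum(axis=1)
        sumB = pooled[:, perm[nA:]].sum(axis=1)
        null[i] = int(np.count_nonzero((sumA > 0) & (sumB > 0)))
    observed = len(shared)
    p = perm_pvalue(observed, null, tail=tail)
    return SharedSpeciesResult(observed, null, p, "A2", shared, specA, specB, tail, n_perm, seed)
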