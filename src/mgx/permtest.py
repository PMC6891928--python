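"""Shared permutation-test machinery.

Every null-model test in the package funnels through this module: the
add-one ("never zero") p-value convention, seeded whole-sample re-splits of
two pooled cohorts, and a counter-based child-seed scheme so any single test
in a batch is independently reproducible from one global seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

__all__ = ["PermutationResult", "perm_pvalue", "resplit", "child_seed", "child_rng"]


@dataclass
class PermutationResult:
    """Observed statistic, its permutation null, and the resulting p-value.

    p_value follows the add-one convention
    ``(#{null at least as extreme} + 1) / (n_perm + 1)`` and therefore never
    reaches zero; its floor is ``1/(n_perm+1)``.
    """

    observed: float
    null_values: np.ndarray
    p_value: float
    tail: str
    n_perm: int
    seed: int | None = None
    extra: dict = field(default_factory=dict)

    @property
    def null_mean(self) -> float:
        return float(np.mean(self.null_values))

    @property
    def null_sd(self) -> float:
        return float(np.std(self.null_values, ddof=1)) if len(self.null_values) > 1 else 0.0


def perm_pvalue(observed: float, null_values: Sequence[float], tail: str = "upper") -> float:
    """Add-one permutation p-value.

    tail='upper' counts null >= observed, 'lower' counts null <= observed,
    'two_sided' doubles the smaller tail (capped at 1).
    """
    null = np.asarray(null_values, dtype=float)
    if null.size == 0:
        raise ValueError("null_values must be non-empty")
    if np.isnan(null).any() or np.isnan(observed):
        raise ValueError("NaN in permutation null or observed statistic")
    n = null.size
    upper = (np.count_nonzero(null >= observed) + 1) / (n + 1)
    lower = (np.count_nonzero(null <= observed) + 1) / (n + 1)
    if tail == "upper":
        return float(upper)
    if tail == "lower":
        return float(lower)
    if tail == "two_sided":
        return float(min(1.0, 2.0 * min(lower, upper)))
    raise ValueError(f"unknown tail {tail!r}")


def child_seed(seed: int | None, index: int) -> int:
    """Derive a reproducible child seed (< 2**31) from a global seed."""
    ss = np.random.SeedSequence(seed, spawn_key=(index,))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def child_rng(seed: int | None, index: int = 0) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(index,)))


def resplit(
    samplesA: Sequence, samplesB: Sequence, seed: int | None, k: int
) -> Iterator[tuple[list, list]]:
    """Yield ``k`` uniform re-splits of the pooled samples.

    Each split partitions the pool into groups of the original sizes,
    drawn without replacement; the stream is fully determined by ``seed``.
    """
    pooled = list(samplesA) + list(samplesB)
    nA = len(samplesA)
    if nA == 0 or len(samplesB) == 0:
        raise ValueError("both groups must be non-empty")
    rng = child_rng(seed)
    for _ in range(k):
        perm = rng.permutation(len(pooled))
        yield [pooled[i] for i in perm[:nA]], [pooled[i] for i in perm[nA:]]
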