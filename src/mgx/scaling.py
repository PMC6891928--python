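"""Power-law scaling of heterogeneity (PLE) and diversity accrual (DAR/PLEC).

Two families of scaling law are fitted, both as ordinary least squares on
logarithmic scales:

* **Power-law extensions (PLE)** of Taylor's law, V = a·m^b.  Type-I takes
  one (mean, variance) point per sample, computed over the species within
  that sample, and b measures intersubject community heterogeneity.
  Type-III takes one point per taxon, computed across samples, and measures
  the heterogeneity of the mixed-species population.
* **Diversity-area relationships (DAR)**: Hill diversity of order q as a
  function of the number of pooled subjects A, fitted either as the classic
  power law D = c·A^z or the power law with exponential cutoff (PLEC)
  D = c·A^z·exp(dA), d < 0.  The PLEC fit yields the maximal accrual
  diversity (MAD): D_max = c·(−z/d)^z·e^(−z) attained at A_max = −z/d.

Between-cohort differences in any fitted parameter are assessed with a
pool-and-resplit permutation test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .io import OTUTable, OTUTableError
from .permtest import PermutationResult, child_rng, perm_pvalue

__all__ = [
    "PLEFit",
    "DARFit",
    "MADEstimate",
    "ple_points",
    "fit_power_law",
    "compare_scaling_param",
    "dar_curve",
    "fit_dar",
    "mad",
]


@dataclass
class PLEFit:
    model_type: str  # 'I' or 'III'
    a: float
    b: float
    r_squared: float
    points: np.ndarray  # (n, 2) usable (m, V) pairs
    n_excluded: int = 0


@dataclass
class DARFit:
    model: str  # 'PL' or 'PLEC'
    c: float
    z: float
    d: float  # 0.0 for the plain power law
    r_squared: float
    points: np.ndarray
    q: float = 0.0


@dataclass
class MADEstimate:
    """Maximal accrual diversity of a PLEC fit: the peak of c·A^z·e^(dA)."""

    q: float
    D_max: float  # effective species
    A_max: float  # subjects


def ple_points(table: OTUTable, model_type: str = "I") -> np.ndarray:
    """Variance-mean points for a PLE fit.

    Type-I: one point per sample — mean and variance of species abundances
    within that sample.  Type-III: one point per taxon — mean and variance
    of its abundance across samples.  Variance uses the unbiased (n-1)
    denominator; points with m <= 0 or V <= 0 are excluded.
    """
    if table.mode != "counts":
        raise OTUTableError("PLE points are computed on read counts")
    x = table.counts
    if model_type == "I":
        if table.n_samples < 3:
            raise OTUTableError("Type-I PLE needs at least 3 samples")
        if table.n_taxa < 2:
            raise OTUTableError("Type-I PLE needs at least 2 taxa per sample")
        m = x.mean(axis=0)
        v = x.var(axis=0, ddof=1)
    elif model_type == "III":
        if table.n_taxa < 3 or table.n_samples < 2:
            raise OTUTableError("Type-III PLE needs >= 3 taxa and >= 2 samples")
        m = x.mean(axis=1)
        v = x.var(axis=1, ddof=1)
    else:
        raise OTUTableError(f"unknown PLE model type {model_type!r}")
    pts = np.column_stack([m, v])
    usable = (pts[:, 0] > 0) & (pts[:, 1] > 0)
    if np.count_nonzero(usable) < 3:
        raise OTUTableError("fewer than 3 usable (m, V) points after excluding non-positive values")
    return pts[usable]


def fit_power_law(points, model_type: str = "I") -> PLEFit:
    """OLS fit of log10 V on log10 m; a = 10^intercept, b = slope."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise OTUTableError("points must be an (n, 2) array of (m, V)")
    usable = (pts[:, 0] > 0) & (pts[:, 1] > 0)
    n_excluded = int(pts.shape[0] - np.count_nonzero(usable))
    pts = pts[usable]
    if pts.shape[0] < 3:
        raise OTUTableError("need at least 3 usable points to fit a power law")
    lm = np.log10(pts[:, 0])
    lv = np.log10(pts[:, 1])
    if np.ptp(lm) == 0:
        raise OTUTableError("singular design: all m values identical")
    slope, intercept = np.polyfit(lm, lv, 1)
    fitted = intercept + slope * lm
    ss_res = float(np.sum((lv - fitted) ** 2))
    ss_tot = float(np.sum((lv - lv.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return PLEFit(model_type, float(10.0**intercept), float(slope), r2, pts, n_excluded)


def _default_extractor(table: OTUTable) -> float:
    return fit_power_law(ple_points(table, "I"), "I").b


def compare_scaling_param(
    tableA: OTUTable,
    tableB: OTUTable,
    param_extractor: Callable[[OTUTable], float] | None = None,
    n_perm: int = 1000,
    seed: int | None = None,
    max_failure_rate: float = 0.05,
) -> PermutationResult:
    """Permutation test for a between-cohort difference in a fitted parameter.

    The observed statistic is |param(A) − param(B)|; the null pools all
    samples, re-splits them into the original group sizes and refits.  By
    default the parameter is the Type-I PLE exponent b.
    """
    if param_extractor is None:
        param_extractor = _default_extractor
    if tableA.otu_ids != tableB.otu_ids:
        raise OTUTableError("cohort tables must be row-aligned")
    pA = param_extractor(tableA)
    pB = param_extractor(tableB)
    observed = abs(pA - pB)
    pooled = np.hstack([tableA.counts, tableB.counts])
    ids = tableA.otu_ids
    nA = tableA.n_samples
    n = pooled.shape[1]
    rng = child_rng(seed)
    null: list[float] = []
    failures = 0
    import pandas as pd

    for _ in range(n_perm):
        perm = rng.permutation(n)
        tA = OTUTable(pd.DataFrame(pooled[:, perm[:nA]], index=ids,
                                   columns=[f"s{i}" for i in range(nA)]))
        tB = OTUTable(pd.DataFrame(pooled[:, perm[nA:]], index=ids,
                                   columns=[f"s{i}" for i in range(n - nA)]))
        try:
            null.append(abs(param_extractor(tA) - param_extractor(tB)))
        except OTUTableError:
            failures += 1
    if failures > max_failure_rate * n_perm:
        raise OTUTableError(
            f"{failures}/{n_perm} permutations failed to fit "
            f"(rate {failures / n_perm:.2%} above {max_failure_rate:.0%})"
        )
    p = perm_pvalue(observed, null, tail="upper")
    return PermutationResult(observed, np.asarray(null), p, "upper", len(null), seed,
                             extra={"paramA": pA, "paramB": pB, "fit_failures": failures})


def dar_curve(table: OTUTable, q: float, n_orders: int = 100, seed: int | None = None) -> np.ndarray:
    """Mean diversity-accrual curve: (A, D) for A = 1..n_samples subjects.

    Subjects are accumulated in ``n_orders`` random orderings; at each
    accumulation level the pooled counts (column sums) give one Hill number,
    and the returned curve is the mean over orderings.
    """
    from .diversity import hill_number

    if table.n_samples < 4:
        raise OTUTableError("DAR needs at least 4 samples")
    x = table.counts
    n = table.n_samples
    rng = child_rng(seed)
    acc = np.zeros(n)
    for _ in range(n_orders):
        order = rng.permutation(n)
        cum = np.cumsum(x[:, order], axis=1)
        for a in range(n):
            acc[a] += hill_number(cum[:, a], q)
    acc /= n_orders
    return np.column_stack([np.arange(1, n + 1, dtype=float), acc])


def fit_dar(points, model: str = "PLEC", q: float = 0.0) -> DARFit:
    """Fit D = c·A^z (PL) or D = c·A^z·exp(dA) (PLEC) by log-linear OLS.

    PL regresses ln D on ln A; PLEC regresses ln D on (ln A, A).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 4:
        raise OTUTableError("need at least 4 (A, D) points")
    A, D = pts[:, 0], pts[:, 1]
    if np.any(A < 1) or np.any(D <= 0):
        raise OTUTableError("DAR points need A >= 1 and D > 0")
    lnA, lnD = np.log(A), np.log(D)
    if model == "PL":
        X = np.column_stack([np.ones_like(lnA), lnA])
    elif model == "PLEC":
        X = np.column_stack([np.ones_like(lnA), lnA, A])
    else:
        raise OTUTableError(f"unknown DAR model {model!r}")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise OTUTableError("singular design for DAR fit")
    beta, *_ = np.linalg.lstsq(X, lnD, rcond=None)
    fitted = X @ beta
    ss_res = float(np.sum((lnD - fitted) ** 2))
    ss_tot = float(np.sum((lnD - lnD.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    c = float(np.exp(beta[0]))
    z = float(beta[1])
    d = float(beta[2]) if model == "PLEC" else 0.0
    return DARFit(model, c, z, d, r2, pts, q)


def mad(fit: DARFit) -> MADEstimate:
    """Maximal accrual diversity from a PLEC fit.

    A_max = −z/d and D_max = c·A_max^z·e^(−z); requires z > 0 and d < 0,
    otherwise the accrual curve has no finite maximum.
    """
    if fit.model != "PLEC":
        raise OTUTableError("MAD is defined on a PLEC fit")
    if fit.d >= 0:
        raise OTUTableError("no finite maximum: PLEC cutoff parameter d must be negative")
    if fit.z <= 0:
        raise OTUTableError("no interior maximum: PLEC exponent z must be positive")
    A_max = -fit.z / fit.d
    D_max = fit.c * A_max**fit.z * np.exp(-fit.z)
    return MADEstimate(fit.q, float(D_max), float(A_max))
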