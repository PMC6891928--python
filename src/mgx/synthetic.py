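"""Synthetic two-cohort OTU tables with known ground truth.

Three generators cover the structures the pipeline's stages assume:

* :func:`generate_cohorts` — two cohorts sharing a configurable fraction of
  taxa, with heavy-tailed (lognormal) expected relative abundances and
  multinomial per-sample counts at lognormal depths.  Ground truth for the
  shared-species analyses: cohort-specific taxa have expected abundance
  zero in the other cohort.
* :func:`generate_planted_network_cohort` — latent-factor correlation
  planting for network recovery: core taxa load on one shared Gaussian
  factor, periphery taxa each track one core taxon, optional skeleton edges
  chain designated taxa, background taxa stay independent.  Because the
  latent-to-count map is monotone per taxon, rank (Spearman) correlation
  sees the planted structure.
* :func:`generate_power_law_points` / :func:`generate_heterogeneity_cohort`
  — variance-mean point clouds and count tables obeying V = a*m^b, for the
  Taylor-law-extension fits.

Every generator is bit-reproducible under its seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import OTUTable, OTUTableError, SampleMetadata, TaxonomyMap
from .permtest import child_rng

__all__ = [
    "CohortSpec",
    "PlantedNetworkSpec",
    "generate_cohorts",
    "generate_planted_network_cohort",
    "generate_power_law_points",
    "generate_heterogeneity_cohort",
    "DEFAULT_PHYLA",
]

logger = logging.getLogger(__name__)

DEFAULT_PHYLA = (
    "p__Actinobacteria",
    "p__Bacteroidetes",
    "p__Firmicutes",
    "p__Fusobacteria",
    "p__Proteobacteria",
)


@dataclass
class CohortSpec:
    """Two-cohort community layout.

    Defaults mirror the scale of a two-sex 16S body-site comparison:
    cohorts of 129 and 113 subjects, a few hundred taxa with lognormal
    expected relative abundances (log-sd 2.5, a strongly heavy-tailed
    rank-abundance curve in which the rarest taxa show genuine sampling
    zeros), sequencing depths lognormal around 5000 reads.
    """

    n_samples: tuple[int, int] = (129, 113)
    groups: tuple[str, str] = ("M", "F")
    n_shared_taxa: int = 350
    n_specific_taxa: tuple[int, int] = (75, 75)
    lognormal_mean: float = 0.0
    lognormal_sd: float = 2.5
    depth_mean: float = 5_000.0
    depth_dispersion: float = 0.3  # sd of log depth
    phylum_labels: tuple[str, ...] = DEFAULT_PHYLA
    site: str = "site_1"
    seed: int | None = 0

    def validate(self) -> None:
        if min(self.n_samples) < 1:
            raise OTUTableError("each cohort needs at least one sample")
        if self.n_shared_taxa + sum(self.n_specific_taxa) < 1:
            raise OTUTableError("spec generates zero taxa")
        if self.n_shared_taxa < 0 or min(self.n_specific_taxa) < 0:
            raise OTUTableError("taxon counts must be non-negative")

    @property
    def shared_ids(self) -> list[str]:
        return [f"shared_{i:04d}" for i in range(self.n_shared_taxa)]

    def specific_ids(self, which: int) -> list[str]:
        g = self.groups[which]
        return [f"{g}spec_{i:04d}" for i in range(self.n_specific_taxa[which])]

    @property
    def otu_ids(self) -> list[str]:
        return self.shared_ids + self.specific_ids(0) + self.specific_ids(1)


def generate_cohorts(spec: CohortSpec) -> tuple[OTUTable, SampleMetadata, TaxonomyMap]:
    """Generate the combined counts table, metadata and taxonomy.

    Group-specific taxa have expected abundance zero in the other group;
    shared taxa use the same expected relative abundance in both, so with
    ``n_specific_taxa=(0, 0)`` the two cohorts are draws from one
    distribution (the null setting for every calibration test).
    """
    spec.validate()
    rng = child_rng(spec.seed)
    otu_ids = spec.otu_ids
    n_total = len(otu_ids)
    # expected intensities, heavy-tailed; drawn once so shared taxa agree
    base = rng.lognormal(spec.lognormal_mean, spec.lognormal_sd, size=n_total)
    n_shared = spec.n_shared_taxa
    nA_spec, nB_spec = spec.n_specific_taxa
    maskA = np.zeros(n_total, dtype=bool)
    maskA[: n_shared + nA_spec] = True
    maskB = np.zeros(n_total, dtype=bool)
    maskB[:n_shared] = True
    maskB[n_shared + nA_spec:] = True
    columns: dict[str, np.ndarray] = {}
    meta_rows = []
    for which, (g, n_samp, mask) in enumerate(
        zip(spec.groups, spec.n_samples, (maskA, maskB))
    ):
        probs = np.where(mask, base, 0.0)
        if probs.sum() <= 0:
            raise OTUTableError(f"group {g} has no taxa with positive abundance")
        probs = probs / probs.sum()
        depths = np.maximum(
            1, np.rint(rng.lognormal(np.log(spec.depth_mean), spec.depth_dispersion, n_samp))
        ).astype(np.int64)
        for s in range(n_samp):
            sid = f"{g}_{s:04d}"
            columns[sid] = rng.multinomial(depths[s], probs).astype(float)
            meta_rows.append((sid, f"subj_{g}_{s:04d}", g, spec.site))
    table = OTUTable(pd.DataFrame(columns, index=otu_ids))
    meta = pd.DataFrame(
        [r[1:] for r in meta_rows],
        index=pd.Index([r[0] for r in meta_rows], name="sample_id"),
        columns=["subject_id", "group", "body_site"],
    )
    lineages = {
        otu: f"k__Bacteria;{spec.phylum_labels[i % len(spec.phylum_labels)]}"
        for i, otu in enumerate(otu_ids)
    }
    return table, SampleMetadata(meta), TaxonomyMap(lineages)


@dataclass
class PlantedNetworkSpec:
    """Latent-factor correlation structure for network-recovery tests.

    The first ``core_size`` taxa share one latent factor at loading
    ``core_strength``.  The next ``n_periphery`` taxa are periphery
    satellites, assigned round-robin to core anchors; each loads on a
    *dedicated orthogonal subcomponent* of its anchor's idiosyncratic part,
    so periphery-periphery and periphery-to-non-anchor correlations vanish
    in the latent model — correlation transitivity would otherwise wire the
    periphery into a clique and no ideal core/periphery graph could exist.
    Two satellites per anchor (the default) make the planted core the
    unique minimal cover of the ideal graph: with a single satellite,
    swapping an anchor for its satellite yields an equally good
    core/periphery split.  Taxa named in ``skeleton_edges`` are chained at
    ``skeleton_strength``; everything else is independent background noise.
    """

    n_taxa: int = 40
    core_size: int = 5
    n_periphery: int = 10
    core_strength: float = 0.7
    periphery_strength: float = 0.95
    background_noise: float = 1.0
    skeleton_edges: tuple[tuple[int, int], ...] = ()
    skeleton_strength: float = 0.95
    skeleton_mode: str = "edge_factor"  # or "cascade"
    depth: int = 30_000
    abundance_sd: float = 0.5
    seed: int | None = 0

    def validate(self) -> None:
        if not 0 < self.core_size < self.n_taxa:
            raise OTUTableError("core size must satisfy 0 < k < n_taxa")
        if self.core_size + self.n_periphery > self.n_taxa:
            raise OTUTableError("core + periphery exceed n_taxa")
        for s in (self.core_strength, self.periphery_strength, self.skeleton_strength):
            if not 0.0 <= s <= 1.0:
                raise OTUTableError("association strengths must lie in [0, 1]")

    @property
    def core_taxa(self) -> list[str]:
        return [f"otu_{i:04d}" for i in range(self.core_size)]

    @property
    def periphery_taxa(self) -> list[str]:
        return [f"otu_{i:04d}" for i in range(self.core_size, self.core_size + self.n_periphery)]

    @property
    def otu_ids(self) -> list[str]:
        return [f"otu_{i:04d}" for i in range(self.n_taxa)]


def generate_planted_network_cohort(spec: PlantedNetworkSpec, n_samples: int) -> OTUTable:
    """Counts table whose rank-correlation structure is the planted graph.

    With default strengths and n_samples >= 30, the co-occurrence network
    at FDR 0.001 recovers the planted core as the optimal partition with
    high probability (asserted statistically in the test suite).
    """
    spec.validate()
    if n_samples < 30:
        logger.warning(
            "n_samples=%d < 30: Spearman screening at FDR 0.001 may lack power",
            n_samples,
        )
    rng = child_rng(spec.seed)
    n = spec.n_taxa
    k = spec.core_size
    z = rng.normal(size=(n, n_samples)) * spec.background_noise
    factor = rng.normal(size=n_samples)
    s = spec.core_strength
    # each anchor's idiosyncratic variance is split over as many orthogonal
    # subcomponents as it has satellites, so satellites of one anchor stay
    # mutually uncorrelated
    n_sub = max(1, -(-spec.n_periphery // k))  # satellites per anchor (ceil)
    sub = rng.normal(size=(k, n_sub, n_samples))
    idio = sub.sum(axis=1) / np.sqrt(n_sub)
    z[:k] = s * factor + np.sqrt(1 - s**2) * idio
    t = spec.periphery_strength
    for p in range(spec.n_periphery):
        row = k + p
        anchor = p % k
        z[row] = t * sub[anchor, p // k] + np.sqrt(1 - t**2) * rng.normal(size=n_samples)
    # skeleton planting, two constructions:
    #  - "edge_factor" (moving-average): each planted edge owns a latent
    #    factor and each skeleton node averages its incident edge factors,
    #    so nodes two steps apart share no factor and their latent
    #    correlation is exactly zero — chord-free backbones, the setting in
    #    which the planted chain is recoverable as the top-salience skeleton
    #  - "cascade" (autoregressive): each edge copies v of its source node,
    #    leaking v^k correlations to k-step pairs (chords); gives arbitrarily
    #    strong adjacent correlations, which survive pooled-cohort dilution
    if spec.skeleton_edges:
        u = spec.skeleton_strength
        if spec.skeleton_mode == "edge_factor":
            edge_w = {tuple(e): rng.normal(size=n_samples) for e in spec.skeleton_edges}
            incident: dict[int, list] = {}
            for e in spec.skeleton_edges:
                for node in e:
                    incident.setdefault(node, []).append(edge_w[tuple(e)])
            for node, factors in incident.items():
                shared = np.sum(factors, axis=0) / np.sqrt(len(factors))
                z[node] = np.sqrt(u) * shared + np.sqrt(1 - u) * rng.normal(size=n_samples)
        elif spec.skeleton_mode == "cascade":
            for i, j in spec.skeleton_edges:
                z[j] = u * z[i] + np.sqrt(1 - u**2) * rng.normal(size=n_samples)
        else:
            raise OTUTableError(f"unknown skeleton_mode {spec.skeleton_mode!r}")
    base = rng.lognormal(0.0, spec.abundance_sd, size=n)
    intensity = base[:, None] * np.exp(z)
    probs = intensity / intensity.sum(axis=0)
    counts = np.empty((n, n_samples))
    for j in range(n_samples):
        counts[:, j] = rng.multinomial(spec.depth, probs[:, j])
    cols = [f"s_{j:04d}" for j in range(n_samples)]
    return OTUTable(pd.DataFrame(counts, index=spec.otu_ids, columns=cols))


def generate_power_law_points(
    a: float, b: float, n_points: int = 80, noise_sd: float = 0.1, seed: int | None = 0
) -> np.ndarray:
    """(m, V) points with V = a*m^b under multiplicative lognormal noise.

    ``noise_sd`` is the standard deviation of the noise on the log10 scale;
    m spans two decades geometrically.  With noise_sd=0 a power-law fit
    recovers (a, b) exactly.
    """
    if a <= 0:
        raise OTUTableError("power-law prefactor a must be positive")
    if n_points < 3:
        raise OTUTableError("need at least 3 points")
    rng = child_rng(seed)
    m = np.geomspace(1.0, 100.0, n_points)
    noise = rng.normal(0.0, noise_sd, n_points) if noise_sd > 0 else np.zeros(n_points)
    V = a * m**b * 10.0**noise
    return np.column_stack([m, V])


def generate_heterogeneity_cohort(
    a: float,
    b: float,
    n_samples: int = 80,
    n_taxa: int = 60,
    m_range: tuple[float, float] = (50.0, 500.0),
    seed: int | None = 0,
) -> OTUTable:
    """Counts table whose per-sample variance-mean points follow V = a*m^b.

    Sample s is assigned a mean abundance m_s (log-uniform over
    ``m_range``, so samples are exchangeable draws) and its taxon
    abundances are gamma draws with mean m_s and variance a*m_s^b, rounded
    to counts — the Type-I heterogeneity-scaling setting with a planted
    exponent b.
    """
    if n_samples < 3 or n_taxa < 3:
        raise OTUTableError("need at least 3 samples and 3 taxa")
    rng = child_rng(seed)
    means = np.exp(rng.uniform(np.log(m_range[0]), np.log(m_range[1]), n_samples))
    counts = np.empty((n_taxa, n_samples))
    for s, m in enumerate(means):
        v = a * m**b
        shape = m**2 / v
        scale = v / m
        counts[:, s] = np.rint(rng.gamma(shape, scale, size=n_taxa))
    ids = [f"otu_{i:04d}" for i in range(n_taxa)]
    cols = [f"s_{j:04d}" for j in range(n_samples)]
    return OTUTable(pd.DataFrame(counts, index=ids, columns=cols))
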