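# Methods

This note documents the models and procedures `mgx` implements, the
numerical and design choices made where more than one reasonable option
existed, what the synthetic generators emulate (and do not), and the
problem sizes at which the simulation-based checks run.

## Data model

An `OTUTable` is a taxa × samples matrix of non-negative reals in either
`counts` (reads) or `relative` (columns summing to 1) mode.  Row alignment
between two cohort tables is required by every pairwise analysis; taxa with
zero total in one cohort stay in the table and are ignored by presence-based
stages, which keeps alignment trivial after splitting.  On-disk formats are
the QIIME-classic TSV (first column OTU id, optional `#OTU ID` header) and
BIOM 1.0 JSON (dense or sparse), both round-tripping exactly; the HDF5 BIOM
2.x variant is not supported.  The prefilter drops OTUs with fewer than 80
total reads per cohort (boundary kept: a row summing to exactly 80
survives), and is applied by default only in network construction, where
spurious singleton-level OTUs are most damaging; diversity and composition
stages accept it as an option but default to the full table.

## Diversity

Hill numbers `qD = (Σ p_i^q)^(1/(1−q))` are computed on each sample's
positive abundances after internal normalization, so they are scale
invariant.  `q=1` is evaluated analytically as `exp(−Σ p_i ln p_i)`;
continuity around `q=1` is asserted in tests rather than relied on
numerically.  Stratified profiles renormalize within the stratum's taxa
(a phylum from the taxonomy map, or the core/periphery classes of a
network partition); samples with zero stratum abundance are skipped and
reported.  Rarefaction to a common depth is available as a seeded,
optional pre-step and is off by default, since no particular depth is
canonical.  Two-cohort comparisons use the two-sample Wilcoxon rank-sum
(Mann-Whitney) test, two-sided — the cohorts are unpaired — with scipy's
exact null for small untied samples and the tie-corrected normal
approximation otherwise, plus Cohen's *d* with the pooled (n−1-weighted)
standard deviation.  The significance call is made on the rank-sum p-value
alone at α = 0.05 per comparison, with no multiple-testing correction
across site × order comparisons; *d* is reported alongside.

## Shared species

Presence in a cohort means total reads ≥ 1; no relative-abundance floor is
applied.  Taxa absent from both cohorts are excluded.  The A1 null
reallocates every pooled read to one of the two cohorts uniformly without
replacement, preserving each cohort's total read count — implemented
exactly as one joint multivariate-hypergeometric draw over taxa, which is
the distribution obtained by labelling each read and reshuffling, without
materializing read tokens.  The A2 null reassigns whole sample columns to
groups of the original sizes.  The test is one-sided for
fewer-shared-than-chance by default (the direction of scientific interest;
two-sided available).  The permutation count defaults to 1000, matching
the network analyses.

## Heterogeneity scaling (PLE)

Type-I takes one `(m, V)` point per sample: mean and unbiased (n−1)
variance of the species abundances within that sample.  Type-III — defined
in the source literature only as the mixed-species population's spatial
heterogeneity — is implemented as the per-taxon construction (mean and
variance of each taxon across samples); the interpretation is isolated
behind the `model_type` switch so it can be swapped without touching the
fitting code.  Points with `m ≤ 0` or `V ≤ 0` are excluded and counted;
fewer than three usable points is an error.  Fitting is OLS of `log10 V`
on `log10 m`; `a = 10^intercept`, `b = slope`.  The between-cohort test
pools samples, re-splits into the original group sizes, refits each side
and compares `|b_A − b_B|` with the upper-tail add-one p-value; more than
5% of permutations failing to fit is an error rather than a silent drop.

## Diversity accrual (DAR, PLEC, MAD)

"Area" is the integer number of pooled subjects; no physical area is
involved.  The accrual curve accumulates samples in 100 random orderings
(seeded; configurable) and averages `qD` of the pooled counts at each
accrual level; fits use the mean curve, not per-ordering fits.  PL is OLS
of `ln D` on `ln A`; PLEC is OLS of `ln D` on `(ln A, A)`, a convex
problem chosen over nonlinear least squares on the original scale for
reproducibility.  PLEC on exact power-law data returns `d = 0` (nested
model).  MAD requires `z > 0` and `d < 0`, otherwise the accrual curve has
no finite interior maximum and an error is raised; the closed form
`A_max = −z/d`, `D_max = c·A_max^z·e^(−z)` is verified against numerical
maximization in the tests and the acceptance script.

## Co-occurrence networks

Correlation is Pearson-on-ranks, identical to the tie-corrected Spearman
coefficient; p-values come from the t-distribution approximation at all
sample sizes, and network construction requires at least 10 samples (rank
correlation below that is not meaningful; no exact-enumeration mode is
provided).  FDR control means Benjamini-Hochberg step-up on all tested
pairs with adjusted `p ≤ 0.001` — the default reading of "FDR control" in
this literature; thresholding raw p-values instead is available by flag.
Taxa with zero rank variance never form edges.  Properties (density, mean
degree, clustering, components, diameter of the largest component, degree
skewness, P/N ratio) are computed on the unsigned graph via networkx; a
network with no negative edges reports P/N as the `+inf` sentinel, and
comparisons drop non-finite statistics, erroring above a 5% undefined rate.
The most abundant OTU (MAO) is the network node with the greatest total
reads, ties broken lexicographically.  The trio census classifies every
unordered pair of non-MAO nodes by the full edge-configuration ×
sign-pattern taxonomy of the trio it forms with the MAO — this subsumes
any fixed list of special trio classes — and names the DLM (exactly two
edges, both MAO-incident) explicitly; unconnected trios are counted so the
classes sum to C(n−1, 2).  Null models for all network-level statistics
re-split the pooled samples into the original group sizes and rebuild both
networks per permutation (1000 pairs by default).

## Core/periphery

The objective `ρ = Σ_ij a_ij p_ij` (ordered pairs, zero diagonal) rewards
every edge touching the core and ignores periphery–periphery edges, i.e.
`ρ = 2 × (edges covered by the core)`.  As stated it is degenerate — any
vertex cover attains the maximum — so detection adds the guards: core size
strictly between 0 and n, greedy single-node switching in which
equal-objective flips only shrink the core, restarts from random states
plus a degree-ranked start, and ties across restarts broken by smaller
core then lexicographic membership.  On an ideal core/periphery graph the
planted core is the unique minimal cover and is recovered exactly.  An
exhaustive search over all 2^n − 2 membership vectors is the correctness
oracle for n ≤ 12.  A normalized variant (ρ divided by the ideal pattern's
ordered edge count) is available for cross-size comparability.  The
adjacency is unsigned and binary.  The observed-network strategy permutes
the two detected node sets within the union of the two networks' node sets
(the union, not the full taxon universe); the permutated-network strategy
re-detects cores on pooled-and-resplit network pairs.

## Link salience

Edge length is `1/|ρ_ij|`, so the shortest path is the strongest
correlation chain; the absolute value is taken because a negative
correlation would yield a negative length, and the sign is kept as edge
metadata.  The shortest-path tree `T(x)` contains edge `(u, v)` iff it
lies on at least one shortest path from `x`, evaluated from the all-sources
distance matrix as `d(x,u) + w_uv = d(x,v)` (or symmetrically) within
1e−9 relative tolerance — this σ-based reading needs no tie-break and
agrees exactly with an all-shortest-paths enumeration oracle, including on
tie cases.  Salience averages tree membership over all N nodes of the
network, isolated nodes included (they contribute empty trees), so an
isolated edge has salience 2/N.  Disconnected graphs are handled per
component with the global N in the denominator.  Skeletons at thresholds
0.25 and 0.5 keep all nodes; nesting in the threshold is asserted.

## Permutation machinery

All tests share one convention: `p = (#{null at least as extreme} + 1) /
(n_perm + 1)`, never zero, floor `1/(n_perm+1)`; two-sided doubles the
smaller tail, capped at 1.  One global seed expands into per-test child
seeds through `numpy.random.SeedSequence` spawn keys (all below 2^31), so
any single test is reproducible in isolation, and whole pipeline runs are
byte-identical under a fixed configuration and seed.

## Synthetic data: what it emulates, and what it does not

`generate_cohorts` draws expected relative abundances once from a
lognormal (log-sd 2.5 by default — heavy-tailed enough that the rarest
taxa show genuine sampling zeros at the default ~5000-read depths) and
per-sample counts as multinomials at lognormal depths; cohort-specific
taxa have expected abundance exactly zero in the other cohort.  Defaults
(129 and 113 subjects, 350 shared + 75/75 specific taxa) mirror the scale
of a two-sex body-site comparison.  With no specific taxa, both cohorts
are draws from one distribution — the exchangeable null used by every
calibration check.

`generate_planted_network_cohort` plants correlation structure through a
latent Gaussian layer mapped monotonically into counts, so rank
correlation sees it.  Core taxa load on one shared factor.  Periphery
satellites load on dedicated **orthogonal subcomponents** of their
anchor's idiosyncratic part: a naive "satellite copies its anchor"
cascade is unusable here, because Gaussian correlation transitivity forces
satellite–satellite correlations above any screening threshold that still
detects the satellite–anchor edges, and no ideal core/periphery graph can
be realized.  Two satellites per anchor make the planted core the unique
minimal cover under the detection objective (with one, swapping an anchor
for its satellite is exactly as good).  Planted skeletons support two
constructions: `edge_factor` (each backbone edge owns a latent factor and
each backbone node averages its incident factors — zero correlation beyond
adjacency, so the backbone is chord-free and recoverable as the
top-salience skeleton) and `cascade` (autoregressive copying, which leaks
`v^k` chords but achieves arbitrarily strong adjacent correlations that
survive pooled-cohort dilution in power studies).  Compositional closure
is real in these tables: strongly loaded taxa induce genuine negative
correlations with background taxa at large sample sizes, which is why the
structured taxa are diluted among background taxa rather than filtered.

None of the generators attempt to match real marginal distributions,
zero-inflation patterns, or phylogenetic structure; they target exactly
the statistical structure each analysis assumes.  Passing tests therefore
demonstrate correctness of the machinery and calibration of the nulls
under those structures, not performance on real 16S data.

## Problem sizes for the simulation-based checks

Calibration (both cohorts one distribution; 200 replicates of 200
permutations; rejection at α = 0.05 required to lie in [0.01, 0.10]):

- shared species A2: 300 taxa, 40+40 samples, depth 2000, log-sd 2.5.
- PLE-b: 40 taxa, 80+80 samples, planted `b = 1.8`.
- shared core: 30 taxa with a marginal-strength 10-taxon core
  (strength 0.74), 100+100 samples — a strong small clique would make
  detected cores deterministic and the test degenerate.
- shared skeleton: 25 taxa with a 16-edge cascade backbone (strength
  0.9), 100+100 samples, threshold 0.25 — the longer backbone gives the
  shared-edge count enough resolution that the discrete p-value can fall
  below 0.05 at all.

Power (planted effects; detection = p ≤ 0.05): A2 with 30%
cohort-specific taxa at 100 replicates (≥ 90% required); shared-core and
shared-skeleton with structurally disjoint planted cores/backbones
(cohort B's rows rotated) at 150 samples per cohort, 50 replicates
(≥ 80% required) — the sample size is chosen so pooled-and-resplit
networks retain the roughly halved correlations.

Recovery: planted-core detection on 40-taxa/300-sample cohorts over 50
seeds (≥ 90% exact recovery); chain-skeleton recovery over 15 seeds at
250 samples (≥ 80%).

## Known limitations

- Spearman on relative abundances ignores compositional coupling by
  design (mirroring the upstream methodology); SparCC-style corrections
  are out of scope, and the generator's compositional artifacts are
  handled by dilution, not by the estimator.
- The Type-III PLE construction is one defensible reading of an
  under-specified definition.
- The core/periphery objective's degeneracy is controlled by tie-breaks,
  not removed; on graphs whose minimal covers are not unique the returned
  core is the lexicographically preferred one.
- Salience is computed exactly, not sampled, so very large dense networks
  (thousands of nodes) would need the all-sources Dijkstra to be batched.
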