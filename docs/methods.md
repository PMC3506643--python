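# Methods

This note records the model, the numerical choices, and the design
decisions behind the package, including the points where the published
description of the approach is ambiguous and a concrete choice had to
be made.

## Distance metric

All genetic distances are root-mean-square differences of additive
genotype codes over jointly non-missing SNPs:

    d(g, r) = sqrt( Σ_j (g_j − r_j)² / n ),   n = #{j : g_j, r_j both present}.

"Normalized by the number of SNPs" admits three readings (divide the
distance, divide the squared sum, or average per SNP before the root).
We divide the squared sum by `n` inside the root. Rationale: this is
the only variant whose scale is invariant to the number of SNPs used,
which the SNP-subsampling stability analysis requires — AMids computed
from 1,000-, 10,000- and 20,000-SNP subsets must be comparable to the
full-panel AMids on one axis. Consequence: absolute raw values may
differ from other implementations by a monotone transform; rankings,
normalized barcodes and all downstream analyses are unaffected.

Missing data are handled pairwise-complete per (individual, reference)
pair, with a configurable `min_overlap` (default 1,000 SNPs) below
which the pair is an error rather than a noisy number. Genotypes with
one missing allele (e.g. "0 2") are treated as fully missing. No
imputation anywhere.

## Reference selection and panel structure

A population's reference is the member with the smallest **median**
distance to all other members; for even counts the median is the mean
of the two central values. Ties are broken by smallest mean distance,
then lexicographically smallest sample id, so selection is
deterministic and independent of input order. A single-member
population is its own reference.

The reference-to-reference similarity matrix is an affine rescale of
the raw distances in which the most similar off-diagonal pair scores
exactly 100 and the most distant pair 0; the diagonal is excluded from
the fit and reported as 100 by convention. (Only the "most similar pair
= 100" anchor is fixed by the approach being reimplemented; mapping the
most distant pair to 0 is this package's choice of the second anchor.)

Reference dendrograms use standard agglomerative clustering on the raw
distance matrix. Default linkage is **complete** — the default of R's
`hclust`, which the original workflow used without stating a method —
with average and single linkage available. Export is Newick, with
branch lengths taken as differences of merge heights.

## AMid normalization

Normalization is per individual (row-wise):
`AMid_j = 100 · (d_max − d_j)/(d_max − d_min)`, so every non-degenerate
profile spans exactly [0, 100] with 100 at the closest reference. High
therefore means similar. Whether the original figures normalized per
individual or globally is not stated; per-individual matches the
wording of the procedure ("the highest … 100, the lowest … 0" per
profile) and is adopted. A constant raw vector (possible only in
degenerate fixtures) is an error, not a silent zero. The ratio is
computed before multiplying by 100 so the endpoints are exact in
floating point. If two references tie at the minimum distance both get
100; argmax queries return the first in panel order and log a warning.

Both raw and normalized tables are always written: the raw values
carry absolute divergence (needed, e.g., to see that some populations
are globally close to everything), the barcode carries the ranking.

## PAM clustering

PAM is implemented from scratch in the classic Kaufman–Rousseeuw form:
greedy BUILD initialization (first medoid minimizes total distance;
each addition maximizes cost reduction) followed by best-improvement
SWAP until no single (medoid, non-medoid) exchange lowers the summed
distance of points to their nearest medoid. BUILD is deterministic, so
the default algorithm needs no seed; `init="random"` is available.
A small negative threshold (−1e−12) on the accepted swap gain guards
against infinite loops from floating-point noise. Assignment ties go
to the lowest-indexed medoid; cluster indices are relabelled by
descending size then medoid id so reports are stable across runs.

Clustering operates on **normalized** AMids by default (all coordinates
share the 0–100 scale); raw-space clustering is a flag. Whether the
original analysis clustered raw or normalized AMids is not stated.
Clusters are labelled by the top-3 panel populations ranked by the
median normalized AMid of cluster members — no individuals of known
ancestry are needed for labelling.

The K sweep (default 2–40) deliberately has no "optimal K" selection:
the sequence of splits as K grows is itself the result.

## Nearest-neighbor ancestry assignment

Queries are compared to database individuals by Euclidean distance
between normalized barcodes (raw-space optional), ties broken by
sample id. The report is the population tally over the k = 10 closest
individuals; the deterministic "call" (top count, ties to the
population of the best-ranked neighbor) is an extension — the original
procedure reports the tally only, so the full tally is always emitted
alongside.

Geographic utilities use the haversine great-circle distance on a
6,371 km sphere; land routes that avoid oceans are supported as
explicit waypoint lists, not auto-routed. The genetic-vs-geographic
table reports, per population, the median normalized AMid toward a
target reference and the distance to the target population, plus a
Spearman rank correlation.

## Synthetic data

The simulator is a two-level hierarchical Balding–Nichols model: per
SNP, ancestral frequency p ~ Uniform(0.05, 0.95); continent frequency
~ Beta(p(1−Fc)/Fc, (1−p)(1−Fc)/Fc); population frequency drawn from
the continent frequency with Fp likewise; genotypes Binomial(2, f),
additive-coded as (count of allele 2) + 2. Frequencies are clamped to
[0.01, 0.99] after each Beta draw so fixed SNPs cannot zero out the
distance variance. Admixed individuals draw each SNP's source
population from their mixing proportions; gradient cohorts interpolate
the proportions across individuals. Missingness is uniform at a
configurable rate. Under this model the expected pairwise Hudson-style
F_ST between two sibling populations equals their shared drift
parameter, which the test suite verifies against an independent
frequency-based estimator.

Standard fixtures (fixed seeds):

- **continental** — 3 continents × 2 populations × 30 individuals,
  20,000 SNPs, Fc = 0.10, Fp = 0.05, 0.2% missingness. Fc ≈ 0.10
  matches continental-scale human differentiation; Fp = 0.05 gives
  sibling populations a pairwise F_ST ≈ 0.05–0.1, comfortably
  resolvable at 10⁴ SNPs.
- **isolate** — as above with one population's Fp doubled to 0.20,
  emulating a drifted genetic isolate.
- **admixed** — 2 continents × 2 populations plus a 50/50 two-source
  cohort and a gradient cohort with sources on different continents.
- **tiny** — 2 populations × 3 individuals × 50 SNPs, for exhaustive
  oracles.

A serial-founder variant chains 6 populations along the equator at
1,000 km spacing with F = 0.02 drift per step, emulating the decay of
genetic similarity with distance along a migration path.

What the model does *not* emulate: linkage disequilibrium,
recombination, array ascertainment bias, and realistic heterozygosity
differences between populations. Passing tests therefore demonstrate
the pipeline's behavior under allele-frequency structure, not its
performance on any particular real cohort.

## Problem sizes and empirical test conditions

The test battery runs entirely on simulated data at desk scale:
parameter-recovery checks use the continental fixture (180
individuals, 20,000 SNPs); subsampling-stability checks use a
40,000-SNP dataset so that 20,000-SNP subsamples remain a proper
subset; the SNP-half correlation check runs at full genotyping-chip
scale (289,160 SNPs, 51 reference populations with heterogeneous
continental drift spanning F = 0.02–0.30, as in worldwide human
panels). That heterogeneity matters: the half-to-half Pearson
correlation of a profile is governed by the ratio of its between-
reference contrast to the subsampling noise (which shrinks as
1/sqrt(#SNPs)), so near-flat profiles from weakly diverged groups need
the full chip density to exceed r = 0.99, while high-contrast profiles
exceed it already at a few tens of thousands of SNPs.

## Known limitations

- Merging assumes allele codings pre-harmonized to the same strand;
  strand flipping is upstream (e.g. plink) and out of scope.
- AMids indicate admixture qualitatively (high values toward several
  references); no admixture *proportions* are estimated.
- PAM is a local optimizer; the exhaustive-search tests bound its gap
  at ≤5% on small random instances and observe exact optima on
  separated data, but no global guarantee exists for large n.
- The 0–100 barcode forces commitment to a closest reference even when
  all raw distances are nearly equal; consult the raw table in such
  cases.
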