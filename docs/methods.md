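# Methods

`stregnet` implements a screen for transcription-factor (TF) regulators of
metabolite pathways in spot-based spatial transcriptomics. The premise is
spatial: a TF can only regulate a structural gene whose promoter it can
physically reach, so a TF that (i) is spatially coexpressed with a
structural gene across tissue domains and (ii) has a binding site of its
family in that gene's promoter is a candidate regulator. Neither line of
evidence suffices alone — spatial coexpression also arises from shared
upstream signals (hormonal gradients, light), and promoter motif matches
arise by chance — so edges require both.

## Pipeline model

**Counts and normalization.** Input is a spot x gene matrix of
deduplicated UMI counts. Expression is normalized as
`log(1 + count * s / total)` with scale factor `s = 1e4` (log1p-CPM with a
10k target), the dominant convention for UMI data; the per-spot expm1 row
sum then equals `s` exactly, removing sequencing-depth differences.

**Spot clustering.** Spots are embedded by PCA (default 30 components on
the top 2000 variable genes, gene-scaled; component signs fixed so the
largest-magnitude loading is positive, making the embedding
deterministic). A k-nearest-neighbour graph (k = 15, Euclidean) carries
shared-nearest-neighbour Jaccard edge weights, and Louvain modularity
optimization partitions it. The cluster count is resolution-dependent and
data-dependent; the package deliberately does not promise any particular
count. When an analysis targets a known granularity, `sweep_resolution`
bisects the resolution toward the requested count, mirroring how atlas
studies settle on their published cluster number.

**Markers and replicate consistency.** Markers are one-vs-rest two-sided
Wilcoxon rank-sum per gene with Seurat-style filters (detection fraction
>= 0.1 in-cluster, log2 fold change >= 0.25), BH-adjusted over all tested
(cluster, gene) pairs. Rank-sum p-values are exact by enumeration when
both groups have <= 8 observations and use the tie-corrected normal
approximation otherwise. Replicate consistency between two disjoint spot
regions is the squared Pearson correlation of their pseudo-bulk mean
log1p-CPM profiles over all genes.

**Coexpression modules.** Spots are collapsed to per-cluster mean
normalized expression (genes x clusters). Genes whose best cluster falls
below 0.1 (log scale) are dropped; there is no canonical threshold for
this filter, and 0.1 simply removes genes with no usable profile. Each retained gene's profile is z-scored (sample sd, ddof 1;
constant genes become zero rows rather than being dropped, keeping
indices aligned with the annotation). An optional symmetric clamp of the
z-scores is exposed but off by default: upstream tooling in this field
sometimes truncates standardized heatmap values (a "scale" argument), and
the clamp documents that reading without imitating an unknown default.
K-means (k-means++ init, 10 restarts, fixed seed) groups the z-profiles
into K modules, K = 9 by default. sklearn's k-means++ seeding is
position-keyed, so module *labels* can change under row permutation; on
separable data the recovered *partition* is stable under permutation, and
that is the property we test and promise.

**Motif scanning.** One position weight matrix per TF family. Log-odds
against a background `b` with pseudocount `c`:
`entry(base, i) = log2((p[base, i] + c*b[base]) / ((1 + c) * b[base]))`,
`c = 0.01`, uniform background by default. Every window of motif width is
scored on the forward strand and against the reverse-complemented matrix;
a window's relative score is `(S - S_min) / (S_max - S_min)` with the
analytic extreme window scores as anchors, and hits require relative
score >= 0.85 by default. Coordinates are 0-based, half-open,
forward-strand anchored (a minus-strand hit reports the offset of the
window's leftmost forward base). Windows containing `N` are skipped on
both strands — conservative, since an unknown base could either make or
break a site. Relative-score thresholding was chosen over p-value
thresholding because it is the simplest reproducible convention; scanning
services differ in their internal score models, so absolute hit lists are
not expected to match any particular external tool.

**Network and ranking.** For every (TF, structural-gene) pair with the
structural gene in a pathway target set: an edge requires >= 1 promoter
hit of the TF's family (family-level evidence — any family hit counts for
any member, matching the family resolution at which such networks are
usually drawn) AND spatial consistency, defined as same K-means module OR
Pearson r >= 0.8 between the two z-profiles (`require_module` makes
co-membership mandatory). Undefined correlations (constant profiles)
disqualify the correlation arm instead of counting as zero. Candidate
coregulators across >= 2 pathway sets are ranked lexicographically by
(pathway sets covered, distinct targets covered, mean spatial r), with a
gene-id tie-break; a weighted scalar score was deliberately avoided
because there is no principled way to set the weights.

**Statistics.** Enrichment is the one-sided hypergeometric tail
P(X >= k) ("Fisher test" in the over-representation sense) with BH FDR
within each analysis family (markers, one enrichment run, a correlation
panel). Pearson significance uses the exact t transform on n-2 df. The
knockdown comparison uses Welch's t (unequal variances assumed — group
variances in small transient-knockdown designs are rarely equal).

## Synthetic data model

The generator produces the statistical structure the analysis assumes,
with ground truth for every recovery test.

- **Lattice and domains.** A `grid_width x grid_height` spot lattice
  (default 50 x 30 = 1500 spots) split into `n_domains` axis-aligned
  bands (default 3; a Voronoi layout is available for irregular shapes).
- **Counts.** `counts[s, g] ~ NB(mean = lib_s * base_g *
  activity[module(g), domain(s)], size = r)` with shared dispersion
  r = 2.0 (UMI counts are overdispersed; a single shared size keeps the
  model small), `lib_s` log-normal with sigma 0.25 normalized to unit
  mean so that `base_g * activity` is the expected count itself, and
  `base_g` log-normal across genes (median 5, sigma 0.6) so that genes
  span realistic abundance decades.
- **Module activities.** Default `activity[m, d] = 1 + cos(2*pi*m/M -
  2*pi*d/D)`: all M = 9 module profiles are evenly phased across the
  D = 3 domains, worst-case peak-to-trough contrast is exactly 4x, and
  standardized profiles of modules m and m' correlate as
  cos(2*pi*(m-m')/M), so adjacent modules (r = 0.77) fall below the 0.8
  network threshold. TF genes are drawn exactly like structural genes of
  their mapped module — the TF-target coupling exists only through the
  shared module activity, which is the link the screen must rediscover.
- **Promoters.** Uniform-random 500-bp sequences over ACGT; one PWM per
  TF family (random consensus, 0.91/0.03 columns, width 10, so the
  consensus scores relative 1.0). For each true edge one exact consensus
  of the TF's family is planted at a random non-overlapping offset and
  strand in the target promoter. Width 10 keeps chance exact-consensus
  matches negligible in 500 bp of uniform background, while chance
  sub-consensus hits at the 0.85 scan threshold remain common — those are
  precisely the false leads the dual criterion must reject.
- **Default screen truth.** One TCP-family TF in module 4 with four
  targets in its own module, two tagged `catechin_synthesis` and two
  `theanine_hydrolysis`; two same-family decoys in an anti-correlated
  module (binding evidence without coexpression); two other-family decoys
  sharing module 4 (coexpression without binding evidence); 25 background
  TFs spread over the remaining modules.
- **Knockdown.** Control TF expression ~ N(10, sd); knockdown scales the
  TF mean by `delta` (default 0.3). Each target shifts by
  `sign * beta * (TF deviation)` plus noise, and each metabolite is its
  signed weighted sum of pathway-gene expression plus noise (the
  theanine-like metabolite loads negatively on its hydrolysis genes, so
  it rises when they fall). The formula is used literally; negatively
  loaded metabolites are not offset to positive values.

**What the generator does not emulate:** tissue morphology, per-spot
cell-type mixtures (each spot is one domain; real spots average 1-10
cells), spatially smooth gradients within a domain, gene-specific
dispersions, batch/slide effects, and realistic promoter base
composition. Passing recovery tests therefore show that the pipeline's
inference is correct *when its assumptions hold*, not that real tissue
meets those assumptions.

## Verification design and problem sizes

All randomness is seeded; sweeps use seeds 0..49 and report a
45-of-50 success criterion so that single unlucky draws cannot flip an
outcome. Scoring routines are checked for exact agreement with
independent enumeration oracles: motif scanning against a brute-force
window walker (100 random sequence/PWM pairs, scores to 1e-9),
hypergeometric tails against exhaustive draw counting for universes up
to 12, and rank-sum p-values against the enumerated exact null for
groups up to 8. Statistical calibration is measured under global nulls
(2000 bivariate-normal replicates at n = 20 for correlation; 200 null
enrichment runs over a universe of 2000 genes with 10 terms of 400,
sizes chosen so the discrete hypergeometric null rejection rate, 0.041
analytically, lies well inside the tested band). The replicate analog
uses 1000 spots x 2000 genes; the screen sweeps use the full default
spec (1500 spots x 600 genes) end to end. These sizes keep any single
check to seconds while leaving the Monte-Carlo margins comfortable.

## Numerical choices and degenerate inputs

- PCA sign fixing, size-ordered cluster relabeling, lowest-index
  K-means tie-breaks, and sorted hit tables make every artifact
  byte-reproducible at a fixed seed.
- An uninformative motif (all-uniform columns, zero score span) treats
  every N-free window as a full-score hit rather than dividing by zero.
- All-zero spots normalize to all-zero rows with a warning; an edgeless
  SNN graph degenerates to singleton clusters with a warning; empty
  target sets yield empty networks with a warning.
- Derived stage seeds come from `numpy.random.SeedSequence` and are
  reduced below 2^31.

## Known limitations

- Edges are unsigned and undirected beyond the TF -> target convention;
  activation vs repression cannot be inferred from coexpression plus
  motifs and requires perturbation or binding assays.
- Family-level motif evidence cannot distinguish paralogous TFs of one
  family that share a binding preference; the ranking separates them only
  through their spatial profiles.
- The correlation arm of the dual criterion is computed over cluster
  pseudo-bulk profiles, so its resolution is bounded by the granularity
  of the spot clustering.
- Promoter provenance is an input contract: the package scans whatever
  sequences it is given and performs no genome extraction.
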