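# Methods

This note documents the models, numerical choices and limitations of
`agesom` in one place. Empirical statements below refer to quantities the
test suite and `scripts/acceptance.py` themselves compute.

## Data model and preprocessing

Both layers are handled as gene x sample matrices in log₂ units.
Expression enters as log-scale intensities; methylation enters as CpG x
sample beta values in [0, 1] with a CpG → (gene, TSS offset) annotation.
Promoter methylation per gene is the unweighted mean beta over CpGs whose
TSS offset lies in the closed window [−1500, +500] bp (both bounds
included; genes without in-window CpGs are dropped and reported).
Beta values are rescaled to the log₂ ratio of methylated to unmethylated
signal, m = log₂(β/(1−β)), with β clamped to [ε, 1−ε], ε = 10⁻³, so the
boundary values stay finite; the transform is strictly monotone on the
unclamped range and inverts exactly to within 10⁻⁹. Genes on chromosomes
X and Y are removed (case-insensitive, `chr` prefix optional; genes with
no chromosome label are kept and logged). Centralization — subtracting
each gene's mean over samples — runs last, so Δe/Δm reflect the analyzed
samples only; it is idempotent and leaves row means below 10⁻⁹. Isolated
missing values are imputed with the row mean before centering; rows with
no finite value are rejected.

Expression matrices may be probe-level; an optional collapse keeps the
highest-variance probe per gene for gene-level joins.

## Age-group schemes

Two ordered closed-open partitions of the age axis: the postnatal scheme
(newborn [0, 5) months, baby [5, 13) months, infant [13 months, 10 y),
teenager [10, 20) y, adult [20, 60) y, late adult ≥ 60 y) and the
extended scheme that prepends a prenatal "fetal" group coded with
negative ages. The printed month/year labels overlap at the baby/infant
boundary if taken literally; the partition places the boundary at 13
months. All group averaging, profiles and flow tables follow the scheme
order.

## Batch SOM

Metagenes form a planar (non-toroidal) rectangular grid, 40 x 40 by
default, with Euclidean metric in both data and grid space. The codebook
is initialized as a linear gradient spanning ±2 standard deviations along
the top two principal components of the gene profiles (deterministic SVD
with a sign convention), so training is reproducible without randomness;
the `seed` parameter is stored for provenance and only matters for
degenerate ties. Each epoch assigns every gene to its best-matching node
(minimal Euclidean distance, ties to the lowest node index) and replaces
the codebook by Gaussian-neighborhood-weighted means; the radius decays
exponentially from max(rows, cols)/2 to 0.5 over 50 epochs. Quantization
error (mean gene-to-prototype distance) is recorded per epoch; it is
non-increasing at fixed radius, and over the annealed schedule it
decreases monotonically after the first batch update (the first update
smooths the PCA initialization) with final error well below the initial
one.

After the schedule a final zero-radius step fixes the assignment and sets
each populated node's prototype to the plain mean of its member genes;
empty nodes are filled by inverse-squared-grid-distance interpolation
from populated nodes. This makes the portrait identity exact: a node's
value at a sample *is* the mean Δ of its member genes, which in turn
makes self-extension (below) reproduce the primary portraits exactly.

## Extension SOM

A secondary cohort, centralized over its own samples and matched by gene
id, is projected onto the frozen map: the secondary portrait value at a
node is the mean of the secondary sample's values over the genes assigned
to that node (empty or unmatched nodes interpolated as above). The
primary codebook and assignment are never modified; projections are
independent of the secondary matrix's row order. A warning is issued
below 50 % gene overlap; zero overlap is an error.

## Spot modules

The over-expression summary map is the node-wise maximum of the
age-group mean portraits (the under-expression map uses the sign-flipped
minimum). The mask keeps populated nodes above the q-th percentile of
summary values; q defaults to 75 with a minimum spot size of 4 nodes,
both exposed in the configuration. On the default cohorts the summary
map is strongly bimodal (module nodes ≈ 1.6–2.3, background ≤ 0.45), so
the threshold sits in the gap; the mask is restricted to populated nodes
because a spot is a cluster of genes and interpolated empty nodes carry
none. Masked nodes are then clustered by their group profiles (complete
linkage on correlation distance, cut so that every pair of nodes within
a cluster correlates at r ≥ 0.6) and each profile cluster is split into
its 8-connected grid components. The complete-linkage step implements
"unsupervised clustering of metagenes": without it, modules whose age
courses correlate at r ≈ 0.5 can fuse through boundary nodes whose mixed
profiles correlate strongly with both sides. A gene belongs to a spot
iff its best-matching node lies in the spot (no soft membership). Spots
are labeled A, B, … by the age order of their peak group (ties broken by
row-major grid position).

Spot profiles are means of member-gene Δ values, per sample and per
group; by construction the sample-weighted profile mean vanishes on
centralized data.

## Sample-level statistics

The PCM is the Pearson correlation between flattened portraits,
age-ordered; zero-variance portraits give missing entries. The
similarity net keeps edges at correlation ≥ threshold and always includes
the maximum spanning tree so the graph stays connected. Supporting maps:
gene population per node; per-node variance over samples; two-sided
one-sample t-test of node values against zero (requires ≥ 3 samples;
constant nodes are excluded); per-sample portrait entropy with B = 25
equal-width bins over each portrait's range (a choice, as is B); wTO
between spot profiles w_ij = (Σ_{u≠i,j} a_iu a_uj + a_ij) /
(min(k_i, k_j) + 1 − a_ij) with a = |Pearson| and k the soft
connectivity; and the invariant-gene region, the largest 8-connected set
of nodes below the 20th variance percentile. Per-sample summary
statistics (mean, variance, entropy over genes) are reported with
per-group quartiles; on cohorts dominated by monotone developmental and
aging programs the group-median variance is minimal in mid-life — the
hourglass shape.

## Gene-set analysis

Overrepresentation uses the one-sided Fisher exact test (equivalently
the hypergeometric tail) of the set x spot table over the analyzed gene
universe, with Benjamini–Hochberg adjustment across all set x spot pairs
of one invocation; degenerate tables report p = 1. The GSZ score is the
standardized set mean, GSZ(s) = (⟨Δ⟩_set − ⟨Δ⟩_all)/(sd_all/√n_set), a
deliberate simplification of variance-corrected gene-set statistics:
random sets are approximately standard normal per sample, and the score
responds to a shift δ of the set in one sample by
((gap₀ + δ(1−n/N))·√n)/sd. Note the per-sample standardization makes GSZ
scale-free: in a noise-free cohort whose variance is entirely carried by
planted modules it reduces to a sign profile, which is why validation
cohorts carry background noise. Gene-density maps are node histograms of
a set's best-matching units smoothed with a column-normalized Gaussian
kernel (bandwidth 1.5 nodes), conserving total mass.

Spot melting: the Shannon entropy of a set's node-occupancy
distribution, normalized by log₂ min(n_set, n_nodes), is compared between
two independently trained maps; the ratio H_dst/H_src > 1 indicates
dispersal in the destination map. Conventions: both entropies zero →
ratio 1; only the source zero → ratio capped at 100; sets below 5 shared
genes are rejected as unstable. Coupling classification takes the
Pearson r of group-ordered (M, E) means: r ≤ −0.5 "repressed", r ≥ +0.5
"de_repressed_RC" (repressive-complex-like co-change), otherwise
"decoupled"; constant series are flagged degenerate.

## Chromatin-state strata

Gene → state tables (one per developmental stage) over the twelve
recognized states are intersected per state into fetal-only / overlap /
adult-only strata; genes absent from a stage's table are simply absent
from that side rather than treated as quiescent. Each stratum is profiled
as a gene set (GSZ) on both layers and its joint (M, E) trajectory is
classified, restricted to the groups the two schemes share. An optional
importer derives state tables from genomic segmentations: a gene takes
the state of the segment overlapping its TSS, longest overlap winning.
Collapsing weak polycomb (RepPCWk → RepPC) is available and off by
default.

## Cohort transfer

Secondary samples projected by exSOM are compared with the primary
cohort through a rectangular portrait-correlation matrix (axes in group
order) and a flow assignment: each secondary sample goes to the primary
age group whose mean portrait it correlates with best, ties resolving to
the younger group; the contingency table is reported with both row
normalizations. Correlation makes the assignment invariant to additive
offsets per sample.

## Synthetic cohorts

The generator emulates a lifespan brain cohort at the scale of
typical microarray aging studies (thousands of gene rows, ~40 samples
in 6–7 ordered age groups). Canonical module profiles are parameterized on the normalized
group index t ∈ [0, 1]: monotone = ±(2t−1); U/inverse-U = quadratic with
the extremum at the middle group; peaks = Gaussian bumps (named early
and late peaks at t = 0.15/0.85 with σ = 0.15, or explicit centers).
Profiles are centered to zero mean and scaled to unit maximum before
multiplication by the module amplitude. Expression is baseline +
amplitude·profile + N(0, noise²). Methylation acts on the log₂-odds
scale around a per-gene baseline (population baseline β = 0.3, per-gene
jitter of 0.5 log₂-odds units), so beta values always stay inside (0, 1);
each gene emits 1–5 CpGs at offsets inside the promoter window with
per-CpG measurement noise. Coupling transmits −strength·profile
(antagonistic) or +strength·profile (positive) to the other layer;
decoupled genes each draw an independent random module whose profile
correlates below |r| = 0.3 with their own (per-gene draws, so decoupled
sets genuinely scatter on the other layer). Modes may be planted directly
on either layer. Everything is deterministic given the spec including
its seed.

The default fixtures plant one module per spot-profile class — seven on
the expression layer (monotone decay, four swept activation peaks at
t = 0.2/0.4/0.6/0.8 with σ = 0.10, monotone rise, and a U-shaped
reversal module that is methylation-decoupled) and five on the
methylation layer under the seven-group scheme — each with amplitude 2
log₂ units, 200 genes, 2 000 background genes, noise 0.3 and 6 samples
per group. The narrower σ = 0.10 bumps keep the classes mutually
distinguishable (maximum positive profile correlation ≈ 0.5). Module amplitudes and sizes are fixture choices, not
estimates of any real cohort.

What the generator does **not** emulate: probe-level microarray
artifacts, batch effects, realistic genome coordinates, cell-type
composition shifts, or heavy-tailed noise. Passing recovery tests
therefore demonstrates correctness of the pipeline's logic under the
stated generative model, not performance on real arrays.

## Problem sizes and determinism

Validation runs use the default fixtures (3 000–3 400 genes, 36–42
samples, 40 x 40 grid, 50 epochs; seconds per fit), five seeds for
coupling/melting recovery, and ten for the hourglass rate. The full
pipeline is deterministic under a fixed configuration: re-running
produces byte-identical TSV outputs.

## Known limitations

- The SOM schedule (exponential radius decay, 50 epochs) is a declared
  default, not a reproduction of any specific published schedule.
- GSZ omits the variance decomposition of the full gene-set Z statistic;
  scores are comparable within a run, not calibrated p-values.
- Spot segmentation assumes group-mean portraits summarize module
  activity; single-sample spot detection is not implemented.
- The melting ratio operationalizes a qualitative notion; its absolute
  scale depends on set size and grid occupancy and is only meaningful
  comparatively.
- The similarity net's layout is left to the consumer; only the graph is
  emitted.
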