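# Methods

This note documents the models, conventions and numerical choices behind
the package, what the synthetic data does and does not emulate, and the
known limitations. Nothing here states an empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Coordinates and records

All interval files (BED, narrowPeak, BEDPE, promoter and anchor outputs)
are 0-based half-open `[start, end)`; all pair and SNP positions are
1-based points. A 1-based point `p` maps to the 1-bp interval
`[p-1, p)`. These conversions live only in `hicut.io`. Chromosome
names are normalized to one configurable style (`chr`-prefixed by
default) and ordered naturally (`chr2 < chr10 < chrX`).

Valid pairs follow the HiC-Pro `allValidPairs` column order (read id,
chrom1, pos1, strand1, chrom2, pos2, strand2, trailing columns ignored).
Parsing is strict by default for pair files and tolerant-with-logging
for GWAS catalog exports, which routinely contain unmapped rows and
composite position fields.

## Interaction calling

The pipeline is deliberately minimal, reflecting the low background of
tagmentation-based protein-directed libraries:

| stage | rule | boundary convention |
| --- | --- | --- |
| canonicalize | ends ordered by (chromosome, position), strands travel with ends | idempotent |
| deduplicate | exact key (chrom1, pos1, strand1, chrom2, pos2, strand2); read id excluded | first occurrence kept |
| pre-filter | drop trans; drop cis `d < 1 kb` | `d = 1,000` kept |
| call | keep `20 kb ≤ d ≤ 2 Mb` with ≥ 1 anchor in a peak | both window ends inclusive |

Anchors are 1-bp points; peak overlap is point-in-interval containment
with an optional symmetric slack (default 0). Surviving pairs are never
merged: identical coordinates from different reads are two interactions.
`classify_pairs` assigns every raw pair to exactly one category
(duplicate / trans / short / out-of-window / no-peak-anchor / called),
so category counts always sum to the input size.

QC reports the cis:trans ratio (`inf` when no trans pairs, `nan` on
empty input) and the peak-anchored fraction of long-range cis pairs
*before* the peak filter — after the filter it is 1 by construction,
an ambiguity worth stating because summary tables in the literature do
not always say which side of the filter they report.

## Benchmarking

A reference loop is *captured* when a single query interaction has
anchor1 inside anchorA and anchor2 inside anchorB (each widened by a
slack parameter, default 0): one paired-end tag through both anchors,
never two independent single-anchor hits. Loop-to-loop comparison uses
≥ 1 bp interval overlap on both anchors. Fractions are always reported
over the reference set. Because published overlap figures rarely state
their matching tolerance, slack is a first-class parameter; matched
fractions are monotone non-decreasing in it (property-tested).

Replicate agreement is the Spearman correlation of genome-wide binned
anchor coverage (both ends of every cis pair, bin `floor((pos−1)/size)`,
10 kb default). Bins that are zero in both replicates are retained by
default; a drop-zeros flag exists because this choice materially changes
the coefficient on sparse data, and the convention used must accompany
any reported value.

## Aggregate peak analysis

Cis pairs are binned per chromosome at 5 kb into symmetric sparse count
matrices (total mass = pair count). Loci are all within-chromosome peak
pairs whose midpoint separation `s` satisfies `5 kb ≤ s < 1 Mb`,
deduplicated at bin level; 200,000 are sampled uniformly without
replacement (seeded). The aggregate is the element-wise mean of the
21×21 balanced submatrices centered on each locus; the score is the
center pixel divided by the mean of the 6×6 corner block nearest the
diagonal — the convention of the standard APA tooling, chosen because
that corner has the *highest* distance-decay background, making the
score conservative.

Two locus classes are dropped from aggregation and from `n_pairs_used`:
windows that exceed a chromosome edge, and windows that would touch or
cross the matrix diagonal (`bin_j − bin_i ≤ 2w`); the latter would fold
mirrored short-range signal into the corner block. A
`keep_near_diagonal` flag restores the unfiltered behaviour.

Two consequences of the score convention are worth stating explicitly
because they shape expectations on null data:

* under a distance-decay background the corner sits ~15 bins closer to
  the diagonal than the center, so the *expected* null score is below 1
  (about 0.8 for a `d^-1` decay with uniformly drawn loci), not 1; only
  on i.i.d.-noise matrices does the score concentrate at 1 (both facts
  are covered by tests);
* the score is a ratio of means, so on shallow matrices heavy-tailed
  balanced pixel values depress it further — the 36-cell corner mean
  captures rare large values that the single center cell usually
  misses.

### Knight–Ruiz balancing

`kr_balance` implements the symmetric inner–outer Newton iteration
(tolerance 1e-6 on scaled row sums, 3,000 matrix-vector products), with
a Sinkhorn–Knopp fallback when the Newton scheme stalls. Correctness
anchors: the closed form for 2×2 matrices, the fixed point on doubly
stochastic input, row-sum deviation < 1e-6 on dense random matrices, and
equivariance under symmetric permutation.

Exact balancing is only meaningful when every bin's scaling factor is
well determined. On shallow matrices (tens of counts per bin), bins
with near-singleton coverage otherwise receive explosively large
weights, which in turn crush the weights of well-covered bins they
touch. Two stability filters address this, in the spirit of the
low-coverage bin filtering every production Hi-C balancer performs:
bins below half the median nonzero coverage are excluded up front
(`min_coverage_frac`, set 0 to disable), and on divergence the
lowest-coverage rows are progressively excluded and the iteration
retried. Excluded bins carry NaN weights and are ignored pixel-wise
during aggregation. At depths where even filtered balancing is
unstable, the `--raw` aggregation mode (also provided because it is
unstated whether published APA scores used balanced or raw counts) is
the robust choice; the worked example in the README uses it for exactly
this reason.

## SNP and promoter annotation

An interaction links to a SNP when either anchor is within 5,000 bp of
the SNP position (inclusive: 5,000 links, 5,001 does not), on the same
chromosome; every qualifying (interaction, SNP) pair is emitted and the
unique-interaction count is reported separately, since "interactions
overlapping SNPs" in the literature usually means unique interactions
while join outputs are row-per-pair.

Promoters are strand-aware: TSS = `tx_start` for `+` genes and the last
transcribed base for `−` genes, extended ±2,500 bp (a 5,001 bp interval,
clipped at the chromosome start). Promoter assignment of a linked
interaction is plain containment of either anchor point — no additional
window. Strand-awareness is a deliberate choice (promoters are
biologically strand-anchored) even though pipelines built on plain
TSS-window BED files are sometimes strand-ignorant.

Motif-anchor preparation inverts the promoter filter: all anchor points
further than 2,500 bp from every TSS survive, are extended ±100 bp into
201-bp intervals, deduplicated and sorted. The output is disjoint from
all promoter windows by construction (property-tested).

## Synthetic data

The generator emulates the statistical structure the analysis assumes,
with planted ground truth written alongside every bundle:

* **peaks** — non-overlapping fixed-width intervals placed uniformly on
  a slot grid (200 peaks of 500 bp over two 10 Mb chromosomes by
  default);
* **loops** — peak pairs with midpoint separation in 20 kb–2 Mb (50 by
  default), each supported by 40 pairs jittered uniformly within the
  anchor peaks, so planted loops are recoverable at slack ≤ peak width
  and can never be excluded by the peak-anchor filter;
* **background** — 50,000 cis pairs drawn from the canonical factorized
  contact model `bias(x) · decay(d) · bias(y)`: separations follow a
  truncated power law (`d^-1` by default, the canonical sub-megabase
  contact-decay slope) on [1 kb, chromosome span]; the per-bp end bias
  is elevated inside peaks such that each end independently falls in a
  peak with probability `q`, `1−(1−q)² = 0.7` (matching the observed
  share of protein-directed pair ends at binding sites), and follows a
  shared lognormal 25 kb tile field elsewhere (the "chromatin state"
  that makes replicate coverage correlated). Sampling is by rejection
  on the second end, so the product intensity is exact;
* **trans pairs** — 5% of emitted pairs, uniform across chromosome
  pairs; **duplicates** — 5%, replaying exact coordinates and strands
  under fresh read ids (so deduplication must collapse them);
* **SNPs and genes** — half the SNPs placed within 4 kb of loop
  anchors, 30% of gene TSSs on loop anchors, the rest uniform, so
  SNP-linking and promoter mapping have planted signal.

Replicates share one planted structure (peaks, loops, SNPs, genes,
coverage field) and draw pairs independently from per-replicate child
seeds. Identical configs produce byte-identical bundles.

What the generator does **not** model: sequence and mappability,
restriction-fragment geometry, TADs/compartments, distance-dependent
trans structure, and library-size variation between replicates. Tests
passing on this generator therefore demonstrate correctness of the
pipeline's arithmetic and its behaviour under realistic coverage bias
and decay — not performance on real genomes, where peak density,
assembly gaps and chromatin structure differ.

## Problem sizes

The default study conditions — two 10 Mb chromosomes, ~57,000 pairs,
200 peaks, 50 loops — were chosen so that every pipeline stage runs in
seconds while each per-bin and per-peak quantity stays in the regime of
real shallow protein-directed libraries (tens of counts per 5 kb bin,
hundreds of pair ends per peak). The acceptance script runs the whole
pipeline, including two replicate draws and a loop-free null dataset, in
well under a minute.

## Known limitations

* The interaction caller trusts upstream mapping: no MAPQ, fragment or
  ligation-junction logic (assumed done by the HiC-Pro-equivalent
  producer).
* KR-balanced APA scores are noisy at shallow depth even with coverage
  filtering (see above); raw mode is recommended below roughly a
  hundred counts per bin.
* Loop matching reports overlap fractions only; no permutation-based
  significance is computed.
* GWAS linking does not expand SNPs by linkage disequilibrium; links
  are to the catalog positions as given.
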