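# Methods

## Read model and post-alignment filtering

A record is one aligned single-end tag read with CIGAR, strand, stored
sequence and the NM (mismatches), AS (alignment score) and NH (hit count)
tags. SAM's 1-based inclusive positions are converted to 0-based half-open
intervals at input; every internal interval uses that convention. The read
length is always computed from the query-consuming CIGAR operations
(M, I, S, =, X), never assumed, because trimming makes nominal lengths
unreliable.

Filtering applies four per-read criteria with strict comparisons:
matched bases (M/=/X) > `min_match_frac`·L (default 0.5), NM <
`max_mismatches` (default 4, exclusive), AS > `min_score_frac`·L (default
0.66; splice-aware aligners score on a roughly read-length scale), and
NH = 1 when `unique_only` (default). Multi-mapped tags are excluded because
a tag count is only meaningful for a uniquely placed 3' fragment. A record
missing one of the tags has that criterion skipped with a logged warning —
never silently passed or failed — so files from aligners that omit a tag
degrade loudly. Filtering is idempotent by construction.

## Overlap clustering and polyA evidence

Clusters are the connected components of the interval-overlap graph over
filtered reads, computed per (reference, strand) and per sample by a sweep
over start-sorted intervals. Touching-but-not-overlapping intervals
(end == start) are distinct clusters; the merge gap is zero. Output order
is (reference, strand, start), so the result is independent of input
record order.

A read supplies polyA evidence when the soft clip at its transcript-3'
end — trailing clip for +, leading clip for − (the stored sequence is the
reverse complement) — has length ≥ `min_tail` (default 5 nt) and A (or T)
purity ≥ `min_purity` (default 0.9). These two thresholds are this
package's choice: 5 nt rejects most adventitious 1–4 nt clips, and 0.9
tolerates one miscalled base in tails of 10 nt or more. No positional
constraint ties the clip to the cluster's downstream edge.

Per replicate group (genotype × time point), per-sample clusters are
merged across samples by transitive interval overlap into meta-clusters.
A meta-cluster is **validated** when at least one member cluster
individually contains ≥ `min_polya_reads` (default 2) tailed reads
(`per_replicate` mode). The alternative `pooled` mode sums tailed reads
over members; the two modes differ exactly on evidence split 1+1 across
replicates. Per-replicate is the default because it demands that one
library independently witnesses the transcript end twice.

Each validated meta-cluster is assigned wholly to the strand-matched gene
(GFF3 `gene` feature span) with the largest overlap, ties broken by
lexicographic gene id; clusters overlapping no gene go to a BED6
intergenic report. Counting uses **all** reads of a validated cluster, not
only the tailed ones — the tail validates the site, the pile-up measures
abundance. Reads therefore partition exactly: assigned + intergenic +
rejected-cluster reads = filtered reads, and the run log records each
term.

## Normalization, transform, QC

Size factors are the median-of-ratios estimator computed in log space over
reference genes with positive counts in every sample:
s_j = exp(median_g(log K_gj − mean_j' log K_gj')). The estimator is
invariant to gene order and equivariant (up to its overall geometric-mean
normalization) under per-sample scaling.

The variance-mitigating transform is t_gj = log2(K_gj/s_j + 1), tagged
`log2-norm-pseudocount` in every output. It is a deliberately simple,
fully specified stand-in for a fitted variance-stabilizing transformation:
it preserves the log2-like scale that the downstream unsupervised analyses
need, at the cost of residual mean-variance dependence at very low counts.
A dispersion-trend-fitted VST is out of scope.

PCA treats samples as observations and genes as variables, drops
zero-variance genes (logged and counted), centers and unit-scales, and
reports explained-variance fractions from squared singular values. Sample
QC is all-pairs Pearson correlation of the transformed matrix with leaf
order from average-linkage clustering on 1 − r; a zero-variance sample is
a fatal, named error rather than a silent NaN row.

Low-expression filtering keeps genes with ≥ `min_count` (5) counts in at
least `min_samples` (3) samples — the standard keep-rule phrasing of the
noise filter.

## Differential expression engine

The engine (`nb-wald-mom`, named in output files) is a fully specified
negative-binomial Wald test:

* normalized counts n_gj = K_gj / s_j;
* log2FC = log2((mean_b + c)/(mean_a + c)) with pseudocount c = 0.5 so
  degenerate all-zero groups stay bounded; orientation is second condition
  over first (D1 over R1 for "R1-D1");
* per-gene dispersion α̂ = max(0, (v̂ − m̂)/m̂²) by method of moments, with
  v̂ the df-weighted pooled within-group variance and m̂ the grand mean of
  normalized counts;
* **moderation**: α̂ is floored at the across-gene median α̂. With three
  replicates per group the raw moment estimate is zero-truncated for
  roughly half the genes, which understates the variance and makes a naive
  Wald test anti-conservative (empirically ~12% null rejection at
  p < 0.05); the median floor restores calibration (~5%) while leaving
  well-estimated dispersions untouched. This is a deliberately simple
  analogue of the empirical-Bayes dispersion shrinkage mainstream DE
  engines perform;
* standard error by the delta method under Var = μ + αμ², Wald statistic
  log2FC/SE against the standard normal, two-sided.

There is no fold-change shrinkage. Benjamini–Hochberg adjustment uses the
step-up procedure (via statsmodels); significance is strict:
up ⇔ log2FC > 0.5 ∧ FDR < 0.05, down ⇔ log2FC < −0.5 ∧ FDR < 0.05. All
thresholds are configurable because published analyses of this design have
used both 0.5 and nearby values.

Shared DEG analysis decomposes per-genotype significant-gene sets into
disjoint membership regions (the UpSet table); the all-genotype
intersection is the shared set, direction-agnostic by default. A shared
gene is re-regulated across transitions T1, T2 when significant in exactly
one (`sig_in_one`) or significant in both with opposite direction
(`reversed`).

## Synthetic data generator

`simdata` emulates the structure of the real experiments: ~75 bp
single-end tag reads, three biological replicates per genotype × time
point, transitions R1 → D1 → R2, and negative-binomial counts with
dispersion 0.1.

* `simulate_annotation` packs non-overlapping 2 kb genes with ≥ 500 nt
  spacing on one reference, strands Bernoulli(0.5), leftover space spread
  as random gaps. Infeasible packing is fatal.
* `simulate_tag_reads` places each read's 3' end within
  `three_prime_window` (default 40 nt) of the gene's 3' terminus, inside
  the gene body. The default window is intentionally smaller than the
  shortest aligned read portion (75 − 20 nt maximum tail), which makes all
  of a gene's reads mutually overlapping — one cluster per gene per
  sample — so ground-truth counts are recoverable exactly. `polya_fraction`
  of reads carry a soft-clipped tail (uniform 8–20 nt, pure A/T, oriented
  by strand); all intended reads carry NM/AS/NH values passing the default
  filters, and optional decoys each violate exactly one criterion, labeled
  in the ground truth. Reads are emitted as SAM directly — the pipeline's
  scope starts downstream of the aligner — and identical seeds give
  byte-identical files.
* `simulate_count_experiment` draws per-gene baselines log-normally around
  `base_mean`, plants ±`de_log2fc` shifts in the first transition for
  `n_de` genes, reverts the first `n_reregulated` of them in the second
  transition (re-regulated by construction; the default of 26 mirrors the
  scale of the motivating field study), applies log-normal per-sample
  depth factors, and samples NB counts.

What the generator does **not** emulate: sequencing-error profiles and
quality strings, internal priming at genomic A-rich tracts, overlapping or
nested gene models, 3'UTR annotation errors, and multi-mapping ambiguity.
Passing tests on this generator therefore demonstrate algorithmic
correctness (clustering, validation, assignment, statistics), not
robustness to those artifacts on real libraries.

## Problem sizes and numerical choices

The test-suite and acceptance-script simulations use 20-gene read-level
fixtures, clustering oracles up to 1,000 intervals, and count experiments
of 2,000 genes — sizes at which every oracle comparison is exhaustive and
the whole suite runs in seconds while leaving all statistical checks
well-powered. Statistical checks (null rejection in 3–8% at p < 0.05,
median planted-log2FC recovery within ±0.25, re-regulation sensitivity
≥ 0.8) run at fixed seeds. Degenerate inputs are fatal and named: no
all-positive gene for size factors, a zero-variance sample in correlation,
all-zero contrast groups, a sample missing from its replicate group.

## Known limitations

* The DE engine is a stand-in: no dispersion trend fitting, no LFC
  shrinkage, normal (not likelihood-ratio) inference. It is calibrated and
  qualitatively comparable at the study's replicate numbers, not
  numerically interchangeable with shrinkage-based engines.
* The transform is not a true VST; at counts below ~5 its variance is not
  stabilized.
* Gene assignment uses the full gene span; tags from unannotated 3'UTR
  extensions land in the intergenic report instead of being rescued.
* Validation assumes the replicate grouping is correct; there is no
  outlier-replicate detection beyond the correlation QC.
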