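# Methods

This note documents the models, the synthetic study conditions, the
numerical choices, and the limits of what the passing tests demonstrate.

## Synthetic data model

The generator (`mbcircuits.synthetic_data`) emulates the data-generating
process of a multi-sample tumor scATAC-seq experiment, not its sequence
content (no FASTA, no reads, no doublets).

**Genome.** `generate_genome` builds chromosomes of equal length on a
500-bp tile grid. The GC track is a Gaussian random walk smoothed with a
boxcar of 200 tiles, standardized to mean 0.5 / sd 0.08 and clipped to
[0.25, 0.75] — smooth enough that 10-Mb windows differ meaningfully in GC,
rough enough that GC-matched neighborhoods are nontrivial. Three 20-kb
blacklist intervals per chromosome stand in for unmappable regions.

**Fragments.** Each cell draws a negative-binomial fragment count
(mean = depth, dispersion 8). A fragment's first insertion is sampled from
the group's tile rate law

    rate(t) = base(t) · exp(gc_bias · (gc_t − 0.5)) · (cn_t / 2) · program(t)

where `base` elevates peak tiles (+50), `cn` is the clone's local copy
number (absent for reference groups), and `program` multiplies a TF
program's peak and gene-body tiles by its effect size (2). A fraction
(10%) of insertions is redirected to ±50 bp of a TSS (gene chosen
proportional to its promoter rate), which gives cells realistic TSS
enrichment; the second insertion sits one gamma-distributed fragment
length downstream (both endpoints are Tn5 insertion sites, 10x
convention). The GC bias form exp(k·(gc−0.5)) is monotone, invertible and
zero-centered; the source analyses state only that GC composition causes
false-positive copy-number signal, not a functional form.

**Regulatory scenario** (defaults; all exposed as arguments): 2 chromosomes
× 30 Mb; 160 genes; 600 cells — 200 immune-like diploid reference + 4 tumor
groups × 100 — at depth 8,000. Four planted TF programs (one per subgroup):
motif sites in the promoter peaks of 5 targets (2 NTR + 3 other genes), in
4 distal peaks per target (20–150 kb from the TSS, for co-accessibility
linking), and in 30 background peaks; 40 decoy TFs with motif sites in 30
background peaks only. Each group (including the reference) additionally
elevates 40 exclusive background peaks — the broad subgroup-specific
accessibility real tumors show — which is what LSI clustering separates.
The background-peak pool is partitioned so profile peaks never host motif
sites; otherwise decoy motifs would inherit group structure and stop being
exchangeable nulls.

**CNV scenario**: 6 chromosomes × 60 Mb (≈168 sliding windows, enough for
the k = 100 GC-matched background), 200 reference + 4 clones × 100 cells,
each clone carrying one copy-4 and one copy-1 segment of 12 Mb (≥ 2 full
windows) on clone-specific chromosomes, GC bias strength 1.

**Cohort**: 763 samples × 94 NTR genes, 4 groups. Block design at the
defaults: two groups with 20 private marker genes each, the last two
(the Group 3/Group 4 analogue) with 12 private genes each plus a 12-gene
shared block, 18 null genes; shift = effect size 5 over N(0, 1) noise. The
shared block makes the last two groups mutually closest (so forcing k = 3
merges exactly them) without eroding the k = 4 optimum.

What these simulations do **not** contain: sequence-level artifacts, PCR
duplicates, doublets, batch effects, subclonal breakpoints below window
resolution, or TF motif families with correlated position weight matrices.
Passing recovery tests therefore certify the pipeline's statistical
machinery under its own assumptions, not performance on real tissue.

## Stage-by-stage choices

**QC.** Thresholds (≥ 1000 fragments, TSS enrichment ≥ 4) are inclusive;
the equivalent minimum-value phrasing in the source tooling's parameters is
read as minima. TSS enrichment is computed on the aggregated meta-profile:
(center pairs / 101 bp) / (flank pairs / 200 bp + 0.1). The pseudocount is
applied to the summed-profile per-bp flank rate — applying it to a
per-TSS-normalized rate would make the score collapse at single-cell
sparsity. `#` is only a comment character at line start, since it also
appears inside sample#barcode identifiers.

**Gene scores.** Kernel exp(−d/5 kb) with no floor; tile membership by tile
center (avoids double-counting window-straddling tiles); gene windows are
clipped at chromosome ends only, not truncated by neighboring genes. The
size multiplier 1/length is rescaled onto [1, 5] so scores are
scale-independent. Raw scores are linear in counts (and therefore scale
with depth); `frame(depth_normalize=True)` rescales each cell to 10,000
total insertions and is what cross-cluster correlations use, since motif
deviations are already depth-corrected and correlating a depth-carrying
quantity against a depth-free one manufactures spurious structure.

**LSI.** Single-pass TF-IDF (log1p-scaled) + truncated SVD on the 25,000
most accessible tiles, L2-normalized embedding, seeded k-means. Clustering
here is plumbing for cluster-level statistics, not a claim under test; the
iterative variable-feature reselection of the source tooling is not
reproduced. The regulatory analysis uses k = 24 clusters (the source
study's cluster count) over 5 planted groups: over-clustering multiplies
the points available to cluster-level correlations.

**CNV.** Trailing windows are truncated at the chromosome end and kept only
if ≥ width/2 (counts are not length-normalized, so sub-half windows would
not compare like with like). The low-GC filter defaults to dropping the
bottom 5% of windows by GC — a deterministic stand-in for the stated intent
of removing the false-positive-prone low-GC tail. The GC-matched background
excludes the window itself (including it biases ratios toward 0) and is
summarized by the **median** of the k = 100 matched windows: with k a large
share of all windows, an aneuploid cell's background inevitably contains
its own copy-altered windows, and their contribution to a plain mean pulls
the expected log2 ratio of a true event toward zero — fatal when a clean
one-extra-copy-pair event sits exactly at the ±1 call threshold
(log2(4/2) = 1). The median is insensitive to that contamination;
`background="mean"` restores plain averaging. Pseudocount 1 guards zeros.
Per-cell calls use the literal strict rule (corrected > 1 gain,
< −1 loss) with runs shorter than 2 windows smoothed to neutral;
single-window calls on an overlapping 10 Mb/2 Mb grid are almost always
noise (`min_consecutive=1` restores the unsmoothed rule). Because a clean
copy-4 event has *expected* corrected value exactly 1, individual cells
exceed the threshold only a minority of the time while neutral windows
essentially never do; the clone-level consensus therefore calls a window
when ≥ 10% of the clone's cells support it — an order of magnitude above
the neutral false-call rate and below the per-cell support of a true event
(predicted ~0.3–0.6 from Poisson counting noise at depth 8,000). Recovery
is scored on unambiguous windows only: fully inside a segment (true event)
or disjoint from all segments (true neutral); partially overlapping windows
have intermediate expected ratios and no defensible binary label.

**Motif deviations.** Counts are used as-is (not binarized), which makes
the per-motif conservation Σ_c (obs − expected) = 0 exact. Background sets
(50) replace each motif peak with one of its 100 nearest peaks in
standardized (GC, log1p mean accessibility) space. Motifs whose peaks carry
zero counts are dropped with a warning. Motif-in-peak annotation is
half-open interval overlap (≥ 1 bp); abutment is not overlap. Marker-peak
enrichment is the upper-tail hypergeometric with BH correction; when motif
prevalence is identical inside and outside the marker set the odds ratio is
reported as 1.

**Circuits.** Correlations run over cluster means by default (the
`per_cell=True` flag switches): the numeric cutoffs (r > 0.5 strict,
padj < 0.01) come from the cluster-level screen in the source analyses.
Clusters with fewer than 5 cells are excluded from the means — a "mean"
over a couple of cells is single-cell noise and acts as a high-leverage
point that both dilutes true correlations and manufactures spurious ones.
BH is applied over TFs in the regulator test and globally over all
gene × motif pairs in the screen (a per-motif alternative is a one-line
change). The motif delta cutoff is the 0.75 quantile of all tested TFs'
deltas. Co-accessibility is KNN-aggregate Pearson correlation: cells are
pooled into ~n/20 pseudo-bulk groups by k-means on the LSI embedding,
profiles depth-normalized and log1p-transformed, links kept at r ≥ 0.5
within 250 kb on the same chromosome. CCANs are connected components of the
link graph; a gene joins via a peak overlapping TSS ± 2 kb, while the
±5 kb window is reserved for the promoter-motif rule of network edges,
where the source states it explicitly. Every edge stores its evidence
labels so the edge set can be re-derived from stored inputs.

**Cohort classifier.** Euclidean z-score space throughout; k chosen by
maximum mean silhouette with ties toward smaller k; K-means with 50 seeded
restarts. ANOVA markers: one-way F per gene, BH over genes, the q < 0.05
gene with the highest within-cluster mean nominated per cluster.
Prediction is nearest trained centroid over shared genes (≥ 50% required),
z-scored with stored training parameters.

**Pipeline.** Stage sub-seeds are blake2 hashes of (global seed, stage
name) reduced below 2^31, so stages are independently reproducible; the
manifest records seeds, shapes and output SHA-256 checksums, and reruns
with the same config are byte-identical.

## Problem sizes

The default studies — 600 cells at depth 8,000 over a 60–360 Mb genome,
1,037 peaks, 44 motifs, 763 × 94 cohort — were chosen so a full analysis
run and the whole test suite each complete in a few minutes on one core
while keeping every statistical regime honest (counting noise at ~500
insertions per CNV window, ~25 cells per cluster, 7,040-pair screens with
meaningful multiple-testing burden).

## Known limitations

* Co-accessibility is aggregate correlation, not a regularized graphical
  model; at small pseudo-bulk counts it can chain adjacent links into one
  component.
* The CNV caller reports window-level events; it does not refine
  breakpoints, infer subclone trees, or estimate integer copy number
  beyond the gain/neutral/loss call.
* Positive-regulator detection assumes a TF's own gene activity is a
  usable expression proxy; TF families sharing motifs are not
  disambiguated beyond that correlation.
* Silhouette-guided k is a heuristic; on cohorts without planted structure
  it will still return some k, and the silhouette profile (written by the
  classifier driver) should be inspected, not just the argmax.
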