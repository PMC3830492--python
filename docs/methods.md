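# Methods

## Experimental design being modelled

The pipeline targets two-colour competitive hybridizations comparing a
sulphur-deficient (–S) sample against a sulphur-sufficient (nS) sample of
the same plant line, for two lines (a wild type, WT, and a transgenic line,
AB3). Each (line, contrast) cell is hybridized on four arrays with the dye
orientation swapped between duplicates (`fwd, fwd, rev, rev`): on forward
arrays the –S sample is in channel A, on swapped arrays in channel B. Dye
orientation is carried as a per-array attribute in the design table rather
than inferred from the data, because the array files themselves contain no
record of which sample was labelled with which dye.

## Synthetic data model

Per gene g a baseline abundance is drawn log-normally,
log2 B_g ~ N(mean 10, sd 1.5) (arbitrary fluorescence units on a 4×44K-style
scanner scale). The condition effect acts multiplicatively on the –S
sample: log2 expression is B_g + β_g with β_g ∈ {+e, −e, 0} for up-,
down-regulated and unchanged genes (default effect e = 1 log2 unit).
Per-channel replicate noise is log-normal with sd 0.1 log2 units per
channel, so a single-array log ratio has noise sd ≈ 0.14. Dye bias is a
polynomial in A added to M in dye coordinates — split symmetrically over
the two log channels so A is untouched — with default coefficients
(0.3, 0.05), i.e. bias = 0.3 + 0.05·A, the smooth curvature Lowess
normalization is designed to remove.

Defaults describe a desk-scale reference design: 1,000 genes, 5% truly up-
and 5% truly down-regulated per line. Half of each line's regulated genes
are shared between lines (`shared_fraction = 0.5`), emulating the partially
overlapping response of a wild type and an antisense line; full-scale 44k
runs are a configuration choice, not a different code path. One probe per
gene by default; with multiple probes, probe-level normalized M values are
averaged per gene within each array before replicate summarization.

GO annotations: each of 50 terms annotates genes independently with
probability `genes_per_term_mean / n_genes` (default 30/1000); a planted
term multiplies the membership *odds* of genes in its target set (default:
odds 10 on the truly up-regulated WT genes). Gene annotations (description
/ Arabidopsis homologue) cover a configurable fraction of genes (default
0.8); clustering is restricted to annotated genes, mirroring the practice
of clustering only interpretable genes.

What the generator does **not** emulate: scanner-level artifacts
(saturation, spatial gradients, print-tip effects), probe-level sequence
bias, correlated noise between genes, and realistic GO term-size
distributions or DAG structure. Passing tests therefore demonstrate the
correctness and calibration of the pipeline's statistics under a clean
two-colour noise model, not robustness to every artifact of real scans.

## Normalization

MA transform per array; features with a non-positive channel are excluded
with a warning. Lowess uses a global (not print-tip) fit with span 0.3 — a
common two-colour default; the span is exposed as a parameter. The fitted
curve is subtracted from M; A and the feature set are never modified.
Replicate p-values are a two-sided one-sample t-test of the oriented,
normalized per-gene M values against zero. This is the standard
replicate-array test; the upstream tool that inspired the workflow does
not document its test, so the choice is ours and is isolated in one
function. Genes with zero replicate variance and nonzero mean receive the
smallest positive float instead of p = 0 to keep downstream logarithms
finite; genes on fewer than two arrays are dropped with a warning.

## Reliability selection

The quintic ceiling uses the published coefficients
(−0.001, 0.0178, −0.1032, 0.2008, −0.2022, 1.0771) with x = 20·t + 1.
Two genuinely open choices are made explicit:

* **x-transform**: t = |log2 ratio| by default. With the signed ratio the
  quintic explodes to huge positive ceilings for down-regulated genes
  (everything passes) and large negative ones for up-regulated genes —
  asymmetric and contrary to the filter's purpose of keeping reliable
  measurements for regulated and unregulated genes alike. Signed mode is
  retained as `x_transform: signed` for literal fidelity.
* **Clamping**: the raw polynomial leaves [0, 1] for |t| ≳ 0.4; since it is
  used as a p-value ceiling it is clamped to [0, 1], making the rule total.

Regulation cutoffs are strict (> 0.5, < −0.5). The Venn partition reports
common and line-only sets per direction plus the regulated union (the GO
input list); genes called up in one line and down in the other are counted
in both directions' line-only sets and reported separately as
`opposite_direction`, so set sizes remain conserved.

## Cross-line ratios and median QC

Cross-line ratios compare raw single-channel fluorescence of the same
condition between lines: per gene, log2 of the mean (over arrays) intensity
in line 2 over line 1. By default each array channel is first divided by
its median (`scale: median`): this operationalizes the argument that stable
channel medians are what make between-array comparisons legitimate, at the
price of absorbing genuine global shifts — with `scale: none` the raw
values are compared and a uniform 2× difference between lines shows up as a
ratio of 1.0. The accompanying QC reports the max/min ratio of per-array
channel-median sums and fails above 1.5 by default.

## Enrichment

Pearson chi-squared on the 2×2 table (in input list vs not) × (annotated
to term vs not), df = 1, without Yates continuity correction (matching the
AgriGO-style chi-square option; the correction is a config toggle). Terms
mapping fewer than five background genes are excluded before testing.
Adjustment is Benjamini–Yekutieli — valid under the arbitrary dependence
created by overlapping GO terms — with significance at adjusted p < 0.01.
The background is the full array gene universe, not the reliable subset.
Annotations are used as given; no GO-DAG ancestor propagation is performed
(the DAG is external data), and both over- and under-represented terms are
reported with a direction flag. Degenerate tables (a zero margin) are
assigned χ² = 0, p = 1 rather than an error.

## Clustering

Distance is 1 − Pearson correlation, centered by default; uncentered
correlation (the historical Cluster 3.0 default) is selectable, since the
original workflow names only the linkage, not the metric. Missing values
are handled pairwise-complete; profiles with more than 50% missing are
dropped with a warning, and a pair sharing fewer than two values is an
error naming the pair. UPGMA agglomeration uses the unweighted average of
member-pair distances (Lance–Williams with size weights); among equally
close pairs the lexicographically smallest (i, j) merges first, making
results bit-exact and row-permutation invariant. Leaf ordering places the
subtree with the smaller mean profile value first at every node. Output is
Cluster 3.0 CDT/GTR with GTR node heights as similarity = 1 − distance
(TreeView's convention). Rows only are clustered; column order is fixed.

## Pipeline and determinism

One master seed drives the simulation; all later stages are deterministic,
so identical config + seed gives byte-identical outputs (floats are written
with 6 significant digits). Each stage reads and writes the same
tab-delimited files whether invoked through `run_full` or the stage
subcommands, which is what makes chained subcommands reproduce the
monolithic run byte-for-byte. The manifest is flat `key=value` text with a
config hash and all stage counts.

## Validation problem sizes

The test suite and acceptance script exercise the reference design at
1,000 genes with 20 seeded replicates for the end-to-end recovery and
Lowess-calibration checks, and up to 8-leaf random matrices (200 instances)
for the brute-force UPGMA oracle. These sizes give stable statistics for
the properties being checked while keeping the suite quick to run;
full-scale runs only change `n_genes`.

## Known limitations

* The t-test with n = 4 replicates has limited power for effects below
  ~0.5 log2 units at the default noise level; the reliability filter is
  deliberately permissive near zero fold change.
* Median scaling in cross-line ratios removes genuine global expression
  differences between lines; the QC ratio should be consulted before
  interpreting them.
* BY adjustment is conservative; planted terms at modest odds or on small
  gene sets can be missed in a minority of seeds.
* The selection curve is treated as fixed; estimating its coefficients
  from data is out of scope.
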