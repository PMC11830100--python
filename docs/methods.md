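# Methods

`spikecut` re-implements, as a tested library, the computational workflow
used to analyse spike-in calibrated CUT&RUN experiments together with the
RNA-seq set constructions that are joined to the binding data.  Because the
original deposited sequencing data are not required, every stage is
exercised against a synthetic-data generator that plants known truth; this
note records the models, the parameters that matter, and the design
decisions taken where the workflow left choices open.

## Coordinate and counting conventions

All intervals are 0-based half-open (`[start, end)`), the BED convention;
GFF-like 1-based closed gene tables are converted on read.  Overlap means
"at least one shared base pair" everywhere (blacklist removal, peak
merging, feature assignment, state calls), matching the intersectBed /
mergePeaks idiom.  Strand is ignored: tag counting and peak calling are
unstranded.  Paired-end fragments read from BEDPE are taken as the outer
span of the mate pair; because a BED6 line and a BEDPE line are
structurally ambiguous, the `.bedpe` filename extension selects the
parser.  A fragment contributes one tag, binned at its midpoint (bin width
50 bp by default), so disjoint-window counts are sums over independent
fragment events and Poisson tests apply cleanly.

## Spike-in normalization

Each library's fragments split into genome-aligned and spike-in-aligned
counts.  The primary scheme rescales the IgG control to each experimental
sample:

    ratio_expr  = expr_spike / expr_genome
    ratio_ctrl  = ctrl_spike / ctrl_genome
    size_factor = ratio_ctrl / ratio_expr
    norm_ctrl_genome = size_factor * ctrl_genome

The alternative "aimed-reads" scheme (an opt-in, per-antibody flag,
useful when the ratio scheme leaves an antibody with too few peaks)
first rescales every sample by its sequencing-target attainment relative
to the cohort and then by its genome/spike ratios against the control
(formulas in `normalization.py`).  When the control itself appears in the
cohort it takes the sample role with its own counts, so its genome and
spike ratios are exactly 1.  Coverage comparisons scale the control
1:S with S = ratio_expr / ratio_ctrl = 1 / size_factor.

Zero counts in any denominator raise an error rather than being
pseudocounted: the formulas are undefined there, and silently fudging a
spike count would corrupt every downstream factor.  All factors are
computed in double precision from integer counts; nothing is rounded
until reporting.

## Peak calling

Candidate windows of width *w* = 500 bp slide at step *w*/2 across each
genome contig.  A window with experimental tag count *k* and normalized
control expectation λ is retained iff

    k / λ ≥ F      (default F = 4)
    P[X ≥ k | X ~ Poisson(λ)] ≤ α      (default α = 1e-4)

with λ = max(λ_min, size_factor × control tags in the window) and
λ_min = 0.5 (the Poisson test is undefined at λ = 0).  The upper tail is
evaluated through the regularized-gamma survival function, stable in log
space for large *k*.

The control tag count entering λ is floored at the genome-wide average
control density times the span length.  Without this floor, windows where
the IgG control is randomly undersampled (Poisson(10) ≤ 2 happens in
roughly 0.3% of windows) would pass the 4-fold test on ordinary
background, producing dozens of false peaks per null dataset; with it, a
null dataset (enrichment 1 everywhere) yields zero peaks at the default
thresholds.  This mirrors the expected-background behaviour of
histone-mode region callers; a *local* background model (sliding local
λ estimates) is deliberately out of scope.

Retained windows separated by gaps ≤ 1,000 bp are stitched and the
stitched span is re-tested as a whole; a stitched peak failing the joint
test is dropped (conservative: stitching cannot rescue sub-threshold
windows).  Note that the *stitched peak count* is not monotone in the
thresholds — loosening F retains more windows, which can merge
neighbouring sites into fewer, larger peaks — whereas window-level
retention (`scan_windows`) is strictly monotone; the property tests
assert monotonicity there.  Duplicate fragments are retained (no clonal
filtering), appropriate for CUT&RUN where identical fragment ends arise
from different cells.  Windows are processed left-to-right per contig and
contigs in layout order, so calling is fully deterministic.

Peaks overlapping ENCODE-style blacklist intervals by ≥ 1 bp are removed.
Cross-sample comparison merges peaks from two or more sets by literal
coordinate overlap with transitive closure, labelling each merged cluster
by the subset of contributing sets.

## Annotation and chromatin states

Enhancers overlapping promoters are removed before any assignment.  Each
peak then gets exactly one class by the precedence
promoter > enhancer > gene body > intergenic; a peak overlapping several
same-class features links all their genes.  Exon/intron sub-classification
of gene bodies is only performed when an exon table is supplied (none is
generated synthetically), otherwise the class is reported as `gene_body`.

Features are conditioned on binding by at most two target peak sets
(`bound_both`, `bound_<name>`, `unbound`) and classified into one of the
16 subsets of {H3K4me1, H3K4me3, H3K27ac, H3K27me3} whose peak sets
overlap them.  State distributions are reported per
(feature class × binding condition), fractions of *features* (not base
pairs), each row summing to 1.  Per gene, the state of its promoter and
(if linked) enhancer is selected; genes with several promoters or
enhancers are resolved to the lexicographically smallest feature id and
flagged — a deterministic rule chosen over guessing intent.

## Signal matrices

The log2-ratio track is log2((expr_b + pc) / (S·ctrl_b + pc)) per bin with
pseudocount pc = 1 (exposed in config; the pseudocount is symmetric, so
swapping the tracks negates the values).  Matrices collect this track in
fixed-width bins across ± 4 kb around region midpoints; cell values are
length-weighted averages of the track over the cell span, computed
exactly from the track's piecewise-linear cumulative integral.  Cells
running off a contig are missing (NaN) and excluded from column means.
Profiles are column means; heatmap rows are ordered by descending row
mean with ties broken by region id (the ordering is a package decision;
nothing in the upstream workflow fixes one).  Rendering is an optional
thin layer — the tested artifact is the numeric matrix/profile.

## DE set construction

Gene tables carry log2FC, raw and adjusted p, and per-sample raw counts.
Genes whose raw-count sum falls strictly below the threshold (60 for
single-comparison analyses, 120 for the three-way single/double-mutant
analyses) are removed first.  Two named rules are provided, both with
strict inequalities as printed in the source figure legends:

* **volcano** — p < 0.05 and |log2FC| > 1 (the p-value field, raw or
  adjusted, must be chosen explicitly; there is no silent default
  because different analyses use different fields);
* **strict_fc** — adjusted p < 0.001 and linear |FC| > 1.5.

Mutation-specific single sets remove any gene also passing in the other
single mutant.  Double-mutant-specific genes additionally require
|log2FC_double| > 1.3 × |log2FC_single| for *both* singles with matching
sign; genes passing the magnitude rule with a sign conflict are reported
separately rather than silently included or dropped.  Venn region counts
use exact membership over 2–3 sets and sum to the union size.  DE sets
are joined to binding-conditioned gene groups as per-(group × direction)
counts and fractions; fractions per direction sum to 1 over the groups.

## Synthetic data and what it does (not) show

The generator emulates the statistical structure of the real libraries:

* **Background**: fragments at a uniform Poisson rate (default 0.02
  fragments/bp, i.e. λ = 10 per 500 bp window — typical of a ~60k-fragment
  library over the 2 Mb toy genome), widths uniform 80–300 bp.
* **Binding sites**: 200 non-overlapping 1 kb sites placed outside the
  blacklist; in-site fragment density is `enrichment` (default 8×) times
  background.  Sites carry a two-target membership (C only / D only /
  both) to exercise cross-sample overlap and binding conditions.
* **Spike-in**: a separate contig receiving Poisson(G·f/(1−f)) fragments
  given G genome fragments, so spike/genome read ratios recover the
  planted fraction f (default 0.01) within binomial error.
* **Annotation**: non-overlapping genes with promoters at TSS−1000..+100
  (a fixed window standing in for curated promoter tables, which publish
  no single window); distal enhancers plus a planted fraction (default
  20%) deliberately overlapping promoters to exercise their removal;
  per-feature planted mark states drawn from promoter/enhancer-specific
  mark probabilities.
* **DE tables**: negative-binomial counts (dispersion 0.1, 3 samples per
  group), null genes with N(0, 0.15) log2FC and uniform p, planted genes
  (10%) with |log2FC| ~ N(2, 0.5) and tiny p; adjusted p is
  Benjamini–Hochberg over the table.  With the default noise-free option
  the planted log2FC is reported exactly, making set recovery checkable
  against the truth sidecar.

Each sample draws from a random stream keyed by (seed, sample id), so
adding samples never perturbs existing ones and identical configs are
byte-identical.  The generator does **not** model read sequences,
mappability, GC bias, duplicate fragments, fragment-length–signal
coupling, or between-replicate biological variance; passing tests
demonstrate the correctness of the computations under the stated
statistical model, not robustness to those real-data artefacts.

## Problem sizes and numerical choices

Default study conditions: one 2 Mb genome contig plus a 100 kb spike
contig, 200 sites, 120 genes, 150 enhancers, 10 blacklist regions, seven
libraries (IgG, two targets, four marks).  Tests run scaled-down variants
(500 kb, 50 sites) where full size adds nothing.  Flatness of null
profiles is judged against the per-cell noise level (profile range under
4× the cell standard deviation); site-centred profile peaking is asserted
with matrix bins at the site half-width, since the planted enrichment is
flat across a site and finer bins produce a noisy plateau with an
ill-defined argmax.  Known limitations: no summit refinement, no local
background, no FDR across windows (raw Poisson p is thresholded, as in
the workflow being re-implemented), and enhancer–gene links are taken
from the catalog rather than predicted.
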