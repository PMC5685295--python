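# Methods

## Scope and model

`methylsilence` identifies genes silenced by CpG-island DNA methylation by
integrating two array modalities measured on the same cell lines: per-CpG
methylation fractions (β-values in [0, 1], Illumina 450K-style) and
normalized expression intensities. One hypomethylated sample — the
seminoma line in the germ-cell-tumour setting the pipeline was designed
for — acts as the reference; every other sample is scored against it.

The causal claim under test is directional: island hypermethylation in a
target line, relative to the reference, silences the gene there. The
pipeline therefore (1) aggregates probe-level β to gene-level island means,
(2) scores differential methylation as Δβ = target mean − reference mean,
(3) asks, per 0.05-wide Δβ bin, whether ≥ 2-fold *lower* expression in the
target is over-represented relative to chance, and (4) only calls genes
silenced above the Δβ level where that over-representation is both
substantial and significant.

## Probe quality control

Probes are removed when (in order; each removal attributed to the first
failing rule so the report's counts are sum-consistent):

* mean detection p across samples > 0.05 (boundary retained at exactly
  0.05 — the rule is "> 0.05");
* averaged log2 signal intensity < 11.1 in either channel (boundary 11.1
  retained);
* multi-site mapping (chrom label containing "MULTI");
* annotation to more than one gene symbol.

Samples with bisulfite conversion ratio ≥ 0.2 are flagged, never removed;
the ratio is a per-sample input (it is not derivable from β values).
Filtering is idempotent, and removing every probe is a hard error.

## Gene-level methylation

A gene's TSS aggregate is the unweighted mean β over island probes
(`island_relation = Island`) whose gene region is TSS1500, TSS200, 5′UTR
or first exon; the body aggregate likewise over `Body` probes. Genes with
several qualifying islands pool all their CpGs into one mean rather than
averaging island means — the aggregate is "the average across all CpGs
analysed", and pooling weights islands by their measured CpG content.
Missing β values are NaN (never 0, which is a valid unmethylated call) and
are simply omitted; an aggregate exists iff its CpG count is ≥ 1.

A gene is *methylated* in a sample when its island-mean β ≥ 0.6. The
boundary is deliberately inclusive and configurable: both ">0.6" and
"⩾0.6" appear in the descriptions this convention derives from, and ≥ is
used consistently here, matching the region-wise summary convention
(methylated ⇔ β ≥ 0.6, unmethylated ⇔ β < 0.3, intermediate between).

## Island annotation and discovery

Probes are classified by distance d to the nearest island edge: 0 inside
(Island), (0, 2000] shore, (2000, 4000] shelf, beyond open sea. Ties at
exactly 2,000/4,000 bp go to the inner band. North/south is strand-aware:
north is 5′ of the associated gene, so for minus-strand genes the north
side lies at higher coordinates.

`find_cpg_islands` implements the classic composition rule: a 500 bp
window qualifies with GC fraction > 0.55 and observed/expected CpG ratio
count(CG)·L / (count(C)·count(G)) > 0.65 (both strict); windows containing
N never qualify. The scan steps 1 bp; overlapping/adjacent qualifying
windows merge, and because a merged union need not itself satisfy the
criteria, each merged interval is re-tested as a whole and trimmed one
base from *both* ends per step until it passes or shrinks below 500 bp
(discarded). Symmetric trimming is a deterministic tie-break; it can
discard an asymmetric interval a one-sided trim would have kept, which we
accept for reproducibility. Reported intervals are 1-based inclusive,
never overlap, and each satisfies all three criteria on re-test (a tested
invariant).

## Expression

Genes below the per-sample control-background threshold in *every* sample
are removed; probe-level matrices collapse to genes by unweighted means.
Fold change is computed on the linear normalized scale as
max(ref, target)/min(ref, target) with the direction carried separately,
so all folds are ≥ 1 and "no difference" ⇔ fold < 2. Genes absent from
the expression matrix cannot enter any expression category and are
excluded before binning. The group test used for primary-tumour tables is
Welch's unequal-variance t with Welch–Satterthwaite df, right tail; two
identical constant groups are defined to give t = 0, p = 0.5.

## Contingency analysis and threshold selection

Per comparison and region basis, genes with Δβ ≥ 0 are assigned to
half-open bins [k·0.05, (k+1)·0.05) (Δβ = 1.0 in the top bin); negative-Δβ
genes go to a reciprocal report rather than the table. Observed counts per
bin are (correlating = ≥ 2-fold higher in the reference, no difference,
anti-correlating); expected counts are row_total × column_marginal /
grand_total with marginals over the whole table — the null that expression
category is independent of the methylation bin. Each bin gets Pearson's
χ² on 2 df with no continuity correction; with 2 df the upper tail is
exactly exp(−χ²/2), which the tests exploit as a closed-form oracle.
Empty bins are retained with zero expectation and a blank p. Stars follow
* p<0.05, ** p<0.01, *** p<0.001 on the recomputed p.

A bin *qualifies* when its observed correlating count is ≥ 2× expected
and p < 0.05; the selected Δβ cut is the lowest qualifying bin boundary
with no qualifying bin below. On the packaged published table this yields
0.65, and deleting the 0.65 row moves it to 0.70 (both tested). The ratio
rule applies to the correlating category only: the question is whether
*silencing* exceeds chance, not whether any association does.

Silenced-gene calls require Δβ ≥ cut (inclusive, configurable) and a
≥ 2-fold deficit in the target; body-island calls are flagged `body_only`
when the gene lacks a TSS aggregate or its TSS Δβ is below the cut — those
genes are silenced in association with body-island methylation alone.
Calls are monotone in the cut (tested property).

## Cross-study concordance and overlap tests

External cohorts enter as per-gene fold tables; a call is concordant when
the external fold is strictly > 1.5 in the same direction. Matching is
case-insensitive exact symbol match; aliases are a curation concern and
are logged as not assessable. Overlap significance is the upper-tail
binomial P(X ≥ k) in m trials at background rate p0 (default: comparison
set size / universe), evaluated through scipy's log-space survival
function so tails below 1e-30 stay representable; p0 is always reported
with the result because no universally correct null rate exists.

## qPCR relative quantification

The Pfaffl ratio E_t^ΔCt_t / E_r^ΔCt_r uses ΔCt = mean Ct(control) −
mean Ct(treated) and per-assay efficiencies in [1, 2.2], defaulting to 2.0
(perfect doubling) since measured efficiencies are rarely reported.
Reactivation significance is a seed-controlled bootstrap: all four gene ×
condition replicate cells are resampled with replacement, the ratio
recomputed, and p is the add-one-smoothed fraction of bootstrap ratios
≤ 1 (one-sided, ≥ 3 replicates required). The test suite checks it
against exhaustive enumeration of every weighted resample at n = 3.

## Synthetic data generator

The generator emulates the study conditions the analysis assumes, not
array chemistry. Each gene gets a TSS island on one synthetic chromosome
(genes every 50 kb), a 0.4 chance of a body island, plus one shore, one
shelf and one open-sea probe in the correct distance bands. Island β
values are beta-distributed — the standard two-parameter model for
methylation fractions — with defaults Beta(1, 9) (mean 0.1) for
unmethylated and Beta(8, 2) (mean 0.8) for methylated regions; open-sea
probes draw from the methylated distribution, shores/shelves intermediate,
reproducing the genome-wide pattern of low island / high open-sea
methylation.

Planted effects: a configurable fraction of genes (default 5% TSS, 3%
body) is hypermethylated with a per-gene Δβ drawn uniformly from the
effect range (default 0.65–0.9, the band where real silencing effects
concentrated); target island probes are drawn around the shifted mean with
concentration 60 and recentred so the island-mean Δβ equals the planted
effect exactly (up to a rare clip at the [0, 1] boundary; island means are
clamped at 0.985, so configs whose *minimum* effect cannot fit under that
clamp are rejected as infeasible). Half of hypermethylated genes (default)
are silenced, with true folds uniform in [3, 10]; expression is a
lognormal per-gene baseline (median 500), divided by the true fold in
target samples, times mean-corrected lognormal noise with CV 0.1 by
default — so zero noise reproduces planted folds exactly. qPCR simulation
gives reactivated genes a 3-cycle earlier treated Ct with 0.1-cycle
replicate noise.

Randomness: one `numpy` Generator per dataset, keyed by
(seed, crc32(dataset name)), so generating expression never perturbs the
methylome stream and adding datasets is reproducibility-safe. Identical
seeds give byte-identical outputs (tested).

What the generator does *not* model: probe type I/II chemistry and
normalization artifacts, batch effects, copy-number confounding, gene
length/probe density heterogeneity, or correlated noise between probes.
Passing recovery tests therefore demonstrate correctness of the inference
machinery under the stated statistical assumptions, not robustness to
those real-data complications.

## Problem sizes and numerical choices

The end-to-end recovery checks use 2,000 genes × 4 samples (~26,000
probes), which keeps the full suite in a few seconds while leaving the
high-Δβ bins populated well above the qualification threshold; at the
strong-effect conditions (Δβ ∈ [0.7, 0.9], folds 3–10, CV 0.1) recovery is
complete (sensitivity 1.0, FDP 0.0 at the tested seeds, comfortably inside
the ≥ 0.9 / ≤ 0.1 bands asserted). Bin assignment adds 1e-9 before
flooring to keep exact multiples of 0.05 in their own bin under binary
floating point. The packaged contingency table is validated on load
(19 bins, width 0.05, strictly increasing).

## Known limitations

* The threshold search can select a low cut when a sparse low-Δβ bin
  happens to qualify (e.g. a body-silenced gene whose TSS Δβ is small);
  with the 2-fold expression gate this does not inflate false calls in
  practice, but the per-bin p-values are not multiplicity-corrected — by
  design, matching the analysis this reimplements.
* Gene symbols are the join key throughout; no alias resolution.
* The island finder's symmetric trimming is one of several defensible
  merge-resolution rules; intervals near the qualification boundary can
  differ from tools that trim asymmetrically.
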