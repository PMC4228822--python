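# Methods

## Scope and coordinate conventions

tuberkit reimplements the bespoke computations of a fungal multi-omics
analysis — methylation calling, window CNV detection, the Composite RIP
Index, RPKM summaries and novel-transcript filtering — over the standard
interchange formats (FASTA, GFF3/BED, CGmap/ATCGmap, GTF, wiggle).
Internally all intervals are 0-based half-open on the forward strand;
per-cytosine positions are 1-based on the cytosine's own strand, matching
the CGmap dialect. GFF3 (1-based closed) and wiggle (1-based) are converted
at the boundary. Read alignment, transcript assembly, repeat discovery and
protein homology search are upstream tools whose outputs this toolkit
consumes; it does not reimplement them.

## Methylation model

The level of one cytosine is estimated as `#C/(#C+#T)` over the bisulfite
reads covering it — an estimate of the fraction of cells methylated at
that site. Sites covered by fewer than `min_cov = 4` reads are excluded
before any summary (the threshold is per-run configurable; very
low-coverage samples such as a symbiotic-stage methylome may need it
lowered, at the cost of noisier per-site estimates).

Contexts (CG, CHG, CHH; H = A/C/T) are classified from the *reference*
genome, reading the two bases downstream on the cytosine's own strand;
sites whose context runs off the contig or touches an N are "unknown" and
excluded from all summaries. Classification from the reference rather than
from reads means a sample-specific variant at the +1/+2 position would be
mis-contexted; at the toolkit's intended scale this is negligible and
matches common practice.

Scope means (genome / gene / TE × context) are **unweighted means of
per-site levels**, not read-pooled `ΣC/Σ(C+T)`. Site-weighted averaging is
the common convention and treats each cytosine equally regardless of its
coverage; the choice is stated in output headers because the two
statistics differ when coverage correlates with methylation. A site inside
two overlapping same-class features counts once (set semantics: scope
membership is membership in the union of the class's intervals).

Metagene profiles rescale each gene body to `n_bins_body = 20` equal bins
with `flank_bp = 500` flanks in `n_bins_flank = 10` fixed-width bins;
minus-strand genes are reversed so bin 0 is always 5′. Bin values pool
sites across genes; empty bins are NaN with an explicit site count. The
defaults are conventional for compact fungal genomes (median gene ~1.5 kb)
and configurable. TE silencing analysis partitions TEs at expression
exactly 0 (silenced) vs > 0 (expressed), threshold configurable, and ranks
expressed TEs ascending by expression with ties broken lexicographically
for determinism.

## CNV model

The genome is tiled from position 0 into `window_bp = 100000` windows (the
last window of a contig may be short). Each library's mean per-bp window
depth is divided by that library's genome-wide mean depth — the simplest
library-size normalization, which makes calls invariant to rescaling
either library — and a window is a CNV call when `|log10(ratio)| >= 0.3`,
boundary inclusive (0.3 ≈ a two-fold change, which is why log base 10 is
the natural reading; the base is configurable and recorded in outputs).
Windows with zero depth in either library are reported but never called:
excluding them avoids an unstated pseudocount/smoothing choice. Each
called window is one region; adjacent-window merging exists behind a flag
but is off by default, since the window is the unit of both calling and
confirmation. Confirmation between two library pairs requires the
identical window called in the same direction.

Note the toy-scale caveat: because normalization divides by the
genome-wide mean, planting copy-number changes in a large *fraction* of
windows shifts the mean itself and shrinks every ratio. Recovery
experiments therefore plant a few windows among hundreds; the same effect
exists in real data only when CNVs cover a substantial genome fraction.

## Composite RIP Index

RIP converts CpA to TpA within repeats. From one pass of overlapping
dinucleotide counts (pairs containing N skipped):

* product index `TpA/ApT` — excess of the mutation product, normalized by
  ApT to control for local TA density;
* substrate index `(CpA+TpG)/(ApC+GpT)` — depletion of the substrate and
  its reverse complement;
* `CRI = product − substrate`; positive values indicate RIP.

Zero denominators yield an explicit undefined result (NaN in tables, with
a `defined` flag) rather than an error or a dropped row. Counting uses the
given strand only: TpA and ApT are each self-reverse-complementary and
CpA↔TpG, ApC↔GpT swap within their sums, so CRI is exactly strand
symmetric and the choice of strand is irrelevant (property-tested).
Features with fewer than 20 counted pairs are flagged low-confidence
(configurable); sliding-window mode defaults to 500 bp windows stepping
100 bp, conventional for RIP scans. The toolkit scores genomic repeat
copies, not consensus sequences.

## Expression

A read counts for a gene or TE only when its aligned span lies entirely
within that feature's span and touches no other feature (strand-blind);
reads touching zero features, crossing a feature edge, or touching two or
more features are tallied as unassigned with reasons, so assigned +
unassigned always equals input reads. RPKM uses the union length of all
exons (the feature span when no exons are annotated) and the total of
counted reads as the per-million denominator. Fold changes are oriented
treated/untreated, undefined when the untreated RPKM is 0, and rounded to
two decimals (round-half-even) only at serialization. Mapability is
100·unique/raw; per-strand coverage is unique·read_length/(2·genome_size)
with the genome size an explicit required input. Differential-expression
testing is out of scope; table writers pass an externally supplied
p-value column through untouched.

## Novel-gene cascade

Filters apply in order: class code "u" (unknown intergenic transcript) →
no positional overlap (≥1 bp, strand-blind) with known annotation → FPKM
≥ 4 across the 95% confidence interval, read as `conf_lo >= 4`, the
strictest consistent reading (a point-estimate mode exists behind a flag).
Survivors are clustered by transitive positional overlap — a start-sorted
sweep whose clusters equal the connected components of the overlap
graph — into one spanning interval each (a longest-member mode exists
behind a flag). Clusters spanning ≥ 36,573 bp (the longest known truffle
gene) are removed, then clusters are accepted only if flagged homologous
to a known protein; the homology flag is consumed from a table, never
computed. Length removal precedes the homology requirement; merged-sample
analyses cluster the union of per-sample survivors. Clustering is
order-invariant and idempotent (tested).

## Synthetic data generator

The generator emulates the statistical structure of the emulated study at
toy scale; defaults:

| parameter | default | rationale |
| --- | --- | --- |
| contigs | 2 × 500 kb | ≥ 4 CNV windows per contig at 100 kb; seconds-scale tests |
| te_fraction | 0.58 | the emulated genome's repeat fraction (> 58%) |
| n_genes / n_tes | 40 / 60 | gene density scaled to the toy genome |
| gene length | ~1.5 kb (uniform 0.5–1.5×) | compact fungal genes |
| meth_means | mycelium feature×context table (TE CG 70.51%, gene CG 0.64%, …) | the study conditions being emulated |
| beta_concentration | 10 | site-level spread around each mean; only means are published, so the Beta concentration is a modeling choice |
| depth | 30× | matches the deep bisulfite libraries |
| conversion_failure | 0.005 | two-round bisulfite conversion is efficient but not perfect; no rate is published, so a small conventional residual is used |

Mechanics: background bases are i.i.d. uniform; features are packed
without overlap with uniform random gaps (every admissible arrangement
equally likely given lengths). True site levels are Beta(mean·c,
(1−mean)·c), degenerate at exact 0/1 means; intergenic sites use the
genome-background means. The observation model is coverage ~
Poisson(depth) per site and `mc ~ Binomial(coverage, p + (1−p)·e)` with
`e` the non-conversion rate — so observed levels are biased upward by at
most `e`, which is why near-zero gene-body means recover to ~1.1% rather
than 0.64% at `e = 0.005`. In-silico RIP marks every CpA (C) and TpG (G,
the minus-strand CpA) on the *original* sequence in one pass, then mutates
a Bernoulli subset — mutation never creates or destroys another site's
eligibility, making the operation order-independent. Coverage tracks
sample window read totals directly as Poisson(depth·width), scaled inside
planted regions (prorated for windows straddling a region edge);
expression counts are Poisson with planted fold changes. Everything is
deterministic under its seed, and every simulator emits a truth table
sufficient to score recovery.

What the generator does **not** emulate — and hence what passing recovery
tests do not establish about real data: sequencing error and read-level
artifacts (pileups are drawn directly, not from reads), mapping bias and
repeat multi-mapping, overdispersed (non-Poisson) coverage and counts,
PCR duplicates, CG-content heterogeneity along the genome, exon structure
(simulated genes are single-exon; multi-exon handling is exercised by
unit tests with explicit exon sets), and biological covariation between
methylation, expression and copy number beyond what a test plants
explicitly.

## Numerical and degenerate-input choices

Undefined is a value, not an error: methylation level at zero coverage,
fold change over zero untreated RPKM, CRI with a zero denominator and the
log ratio of a zero-depth window are all NaN/None with a flag or reason,
and propagate rather than abort. Parsers are strict — malformed lines
abort with the line number; a CGmap level column inconsistent with its
counts (beyond 0.01) is an error, and the stored level is always
recomputed from counts. Thresholds are boundary-inclusive exactly as their
definitions state: coverage ≥ 4 kept, `conf_lo` = 4 kept, span = 36,573
removed, |log ratio| = threshold called. Table rounding (2 decimals,
round-half-even) happens only at serialization. All analysis thresholds
live in one config namespace with the study's values as defaults and are
echoed into every run manifest; runs are byte-identical under a fixed seed
and config, with stage-level checksum gating on reruns.

## Problem sizes used in validation

The shipped validation suite measures recovery at: 1 Mb genome / 30×
depth (~500k cytosines) for methylation; 24 Mb of 100 kb windows (240
windows, 7 planted) for CNV sensitivity/FPR and a 9.6 Mb / 7-window
construction for the genome-fraction figure; 87,380 exhaustive short
sequences plus 1,000 random kilobase sequences for the CRI oracle and
strand symmetry; 50 features at Poisson mean 1,000 for fold-change
recovery. These sizes make the statistical tolerances (±0.01 on
methylation means, <1% CNV FPR, ±10% fold change) comfortably larger than
the corresponding standard errors.

## Known limitations

* CNV calling has window-level resolution only: no segmentation (HMM/CBS),
  no breakpoint refinement, no absolute copy-number estimate.
* The methylome module computes summaries, not statistics: no
  differentially methylated region calling or between-sample tests.
* The expression module consumes unique placements; multimapping rescue
  and FPKM-with-CI estimation are upstream concerns.
* CGmap/ATCGmap column order follows the BS-Seeker2 convention; other
  dialects need conversion.
* The generator's Poisson coverage understates real-data variance;
  recovery tolerances would widen under overdispersion.
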