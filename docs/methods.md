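# Methods

dmrkit implements the bin-based comparison workflow used to study DNA
methylation dynamics across plant cell types from whole-genome bisulfite
sequencing (WGBS), together with a synthetic methylome generator that makes
every stage testable without sequencing data. This note records the model,
the parameter choices, and the places where a design decision was genuinely
open.

## Input model and coordinate conventions

The pipeline starts downstream of alignment and methylation extraction: its
input is a per-cytosine report (chromosome, 1-based position, strand,
methylated read count, unmethylated read count, CG/CHG/CHH context). Strands
are never collapsed — the two cytosines of a symmetric CG dyad are separate
records, as extraction tools emit them. Internally every interval (bin,
feature, DMR, output BED) is 0-based half-open; only cytosine positions are
1-based.

Biological replicates are pooled by summing read counts per cytosine
**before** any coverage filtering. Pooling first retains loci that reach the
coverage floor only jointly, which is the point of pooling replicates at
all; the alternative order (filter per replicate, then pool) would discard
them. A position present in one replicate only keeps that replicate's
counts.

## Bin methylation level

The genome is tiled from coordinate 0 into non-overlapping 100-bp bins. A
cytosine's level is `n_meth / (n_meth + n_unmeth)`, defined only at non-zero
coverage. A bin's level is the **unweighted mean of per-cytosine levels**
over the context cytosines in the bin with coverage ≥ 5 reads — not the
pooled-count ratio — so a single deeply covered cytosine cannot dominate the
window. Bins with fewer than 5 qualifying cytosines are emitted but flagged
ineligible; cytosines under the coverage floor are excluded from the mean
rather than disqualifying the bin. Bin accumulation is strict left-to-right
summation (not vector pairwise summation) so the result is bit-identical to
a per-cytosine reference loop; this makes the level reproducible to the last
bit across implementations of the same definition.

The tiling phase (bins starting at 0) is a convention; nothing downstream
depends on it. "Overall" methylation of a sample or feature class is the
unweighted mean of eligible bin levels.

## DMR calling

For two pooled samples, only bins eligible in both are compared (no
imputation). Two criteria must both hold:

* effect size: |level_B − level_A| ≥ 0.5 (CG), 0.3 (CHG) or 0.1 (CHH);
* significance: two-sided Fisher's exact test p < 0.01 on the 2×2 table of
  pooled bin read counts `[[meth_A, unmeth_A], [meth_B, unmeth_B]]`.

The effect-size criterion uses the mean-of-cytosines level and the test uses
pooled integer counts; these are different statistics by design — the exact
test needs counts, and the level formula deliberately is not a count ratio.
No multiple-testing correction is applied by default (the rule is stated on
raw p-values); a Benjamini–Hochberg option exists behind a flag.

Fisher's test is implemented by direct enumeration of the hypergeometric
support from cached log-factorials; the two-sided p sums all tables whose
probability is ≤ the observed table's with 1e-7 relative slack on the tie
comparison. The unit suite checks it against `scipy.stats.fisher_exact` and
against exact integer-arithmetic enumeration; an exhaustive grid over all
2×2 tables with entries ≤ 30 agrees with the exact oracle within 1e-10.

Significant bins of the same chromosome, context **and direction** are
merged transitively when the end-to-start gap is ≤ 200 bp (inclusive at
exactly 200). Direction-blind merging would destroy the hyper/hypo label
that every downstream summary uses. Merged DMRs carry the minimum
constituent p, the bin-count-weighted mean difference (which makes
re-merging idempotent) and the constituent bin count. Because hyper and
hypo runs are merged independently, disjointness is guaranteed within one
(context, direction) stream.

## Feature annotation and DMGs

Each DMR gets exactly one class by the exclusive priority **TE > TEG > gene
> intergenic**, where TE candidacy requires the overlapping TE interval to
be strictly longer than 500 bp. The priority makes the partition exclusive;
within the winning class, the feature with the largest overlap (leftmost on
ties) supplies the identifier. A differentially methylated gene (DMG) is a
gene covering strictly more than 80% of a DMR's length; each DMR nominates
at most one gene (greatest overlap), so a DMR split 50/50 across two genes
nominates none.

## Density profiles

The methylation-difference distribution between two samples uses 50-bp
windows with the same mean-of-cytosines level formula. A window is counted
only when both samples have ≥ 20 *informative* cytosines of the context and
at least one sample reaches 70% (CG), 30% (CHG) or 10% (CHH) methylation.
"Informative" is read as covered by ≥ 1 read: the 5× floor is a bin/DMR
rule, and a coverage floor on informativeness is not part of the stated
census. Note that 20 context cytosines per 50 bp is a demanding density —
in an i.i.d. random sequence only CHH approaches it — so on synthetic
genomes the census is sparse unless the context is dense; this mirrors the
fact that real plant genomes satisfy it mainly in cytosine-rich windows.

## SLH and SLM

Sexual-lineage hypermethylation compares male sex cells (meiocyte,
microspore, sperm) with somatic tissue (seedling) in 100-bp bins. The sex
average (SexAV) is the unweighted mean of cell-type bin levels over all
three cell types for mCG and mCHH, but over meiocyte and microspore only
for mCHG (sperm loses CHG methylation and would dilute the contrast). With
Diff = SexAV − Seedling per context, a bin is SLH when all of:

1. Fisher's exact p < 0.01 on **total** methylation counts. "Total" is read
   as the all-context pooled counts of the bin: the sex side pools each
   context over its contributing cell-type set and unions the three
   contexts into one 2×2 table against the pooled somatic counts — the only
   reading that yields a single table per bin.
2. Every sex-cell replicate's all-context bin level exceeds every somatic
   replicate's. A bin where any replicate lacks a defined level fails this
   condition (no evidence, no call).
3. Diff_CG > 0, Diff_CHG > 0.05, Diff_CHH > 0.1, and their sum > 0.4.

SLH bins require a defined level in all three contexts in every
contributing cell type and in soma (minimum one ≥ 5× cytosine per context;
the five-cytosine bin rule is a DMR eligibility rule, and imposing it per
context would discard most CG bins).

SLH loci split into **SLM** — somatic mCHH strictly < 0.05 AND somatic mCHG
strictly < 0.1, i.e. non-CG methylation arising de novo in the sexual
lineage — versus **canonical SLH** (everything else). Boundary values go to
canonical because the SLM definition is strict. A locus with an undefined
somatic level is unclassifiable and excluded with a warning rather than
assumed unmethylated, which would invent evidence for SLM.

## Synthetic data generator

The generator emulates the statistical structure the pipeline assumes, not
rice biology:

* **Genome** — i.i.d. nucleotides at 44% GC (plant-typical); cytosine
  positions and contexts derive from the actual trinucleotides on both
  strands, so context calls are internally consistent with a sequence.
  A gene/TEG/TE annotation is laid down with TE lengths (150–1500 bp)
  straddling the 500-bp class boundary by construction.
* **Counts** — coverage ~ Poisson(mean 30 by default, the depth at which
  the ≥ 5-read floor retains essentially all sites); methylated reads ~
  Binomial(coverage, level) with a symmetric error rate (default 0.005)
  folding bisulfite non-conversion and sequencing error into one parameter,
  since the pipeline never separates them. Everything is deterministic per
  (seed, cell type, replicate); replicates differ only by sampling noise.
* **Baselines** — mCG 0.5, mCHG 0.25, mCHH 0.05 for every cell type unless
  a truth profile says otherwise: plant-typical magnitudes that keep planted
  effects inside [0, 1].
* **Planted DMRs** — grid-aligned runs of 1–4 bins, shifted by a chosen
  delta in one cell type, placed only where every spanned bin holds ≥ 5
  cytosines of the target context and separated by a guard bin. A "planted
  differential region" in a window with too few context sites would be
  undetectable by the caller's own eligibility definition and is not a
  meaningful truth label, so the generator does not create such labels.
* **Planted SLH loci** — single bins with designed levels: the SLM-type
  truth uses a somatically clean non-CG profile (mCHG 0.02, mCHH 0.01), the
  canonical-type a somatically methylated one (mCHG 0.3, mCHH 0.15); sex
  levels satisfy every Diff threshold with ≥ 0.1 margin. The margins mean
  recovery failures indicate defects, not sampling bad luck.

What the generator does **not** emulate: real sequence composition and CpG
island/pericentromere structure, spatially correlated methylation,
coverage biases (GC, mappability), asymmetric non-conversion, or
context-dependent error. Passing recovery tests therefore demonstrates that
the calling logic implements its definitions correctly at realistic depths
and effect sizes — not that those thresholds are optimal for real
methylomes.

## Problem sizes and numerical choices

The recovery checks use a 1-Mb single-chromosome genome with 200 planted
CHG regions (Δ = 0.4 at 30×) and 50 planted SLH loci — large enough that
recall/precision estimates are stable, small enough to re-run routinely.
Levels are kept at full floating precision with no rounding before
comparisons; all threshold comparisons are exactly as stated (≥ for effect
sizes, strict < for p-values, strict > for the Diff and SLM criteria).
Degenerate inputs are defined, not special-cased: empty files give empty
tracks, a zero-margin Fisher table gives p = 1, a zero-coverage cytosine
has no level and never contributes.

## Known limitations

* DMR calling is per-bin with post-hoc merging; no smoothing or HMM
  segmentation, and boundary precision is one bin.
* Bins eligible in only one sample are dropped, so coverage differences
  between samples shrink the compared territory.
* The SLH "total methylation" table and the replicate-ordering level are
  stated informally in the field's methods descriptions; the readings used
  here (all-context pooled counts; all-context per-replicate bin levels)
  are documented above and encoded in one place each.
* The generator's i.i.d. sequence makes the 20-cytosine density census
  sparse outside CHH; tests of that census therefore use constructed
  fixtures with known window contents.
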