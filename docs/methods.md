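# Methods

## Scope and model of the data

The package analyses a two-condition (control vs knockdown), replicated
RNA-seq experiment at the exon level, together with genomic signal tracks
and gene/protein set resources. The statistical unit is the *counting bin*:
per gene, the union of all transcript exons partitioned at the union of all
exon boundaries, numbered in genomic order (`gene:E001`, …). All internal
coordinates are 0-based half-open; GTF (1-based closed) and BED are
converted at the file boundary. Bin numbering ignores strand; strand enters
only when profiles are oriented. Overlapping genes are flattened
independently per `gene_id` — the analysis unit is the gene-linked exon.
Whether whole annotated exons or counting bins are the right unit for the
signal-profile stage is not uniquely determined; bins are used throughout
because they make one exon table serve every stage, and whole-exon input is
possible by supplying single-transcript models.

## Differential exon usage

Exon usage is the fraction of a gene's reads on one bin. Replicate counts
are summed per condition and each bin is tested with a two-sided
conditional exact (Fisher) test on [exon, gene-rest] × [control,
knockdown], with Benjamini–Hochberg correction across tested bins and
classification at p_adj ≤ 0.05 (the ≤ convention; a raw-p mode exists for
analyses that used unadjusted p < 0.01). The effect size uses a 0.5
pseudocount to stay finite at zero counts. Significant positive bins are
"exclusive" (more excluded in normal cells), negative ones "inclusive".

This deliberately replaces an exon-level negative-binomial GLM of the
DEXSeq kind. The justification: conditional on a gene's per-replicate
total, bin counts are multinomial, so the exon-vs-rest split given its
margins is binomial and the conditional exact test is exact regardless of
gene-level overdispersion — the test is valid whenever within-gene usage
*proportions* are stable across replicates. What is lost relative to a GLM
is power/robustness when the proportions themselves vary biologically
between replicates; that regime is outside the generator's model and the
package's validation, and is the main caveat for real data. Bins of
single-bin genes (empty gene-rest) and of genes with summed counts below
`min_gene_count` (default 20 per condition; the exact test is powerless
below this) are reported `untested`, not dropped.

## Splicing events and PSI

Events are derived from annotation (pairwise transcript comparison on the
shared splice graph), not discovered from reads; junction counts arrive as
a table, with BAM→junction extraction a documented pre-step. Eight modes
are recognised (CE, MCE, A5SS, A3SS, RI, AFE, ALE, MXE). Precedence rules
where modes overlap are a design choice: retained introns are recognised
before alternative splice sites (a merged exon would otherwise read as
A5SS/A3SS against each flank), and a multi-exon skip supersedes its
constituent single-exon skips (longest pattern wins; CE events whose
cassette lies inside an MCE's skipped span are dropped). Donor/acceptor
assignment is in transcribed-strand orientation. Event ids are stable under
input order (sorted by genomic coordinate).

PSI per condition is inclusion/(inclusion+exclusion) over replicate-summed
junction counts; the test is the same two-sided conditional exact test,
BH-adjusted by default with a raw-p option, significance at p < alpha
(strict, matching the common event-level threshold convention). Events
with zero reads in a condition are `untested`.

## Meta-exon profiles

Each exon contributes a 300-bin row: upstream flank, body, downstream
flank, with flank length equal to the exon length, so the x-axis is in
exon-length units (−1.0 to 2.0, 0.0 = exon start, 1.0 = exon end). Per-base
values are either binary peak occupancy or continuous track signal; both
modes exist because peak-based and input-normalised descriptions of such
figures are both common, and neither is claimed to reproduce any specific
published panel. The 10-bp centred sliding-window mean is applied in base
space *before* rescaling, keeping the window's physical meaning across exon
lengths (smoothing after binning would make the window exon-relative).
Rescaling is fractional-overlap mean pooling, which conserves the mean of
each third exactly (each base carries total weight 1); occupancy profiles
are clipped to [0,1] to absorb ~1e-13 cumulative-sum round-off. Minus-strand
exons are reversed so bin 0 is transcriptionally upstream. Flanks running
past the chromosome start are zero-filled and the clipped fraction
recorded; exons shorter than 3 bp are excluded with a warning.

Class comparisons apply the two-sample KS test and the Welch t test to
per-exon summaries (mean over body bins by default; region selectable)
for up-vs-unchanged, down-vs-unchanged and up-vs-down. Per-exon summaries
are used rather than bin-wise means because exons, not bins, are
exchangeable units. The `unchanged` class is the default background, with
an all-tested-exons option. Note that the two-sample KS p-value is discrete
(the statistic lies on a k/n lattice), so calibration checks of p-value
uniformity should use the continuous t-test p-values; the KS test's
rejection rate is still checked against its nominal level.

## Enrichment and proteomics set logic

Gene-set enrichment is a one-sided (over-representation) Fisher exact test
per GMT set, restricted to a user-supplied universe (default in the
pipeline: all genes with ≥ 1 tested exon — the fair background for "genes
containing regulated exons"), BH-adjusted across sets; a two-sided option
exists. Term hierarchies are not modelled: each set is tested flat.
Contaminant exclusion for proteomics lists uses prefix regexes (default
`^KRT`, `^RPL`, `^RPS` after upper-casing) applied identically to all
lists; high-confidence interactors are the contaminant-free anchor list
intersected with the union of the support lists.

## Peak calling stand-in

The bundled caller estimates one genome-wide Poisson rate λ̂ = track mass /
covered bases, scores tiling windows (default 100 bp) by the Poisson upper
tail of the rounded window sum, merges adjacent significant windows and
drops regions shorter than `min_length`; score = −log10 of the best window
p. It has no duplicate handling, no local background and no control track —
it exists so the pipeline runs end-to-end from a bedGraph alone; externally
generated peak BEDs are the canonical input.

## Synthetic data generator

The generator emulates the statistical structure the analyses assume, with
one RNG stream per output file seeded by (master seed, file label) so
outputs are byte-reproducible and independent of one another.

- **Annotation**: gene *i* plants event mode *i* mod 8 via a two-transcript
  pair, alternating strands and two chromosomes; loci are disjoint; every
  fifth gene is a processed transcript. Defaults: 60 genes, 4–8 exons of
  80–300 bp, introns 200–1000 bp.
- **Counts**: per replicate, gene totals ~ NB(mean = 2000, variance =
  mean + 0.1·mean²; Poisson at dispersion 0), split multinomially over bins
  with length-proportional baseline proportions. 10% of bins are planted
  "up" and 10% "down" by multiplying the knockdown proportion by 2^±1 and
  renormalising. Renormalisation necessarily shifts the other bins of a
  planted gene slightly in the opposite direction; the ground truth
  therefore labels every bin by its exact true usage-odds change and lists
  the primary planted bins separately — power is measured on the planted
  set, FDR against truly unchanged bins.
- **Junctions**: per event and replicate, totals ~ Poisson(200), inclusion
  ~ Binomial(total, PSI) with PSI 0.5 in control; 20% of events (a choice
  the configuration exposes) get knockdown PSI shifted by +0.4.
- **Tracks/peaks**: peaks cover exon bodies with class-dependent
  probability (default scenario: hydroxymethylation, H3K4me3, MeCP2 and
  Pol II at 0.8 over down-regulated vs 0.1 elsewhere; H3K36me3 at 0.8 over
  up-regulated; methylation depleted over both changed classes at 0.05 vs
  0.3), plus Poisson background peaks (0.5 per 10 kb) and a gamma-noise
  piecewise-constant signal (mean 1, +6 inside peaks) on a 25-bp lattice.
- **Gene sets / protein lists**: GMT sets built around genes with planted
  exons plus random sets; three protein lists with known overlap and
  seeded keratin/ribosomal contaminants.

What the generator does **not** emulate: replicate-to-replicate variation
in usage proportions, positional read biases, mappability, junction-read
ambiguity between events, or spatially correlated signal noise. Passing
tests therefore demonstrate correctness of the statistics under the
multinomial-within-gene model, not robustness to those real-data effects.

## Validation problem sizes

The bundled checks run at desk scale: exact-test oracle agreement on ~430
2×2 tables with margins ≤ 200 against integer-arithmetic tail summation;
null calibration on 20 simulations of ~630 bins (usage) and 20 × ~500
events (PSI); recovery at the default conditions averaged over 3 seeds
(usage at 60 genes, PSI at 250 genes); marker-ordering checks at 200 exons
per class. Published analyses of this design ran on full mouse/rat
transcriptomes with external tools (DEXSeq, MACS, DAVID, vendor splicing
software); those tool internals and dataset-specific counts are not
reproduced here.

## Numerical and degenerate-input conventions

Pseudocount 0.5 in usage effect sizes; Poisson window counts rounded to
integers; peak p-values floored at 1e-300 before −log10; identical
summary vectors short-circuit to (stat 0, p 1) in class comparisons, and
zero-variance Welch tests report (0, 1); empty classes/comparisons are
omitted with warnings rather than errors; category fractions of empty
protein sets report 0/0 = 0.0. Even smoothing windows are incremented to
the next odd width (logged).
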