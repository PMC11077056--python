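# Methods notes

## Gene-model flattening

Genes are keyed by (gene symbol, chromosome, strand); the same symbol on two
chromosomes is treated as two genes, and overlapping genes on opposite
strands are processed independently.  All isoform exons of a gene are
projected onto the genome and the exonic union is cut at every distinct exon
boundary, producing segments whose identifiers are coordinate-derived
(`gene:chrom:start-end`), so output is reproducible regardless of input row
order.  A segment is *internal* when, genomically, an annotated intron ends
at its start and another begins at its end; it is a *cassette exon* when it
is internal and at least one transcript carries it inside a non-terminal
exon.  Flanking exons are taken from the transcript with the numerically
lowest accession among those carrying the segment as an internal exon
(prefix and version ignored; lexicographic tie-break), which keeps flank
assignment deterministic in genes with many isoforms.  Intron retention is
outside the model: only exonic sequence is segmented, and retained-intron
segments are not produced.

## PSI estimation

Inclusion junctions are summed over every donor inside the flanking exon
that reaches the segment's boundary exactly (this tolerates composite flanks
created by flattening); the exclusion count is the single exact
flank-donor-to-flank-acceptor skip junction — more distant skips are
ignored, i.e. each cassette exon is treated as isolated.  The default
estimator PSI = (Ju+Jd)/(Ju+Jd+2·Je) reflects that an included molecule
yields two junction reads and an excluded one a single read; `max_side` and
`mean_side` variants are available as a sensitivity switch.  The per-sample
coverage filter (≥30 reads) applies to the unweighted total Ju+Jd+Je, and
the per-exon filter (mean ≥50) is the mean of that total over retained
samples.  The standard deviation uses the n−1 denominator; with fewer than
two retained samples the CV is undefined and the exon is flagged
below-coverage.  PSI is a fraction internally and a percent in every
report and threshold.

## Classification

CV thresholds are derived once, on the pooled population, and reused for any
per-tissue partition (`partition_by_group`), which mirrors deriving global
cutoffs and then asking in which tissues an exon dips.  Two published rule
profiles are kept switchable because the text and the figure legend of the
source analysis disagree slightly: `methods` (default) anchors cv_max on the
[85,90) bin and cuts resilience at PSI > 99; `figure` anchors on [80,85) and
cuts at 99.5.  Boundary ties go to *vulnerable*: resilience requires CV
strictly below cv_min, and "between the thresholds" is read inclusively.
"Not spliced in" is an exact zero of the mean PSI, which in integer counts
means no inclusion read in any retained sample.  Medians of even-sized
anchor bins are the mean of the two central values; an empty anchor bin or
inverted medians raise `ThresholdError` rather than guessing.

## Sequence features

Exon sequences are analysed on the mRNA sense strand (minus-strand exons
reverse-complemented first).  Motif densities count overlapping occurrences
individually — the most sensitive convention.  Splice-site strength is a
pluggable interface around the maximum-entropy context windows (23-mer
acceptor: 20 intronic + 3 exonic; 9-mer donor: 3 exonic + 6 intronic):
either a precomputed score table is ingested bit-exactly, or a PWM log-odds
scorer (uniform background) is used; re-deriving the maximum-entropy model
itself is out of scope.  Flank deltas subtract the exon's own score from the
downstream flank's acceptor score and the upstream flank's donor score, so
positive deltas mean the exon competes against stronger neighbours.  For the
0..5 above-mean profiles, the five inclusion-promoting features are PESE
density, GC fraction, exon length and the two splice-site scores; the five
repression-associated features are PESS density, the two flanking intron
lengths and the two flank deltas — the only split of the measured features
that yields a 0..5 range on both sides.  "Above the mean" is strict;
ties count as not-above.  The k-mer test is a pooled-proportion z-test
without continuity correction over all 4^k k-mers, Bonferroni-adjusted;
ambiguous-base windows are excluded from both counts and totals so counts
stay conserved.  Wilcoxon rank-sum comparisons use the exact null
distribution for tie-free samples up to a combined n of 30 and the normal
approximation beyond.

## Variant analyses

Edge distance counts exonic bases from the nearest boundary (1 = terminal
base); both the ESM curation rule ("first or last three bases") and the
SNP-density edge exclusion use the same edge_distance ≤ 3 test.  The
curation filters are idempotent and order-independent, and record one reason
per rule.  The 2×2 enrichment reports the cross-product odds ratio with a
Wald CI on the log scale (the CI method was an open choice; Wald is the
transparent default), the relative fold difference of row proportions, and
a two-sided Fisher exact p; a zero cell triggers the Haldane–Anscombe 0.5
correction, flagged in the result.  Created motifs must overlap the variant
base itself — occurrences elsewhere in the window are ignored, which makes
the result independent of window length.  Non-SNV records pass through
assignment and filtering but skip motif scanning unless an explicit mutant
window is supplied.  Consequence annotations (synonymous/missense/nonsense)
are consumed from the input table, not recomputed from codons.

## Synthetic cohort

The generator's defaults are the package's reference study conditions: 450
three-exon genes (one cassette exon each, so no junction row is shared
between simulated cassettes), 400 samples, negative-binomial depth with mean
200 and size 10.  Class mix: 44% resilient (π ~ U(0.9945, 0.9995),
concentration 5000), 30% vulnerable (π ~ U(0.90, 0.995), concentration 250),
16% alternative (π ~ U(0.35, 0.895), concentration 50), 5% zero-inclusion
and 5% low-coverage (depth mean 4, far below the 30-read sample filter).
The π ranges were chosen from the threshold geometry, not tuned: the
[99,99.5) anchor bin must contain both a low-CV population (the resilient
tail below PSI 99.5) and a higher-CV population (the vulnerable tail above
PSI 99) for its median to separate the classes, and likewise the [85,90)
bin receives the alternative tail above 85 whose CV exceeds the vulnerable
range starting at 90.  A narrower resilient range (e.g. a point mass at
π = 0.999) empties the [99,99.5) bin entirely and threshold derivation
correctly fails.  Beta-distributed per-sample inclusion with class-specific
concentration, on top of the Poisson sampling floor, reproduces the
qualitative CV-vs-PSI decline that the thresholds exploit.

For genes with more than three exons the junction rates generalize to a
product-of-inclusion model (an adjacent junction requires both its exons
present, a skip requires the neighbours present and the middle absent), and
the truth class is drawn per gene so a low-coverage gene cannot host a
well-covered exon.  What the generator does **not** emulate: realistic
sequence composition, correlated inclusion between neighbouring exons,
multi-exon skips, intron retention, tissue structure (unless injected via
the group partition), or mapping biases — so passing recovery tests show
the classifier's decision logic is sound under the stated noise model, not
that real GTEx data meet that model.

## Problem sizes and numerics

The default test and acceptance runs use the 450 × 400 cohort (seconds on
one core) and 200-sample Poisson draws at depth 10⁴ for the estimator
consistency check; these sizes give Monte-Carlo errors comfortably inside
the asserted bounds (SEM of mean PSI ≈ 0.0005 at depth 10⁴).  Degenerate
inputs are handled by flags rather than exceptions wherever a value can
legitimately be missing (below-coverage exons, off-contig splice-site
windows, empty MAF strata); exceptions are reserved for malformed inputs
and impossible derivations.  Known limitations: junction evidence cannot
distinguish NA from truly unexpressed genes; classification near the
thresholds is inherently unstable because the thresholds are sample
medians; and the genome-wide counts of the original analysis depend on the
exact junction snapshot used.
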