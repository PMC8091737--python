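# Methods

This note documents the models, parameter choices and numerical
conventions behind each pipeline stage, what the synthetic generators
do and do not emulate, and the known limitations.

## Phenotype-microarray scoring

Model. A PM well's redox signal is read as absorbance at 590 nm with a
750 nm reference; `A590 − A750` removes background light scattering.
The corrected values are averaged over all timepoints per well (a
single timepoint is valid — some assays permit only one read), then
linearly rescaled per plate × strain so the lowest well maps to score 0
and the highest to 100. Per-plate scaling absorbs growth-condition
differences between plate types; it also means scores are only
comparable within one plate × strain. Replicate plates are averaged on
the corrected-mean scale before normalization (configurable to
per-replicate calls). A plate whose wells all coincide cannot be
scaled; it receives all-zero scores and a warning.

Thresholding. The procedure assumes negative wells form a distribution
of non-zero scores near the bottom of the scale and utilizing wells a
second mode above it. The score density is estimated with a Gaussian
KDE on a 512-point grid over [0, 100], boundary-reflected at 0 and 100
so the grid density integrates to 1 (±1%). The cutoff is the density
minimum strictly between the two highest modes. The bimodality decision
requires (i) two local maxima, (ii) a deep valley (density below 0.5 ×
the lower of the two peaks), and (iii) at least 5% of wells (minimum 2)
on each side; otherwise the model falls back to a fixed cutoff,
default PM score 7. Calls are strict: positive ⇔ score > cutoff. The
A1 no-substrate control is flagged but still called, and the
utilization denominator includes all 96 wells (configurable).

Bandwidth. The default kernel SD is 3 score units, not a data-driven
rule. Scott/Silverman rules derive the bandwidth from the sample SD,
which in a strongly bimodal score distribution is dominated by the mode
separation (~14 score units here); the resulting oversmoothing shifts
the valley far into the gap and can misplace it above low-scoring
positive wells. A fixed kernel SD matched to the width of the
negative-well mode (the fixed cutoff 7 implies that mode lives below
~7) resolves both modes reliably; `bandwidth="silverman"` or
`"scott"` restores the classical rules, and any numeric kernel SD can
be set.

Proportion comparison. Utilization fractions of two strains are
compared with the pooled two-proportion chi-square statistic with Yates
continuity correction (default on; the corrected difference clamps at
zero), referred to χ²(1). This matches R's `prop.test` and is symmetric
in the two groups; the uncorrected statistic is never smaller than the
corrected one. With counts 30/96 vs 24/96 the corrected statistic is
0.64 (p = 0.42); with 55/96 vs 54/96 it clamps to 0 (p = 1).

## rDNA ITS–D1/D2 profiling

Primer search. Primer sequences ship as config defaults (canonical
published oligos: ITS1 `TCCGTAGGTGAACCTGCGG`, ITS4
`TCCTCCGCTTATTGATATGC`, NL1 `GCATATCAATAAGCGGAGGAAAAG`, NL4
`GGTCCGTGTTTCAAGACGG`) and are overridable. Matching is IUPAC-aware (a
degenerate code matches any base of its set, on either side) with a
per-primer mismatch budget, default 2; both strands are scanned and
reverse-strand hits reported in forward coordinates.

Extraction. The barcode segment is taken as forward primer ITS1 to
reverse primer NL4, spanning ITS1–5.8S–ITS2–D1/D2 as one ~880 bp unit
(ITS4/NL1 sites serve only as internal QC anchors). For every
correctly oriented same-contig primer pair spanning at most `max_len`
(default 2,000 bp) the segment inclusive of both primer sites is
emitted, reverse-complemented when on the minus strand so the forward
primer always comes first. Overlapping candidates are resolved
full-length-first, then shortest-span-first. A lone primer site whose
partner window runs off the contig edge yields a truncated copy
flagged not-full-length — rDNA arrays sit at contig ends in draft
assemblies, so partial terminal copies are expected. Internal
coordinates are 0-based half-open; emitted tables are 1-based inclusive
and say so.

Variability. Copies of one genome are aligned by center-star: the copy
minimizing the summed unit-cost edit distance to all others is the
center, every other copy is globally aligned to it (edlib) and pairwise
gaps are merged into shared columns. For the near-identical members of
an intragenomic repeat family this is effectively exact; column counts
are insensitive to the residual ambiguity of gap placement inside
homopolymer runs, though reported column *positions* can shift by a few
bases there. A column is variable iff it holds ≥ 2 distinct symbols,
the gap symbol included, so a single-base indel contributes exactly one
variable position; adjacent variable columns are grouped into runs.
Multi-base indels produce one variable position per column, which makes
counts on real data mildly aligner-sensitive.

Distances. The minimal inter-strain distance is the smallest
variation count (mismatch columns + gap columns of a unit-cost global
alignment, i.e. the Levenshtein distance) over all pairs of full-length
copies; partial copies are excluded, and a strain with no full-length
copy is an error rather than a silent underestimate. Distance 0 iff
two strains share an identical full-length copy.

Copy number. Collapsed repeats attract the reads of all true copies,
so expected copies = assembled copies × mean depth over copy bases /
median depth over all other bases. The median baseline resists other
repeat families; the formula is a documented package choice, exact for
a uniformly collapsed array under mean-one noise. Zero baseline is an
error. Positional QC flags copies within an `edge_window` (default
20 kb) of either contig edge.

## Genome partition

Exon = union of all exon intervals of all transcripts; gene spans are
merged before the intron/intergenic split, so overlapping genes are
counted once; intron = merged span minus exon; intergenic = contig
minus merged spans. Features other than exon inside mRNA (UTR-like
records) are ignored: exon is the coding-region basis of the summary.
GFF3 1-based inclusive coordinates are converted on load, hierarchy
errors (exon outside its transcript, features past the contig end,
dangling parents) are rejected, and contig lengths come from a FASTA or
from `##sequence-region` pragmas. The three classes tile each contig
exactly (tested base-for-base). Percentages are reported from exact
base counts, not from pre-rounded megabase totals — recomputing
percentages from rounded Mb entries can disagree in the second decimal
— and largest-remainder rounding makes the three percentages sum to
exactly 100.00. Length-class histograms use left-closed right-open
bins, consistent with the half-open interval convention; the default
edges are 0, 1 kb, 10 kb, 100 kb, ∞. The coding-density track reports
the exonic fraction per non-overlapping window (default 10 kb); the
final partial window uses its actual length.

## RBH classification

One transcript represents each gene: the transcript with homolog
support in the most genomes, ties broken by longest sequence, then
lexicographically smallest id. Pairwise scores are in-process
Smith–Waterman local alignments (BLOSUM62; a gap of length L costs
11 + L, the BLAST default cost model), making the artifact
self-contained and deterministic; tie best hits resolve to the
lexicographically smallest subject id, and a best hit requires a
positive score. An ortholog pair must be mutually best and pass a
score-ratio filter, score ≥ `min_ratio` × the query's self-score
(default 0.3; score-ratio methods make the cutoff scale-free across
protein lengths). Groups are single-linkage over RBH edges; a group
holding two genes of one genome is kept and flagged as an inparalog
collision. Singletons are stricter than pattern-exclusive genes: best
cross-genome score ratio below `singleton_cutoff` (default 0.3) in
*every* other genome — a gene whose partner was disrupted (frameshift
splitting an ORF) still scores a strong partial hit and is correctly
not a singleton. Genome-scale counts from real proteomes depend on the
search engine and annotation choices, so absolute counts from external
tools are not comparable targets; the pipeline's correctness is
instead established against planted family architectures and an
exhaustive all-pairs oracle.

## Synthetic data and what passing tests show

All generators draw from `numpy.random.default_rng(seed)` and are
byte-deterministic per seed; every truth bundle suffices to compute the
expected downstream result without re-running the generator.

* Plates: exactly `round(frac_positive × 96)` positive wells (default
  30/96), A1 forced negative; per-well signals from N(3, 1) for
  negatives and N(60, 10) for positives on the raw score scale
  (clipped at 0), decomposed into `A590 = signal + baseline`,
  `A750 = baseline` so the corrected mean recovers the signal exactly.
  Not emulated: kinetic growth curves, plate-edge effects, correlated
  replicate noise. Mode separation here is ~8 pooled SD; threshold
  recovery is reliable, but a positive drawn ≳3.5 SD below its mode can
  detach into the inter-mode gap and fall below the valley — a genuine
  ambiguity of valley thresholding, observed in roughly 1 in 300
  simulated plates.
* rDNA genomes: i.i.d. background at 49% GC (typical for these nuclear
  genomes) with planted primer-flanked copies near contig ends; each
  copy carries single-position edits (SNPs, single-base indels) at
  distinct master positions ≥ 5 bp apart and outside primer regions, so
  the expected variable-position count equals the number of planted
  edits exactly. Not emulated: tandem-array internal structure beyond
  spacing, chimeric copies, assembly gaps.
* Depth: per-base log-normal multiplicative noise with mean one
  (σ² = ln(1 + CV²)), copies scaled by a collapse factor; the
  estimator recovers the planted factor within ±5% at CV 0.1. Not
  emulated: GC-coverage bias, mapping artifacts at repeat boundaries.
* Annotations: non-overlapping genes with 1–4 exons and random
  intergenic gaps, or an explicit exon-layout plan for exact class
  percentages; truth totals are exact by construction.
* Protein families: one random master per family, copied into member
  genomes with independent per-residue substitutions (default rate
  0.05, length 150 aa); singletons are fresh random sequences. The
  planted architecture (5 genomes, 50 core families, 10 + 10
  clade-specific over a 2 + 3 clade split, 2 singletons per genome)
  mirrors a two-clade isolate panel. Random masters are mutually
  unrelated, which understates the paralog structure of real proteomes;
  recovery there is exact at these rates, real proteomes are harder.

Problem sizes in the tests and in `scripts/acceptance.py` (12 kb
contigs, 9 rDNA copies, 130 kb annotated genomes, ~60-protein
proteomes) are scaled-down study conditions chosen so the planted
structure matches the analyses' assumptions while the whole suite runs
in seconds.

## Numerical conventions and degenerate inputs

0-based half-open intervals internally everywhere; 1-based inclusive in
emitted FASTA/ GFF-style tables. Score normalization divides before
scaling so the extremes land on exactly 0.0 and 100.0. KDE grids have
512 points; density reflection keeps the [0, 100] integral at 1.
Degenerate cases error or fall back explicitly: empty score lists,
non-finite absorbances (named well), max = min plates (warning +
zeros), pooled proportions of 0 or 1 (statistic 0, p 1), single-copy
genomes (alignment refuses, advising a skip), zero depth baseline,
infeasible gene packing, empty protein sequences.

## Known limitations

The valley threshold has no confidence measure; borderline wells near
the cutoff flip with the bandwidth. Copy-number estimates assume the
depth track and assembly refer to the same sequence set and that rDNA
is the dominant collapsed family in its loci. The partition treats any
`exon` feature as coding and so counts annotated UTR exons as coding
bases where an annotation provides them. The RBH engine is quadratic in
proteome size; genome-scale proteomes are feasible but slow compared to
indexed search tools.
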