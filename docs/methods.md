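# Methods

`mitodiff` implements the comparative analysis of two circular plant
mitochondrial genomes — canonically a cytoplasmic-male-sterility (CMS)
line and its isonuclear maintainer, such as the wheat K-type pair
Ks3/Km3 — as a set of composable stages over a shared coordinate and
alignment core. This note documents the models, conventions, numerical
choices and limitations.

## Coordinate model

A genome is a single circular molecule (the "master circle", MC).
Internally all algorithms work with 0-based half-open slices on the
forward strand; externally everything is 1-based and end-inclusive, and a
reverse-oriented interval is printed with descending coordinates
(start > end), the convention of printed organelle repeat/ORF tables. An
interval may wrap the (arbitrary) origin, covering `start..L` then
`1..end`, with inclusive length `L − start + 1 + end`.

Circularity is handled uniformly by the doubling trick: searches run on
the genome concatenated to itself and results are canonicalized modulo
`L`. Two cleanup passes remove doubling artifacts: exact duplicate
matches at a +L shift, and fragment matches whose two sides are both
contained (≥ 90 %, circularly) in a longer match — the signature of an
origin-wrapping copy seen piecewise across the seam. This makes repeat
and ORF discovery invariant under rotation of the circle, which the test
suite asserts directly.

`N` bases are excluded from the GC denominator and never match in
alignment seeds.

## Similarity core (seed–chain–extend)

Repeat discovery and cross-genome homology share one primitive: local
similarity segments between two DNA strings, on both strands.

1. **Seeds.** Exact k-mer matches (default k = 31) are merged along
   diagonals into maximal exact runs. Every common substring ≥ k is
   recovered exactly by this merge.
2. **Chaining.** Runs on nearby diagonals (shift ≤ 50 bp) separated by
   ≤ 100 bp on both sequences are chained single-linkage into candidate
   regions. With a zero difference budget, chaining is skipped and only
   maximal exact runs survive — merging two neighbouring exact repeats
   into one gapped candidate would otherwise lose both.
3. **Refinement.** Each candidate is re-aligned end to end with unit-cost
   Needleman–Wunsch (edlib); mismatch and indel counts come from the
   CIGAR, and ends are extended by direct character comparison.

Detected boundaries are exact for exact copies and may err by up to the
seed length (k − 1 bp) at a mutated end; all recovery tolerances quote
this slack. An E-value in the Karlin–Altschul form
`E = K·m·n·exp(−λS)` (ungapped blastn-like constants λ = 1.28, K = 0.46,
score +1/−2/−2) is attached to homology segments as a reporting field and
gates them at the conventional 0.001 cutoff; it is deliberately a
screening statistic, not a calibrated significance.

## Repeat families

Pairwise self-matches (identity ≥ 90 % by default) are clustered into
families: match endpoints with ≥ 90 % reciprocal overlap are one copy,
and matches connect copies into a family graph whose components are the
families. Copies are listed in ascending start order; copy-1 defines the
forward orientation and the remaining strands follow by propagation along
match edges. Orientation labels follow the published convention: all
copies on one strand → DR; two opposite copies → IR; three or more mixed
copies → "IR/DR" when copy-2 opposes copy-1, else "DR/IR".

The family size is the gap-inclusive aligned length: the copy-1 length
plus the union of insertion columns observed in copy-vs-copy-1
alignments. This reproduces the published convention in which a family's
printed size exceeds its coordinate span by the deletion count. Identity
is `100 × (aligned − mismatch − indel) / aligned`, rounded half-up to two
decimals, which reproduces the printed two-copy identity values exactly
(e.g. 442 columns, 7 bp mismatch, 1 bp deletion → 98.19). The published
table contains two rows (R14, R18) whose printed identities are not
consistent with this formula — presumably a different multi-copy
averaging — and they are not forced.

Diff counts for families with more than two copies are measured pairwise
against copy-1 and summed, matching the "copy-1 N bp del." phrasing of
the reference table. Low-complexity filtering is off by default:
mitochondrial genomes are small and the E-value/identity gates suffice at
this scale.

## Homology and unique regions

Cross-genome segments use the same core with both genomes doubled.
Coverage is the union of segment footprints; unique ("line-specific")
regions are the maximal uncovered runs longer than 100 bp, labelled U1…
in coordinate order, with zero gap tolerance (runs separated by a single
covered base stay separate). Totals over unique regions count every
copy, following the published convention for multi-copy specific regions.
Near-identical regions (≥ 97 % identity over ≥ 90 % of the shorter
length, either orientation, via infix alignment) group single-linkage
into copy groups.

Region annotation searches each region against user-supplied local
reference sets (mitochondrial relatives, a chloroplast genome, nuclear
sequence, element libraries) at the 81 % identity floor used for mt–ct
homology. One class covering ≥ 90 % of the region assigns it; no hits →
novel; anything partial or conflicting → mixed, with sub-intervals
recorded per hit.

## SNP classification

Orthologous CDS pairs (maintainer first — its coordinates and bases are
the reference) are aligned globally with affine gaps (match +2, mismatch
−3, open −8, extend −1; Biopython PairwiseAligner). Each substitution
column yields a record with codon index `ceil(pos/3)`, amino acids under
the standard genetic code (three-letter names), S/N effect, and
transition/transversion class. All substitutions within one codon are
applied jointly when translating, so multi-hit codons report the same
codon-level amino-acid change on each row, as the reference table does.
Substitutions within 2 bp of a gap column are flagged low-confidence but
reported. The reference table maps two third-codon-position rows (atp4
249, rps2 837) to the following codon, inconsistent with the ceil rule
every other row follows; the ceil rule is implemented.

## ORF screening

ORFs are ATG-initiated, stop-terminated, with the stop codon included in
the interval and length (printed sizes are then exactly the coordinate
spans). Within a frame only the longest ORF per stop is reported. All
six frames are scanned; on circular genomes the doubled-sequence scan
finds origin-spanning ORFs in every wrap frame. Identical-sequence ORFs
at several loci merge into one multi-copy record.

Uniqueness classes mirror the published categories. Thresholds the
publication leaves unstated are package defaults, chosen once and
configurable: "not-unique" needs one comparator segment covering ≥ 95 %
of the ORF; "two-discrete-segments" (the chimeric signature) needs two
or more comparator hits each covering ≥ 20 % of the ORF, jointly ≥ 80 %,
covering distinct ORF parts, with comparator loci > 1 kb apart or
discordant in order/orientation; chloroplast-derived requires ct coverage
≥ 80 % exceeding comparator coverage. CMS-candidate geometry flags use a
2 kb upstream window for "vicinity of a gene" (the value is a convention,
not a published number), ≥ 1 bp overlap for "overlaps gene", and
intersection with a unique region.

## Multipartite structure

Every same-strand copy pair of a family ≥ 500 bp implies one subgenomic
circle pair with lengths `d` and `L − d` (`d` = circular distance between
copy starts); every opposite-strand pair implies one isomer of unchanged
length. Only first-order events are enumerated by default. Sequence
realization places the crossover at the repeat midpoint; for identical
copies the products are independent of that choice up to rotation (tested
directly). Crossovers between copies below 99 % identity are refused
unless forced.

The reduced ("actual") genome size removes one copy of each family
≥ 500 bp after dropping families nested inside copies of larger retained
families — without the deduplication, nested families would be removed
twice. On the bundled reference repeat table the retained set is R1–R5
plus R9 and the arithmetic gives 374,407 bp, inside the 370–410 kb window
around the published ~400 kb estimate; the exact inclusion rule behind
the published figure is not stated, so the value is documented rather
than forced.

## Synteny

Gene orders are circular words of gene symbols sorted by start coordinate
(tRNA genes excluded by default; multi-segment genes sit at their first
segment; duplicate copies carry suffixes but match by base symbol).
Shared clusters are maximal common contiguous runs of the two circular
words, allowing reversal with an orientation flip; singletons are
excluded, and each gene copy is assignable to one cluster only (greedy,
longest first, ties by coordinate). Strand agreement within a cluster is
recorded but not required — adjacency is the criterion.

## Synthetic data

The generator emulates the study design at desk scale so every stage has
planted ground truth. The ancestor (maintainer analog) is a 50 kb circle
at 44.3 % GC with 20 protein-coding genes (valid ATG…stop ORFs drawn
from the standard plant mitochondrial gene complement), three rRNA and
two tRNA features, and random intergenic sequence. A 10 kb random circle
stands in for the chloroplast donor. The variant (CMS analog) applies a
declarative edit plan in a fixed canonical order — gene deletions, CDS
substitutions, inversions, then insertions (fresh random sequence,
chloroplast fragments, self-copies forming repeat families, and chimeric
ORFs fused from two donor fragments) — and lifts every truth coordinate
through each length-changing edit.

The study-profile plan mirrors the published category structure at
reduced scale: eight unique regions (two chloroplast-sourced; one
sequence planted at three loci as a copy group), five repeat families
(5 kb DR, 2 kb IR, 600 bp three-copy DR with mismatches, 300 bp IR,
150 bp DR), twelve CDS substitutions (four synonymous) in five genes,
one deleted gene (rpl5, the classic maintainer-only gene), one two-gene
inversion, and three chimeric ORFs whose donors are > 5 kb apart.
Chimera donors are resampled until the stop-removal edits needed to
ORF-ify the fusion are ≥ 40 bp apart, so each donor fragment retains
clean seed windows and stays detectable by homology; an in-frame stop is
planted immediately ahead of the chimera ATG so the reported ORF start is
exact. All randomness flows from one explicit seed through spawned NumPy
generator streams; identical seeds give byte-identical FASTA/GFF3/truth.

What the generator does not emulate: real wheat base composition beyond
GC%, RNA editing, sequencing error, nuclear insertions, and the sheer
repeat density of a 647 kb genome. Passing recovery tests therefore
demonstrates correctness of the algorithms under clean planted structure,
not performance on noisy real assemblies.

## Problem sizes and rounding

Desk-scale defaults keep every stage fast: oracle-equivalence tests run
on ≤ 5 kb genomes (repeats), ≤ 10 kb (ORFs) and ≤ 40 symbols (synteny);
the full synthetic pipeline runs on the ~50 kb profile pair in a few
seconds. All printed percentages round half-up (never banker's), with
two decimals for genome-fraction censuses, one for coverage, two for
repeat identity (an integral 100 prints bare) — the mixed style of the
reference tables, configurable per call.

## Known limitations

- Segment *counts* from homology search are aligner-specific (they depend
  on chaining and merging behavior) and are not comparable across tools;
  coverage and unique-region coordinates are the stable quantities.
- Strand propagation inside a repeat family assumes a consistent
  orientation graph; a pathological palindromic family could admit two
  labelings, in which case the first assignment wins.
- `apply_recombination` requires both copies not to span the origin;
  rotate the genome first (rotation is lossless).
- The E-value is a screening heuristic; gapped Karlin–Altschul parameters
  are not estimated.
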