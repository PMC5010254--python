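# Methods

## The analysis model

The pipeline targets single-gene mitochondrial minicircles sequenced by
an outward-facing PCR design: the protein gene is sequenced internally,
then two primers pointing away from each other within the gene amplify
the gene-external arc.  Amplification succeeds only if the template is
circular (or the gene tandemly repeated), so an amplicon whose two ends
each overlap one end-region of the gene is direct evidence of
circularity.  `merge_amplicon` performs the join in silico: it requires
both junction overlaps (default minimum 20 bp, matching typical primer
lengths of 21–22 bp, with 0 mismatches by default), refuses ambiguous
placements rather than guessing, and returns the circle rotated so the
gene starts at position 0.  All coordinates are 0-based half-open;
features crossing the origin use wrap-aware intervals, and gene-at-origin
rotation makes codon-position arithmetic trivial
(`codon position = ((pos − frame) mod 3) + 1`).

Heteroplasmy is measured from clone sets.  Instead of a progressive
multiple alignment, each clone is aligned independently to the reference
circle and projected onto reference coordinates.  For clone sets that are
>98% identical to the reference this is equivalent to an MSA for
site-calling purposes, and it is exactly testable: the affine-gap global
aligner (Gotoh; match +2, mismatch −1, gap open −4, gap extend −1, a gap
of length *k* costing `open + (k−1)·extend`) is verified against a
brute-force enumeration of the entire alignment space on small inputs,
and its traceback tie order (diagonal, then vertical, then horizontal) is
fixed so results are bit-reproducible.  Clones are placed on a doubled
linearization of the circle so a clone spanning the origin maps to one
contiguous window; clones aligning below 60% identity are excluded with a
warning.

A heteroplasmic site is a reference column where at least two distinct
bases from {A,C,G,T} occur among clones.  Gaps and IUPAC ambiguity codes
neither create nor join sites: an uncertain base call is never evidence
of variation.  Insertions relative to the reference are stored as side
records rather than matrix columns — substitution sites and indel events
are tallied separately, which is how such data are conventionally
reported.  The headline statistic,

    rate = sites / (n_clones × surveyed bp),

uses as denominator only reference positions covered by *every* clone,
so individuals sequenced to different extents remain comparable.
Reported values are rounded half-up: 4 decimals for the rate, 1 decimal
for sites per clone and expected polymerase errors, integer percent for
identity.  Raw unrounded values are always emitted alongside.

Sites in the gene/tRNA overlap are classified as region `overlap` and
included in **both** the coding tallies (and the rate denominator) and
the tRNA tally; the report carries a flag noting this double counting,
since the attribution of overlap bases is a reporting convention rather
than a biological fact.

Frameshifts are called per clone from the net indel length within the
gene (flagged iff not divisible by 3); the truncated-protein length is
the number of codons before the first stop in the shifted frame, under
the invertebrate mitochondrial code (NCBI table 5: ATA→M, TGA→W,
AGA/AGG→S).  Replacement substitutions are amino-acid differences of
non-frameshifted clones against the translated reference; a substitution
is *unique* when its (position, amino acid) pair occurs in exactly one
clone.

Start classification recognises three patterns.  A gene whose first
codon is ATG/ATA with a clean frame is a standard start.  A gene
beginning `ATGT` whose offset-1 frame is internally stop-free while the
offset-0 frame is not is reported as a 4-bp tetranucleotide start region
(the mRNA-editing hypothesis), with the cysteine `TGT` reading — the
same offset-1 frame starting one base in — always listed as the
alternative interpretation.  The ATGT check precedes the standard-ATG
check deliberately: `ATGT…` genes begin with a literal ATG codon, and
only the stop-free-frame criterion distinguishes the two readings.

Inverted repeats are found by local alignment of the sequence against
its own reverse complement (match +3, mismatch −4, linear gap penalty 5
per gap position, minimum reported score 15, minimum arm 3 bp).  The DP
is restricted to the triangle `i + j ≤ n − 2`, which simultaneously
forces the two arms to be disjoint and ordered and collapses the two
mirror-image representations of every repeat to one.  A perfect
palindromic arm pair of arm length *a* scores 3*a*, so the detection
threshold is exactly *a* ≥ 5.  Hits are selected greedily by descending
score (ties: arm-1 start, then region span) with arm-overlap
suppression.  Circular input is searched on a doubled linearization with
duplicate suppression.  Because the figure usually quoted for such
repeats is the size of the whole "region", hits report both
`region_span` (arm 1 start through arm 2 end) and the arm intervals.

Cross-species comparison aligns homologous regions globally and reports
percent identity with gap columns counted as mismatches, plus maximal
runs of gap-free identical columns (default minimum 10 bp, which
captures conserved blocks of the 10–23 bp scale without drowning in
chance 6-mers).  Noncoding regions between species are aligned with a
permissive preset (match +1, mismatch −1, open −2, extend −1) and the
resulting identity is treated as exploratory: gap-heavy alignments of
dissimilar noncoding DNA are aligner-dependent.  A block is *universal*
when every clone of both individuals matches the reference across it;
blocks partly outside the cloned region come back undetermined rather
than asserted.

Clone trees use uncorrected p-distances (differing sites over columns
where both clones have an unambiguous base) — clone divergence is far
from saturation, so a substitution model would only add parameters — and
Saitou–Nei neighbor joining with a deterministic tie-break (smallest
index pair) and negative branch lengths clamped to zero with a warning.
The unrooted tree is serialised with a trifurcating root; on additive
matrices the output reproduces the generating tree's path-length matrix
exactly.

## The synthetic-data generator

`simulate` builds circles with the organisation the pipeline is designed
around.  Two presets encode the two study organisations:

| parameter | `G_AUREI` | `T_MINOR` |
|---|---|---|
| gene | 1,536 bp, ATG start | 1,537 bp, ATGT start region |
| tRNA / overlap with gene start | 68 / 6 bp | 65 / 4 bp |
| noncoding | 316 bp | 307 bp |
| circle | 1,914 bp | 1,905 bp |
| planted repeat (arm/spacer/region) | 30/31/91 bp | 14/10/38 bp |
| clones | 26 | 12 |
| coding substitution rate (per site per clone) | 0.0017 | 0.0014 |
| tRNA substitution rate | 0.0011 | 0.0038 |

The gene body is stop-free random codons with a terminal stop; for the
ATGT preset the generator verifies that the offset-0 frame contains an
internal stop (true for essentially every random body), so the start is
genuinely atypical.  The noncoding region carries two conserved motifs
(19 bp and 11 bp, the first placed a fixed distance after the stop
codon, the second 15 bp further downstream) and one inverted repeat
placed mid-region.  Clones cover the amplified arc: 591 coding bp (491
before the gene end, 100 after the origin, including the 6-bp tRNA
overlap), the full noncoding region and the tRNA core — about 970 bp,
matching the scale of real cloned products.

Substitutions are i.i.d. per site per clone at region-specific rates; a
recombination process is deliberately not modelled (for these
chromosomes it is a hypothesis, not a measured mechanism), so the
generator cannot produce the block-wise allele sharing recombination
would create.  The noncoding per-site rate (default 0.01) is a free
parameter chosen so noncoding variation clearly dominates coding
variation, as observed for such circles; no empirical per-site noncoding
rate is available to pin it.  Noncoding indel counts are Poisson per
clone (mean 2) with lengths uniform on 1–8 bp, yielding clone noncoding
lengths spread over roughly ±15 bp — the scale of real clone length
heteroplasmy.  A configured number of clones receives a single 1-bp
coding indel (a frameshift).

Three deliberate regularities keep the ground truth well-defined:

* **Planted motifs and repeat arms are excluded from clone mutation**, so
  universality of conserved blocks is exact by construction.
* **Repeat arms are buffered by 6-bp poly-A guards and a poly-A spacer.**
  Adenines cannot pair with each other under reverse-complement
  matching, so the planted arms cannot extend by chance into their
  surroundings and the detector recovers them with exact coordinates and
  score 3 × arm length.
* **Indels are planted only in the noncoding interior** (at least
  `max indel length + 2` bp from a region boundary): an indel flush
  against the gene boundary cannot be attributed to either side by any
  alignment, so events there would make frameshift ground truth
  ill-defined.  Real data carry no such guarantee — a boundary indel in
  real clones would be attributed by the aligner's leftmost-placement
  convention.

For two-species comparisons, `generate_species_pair` derives species B's
gene from species A's by codon-aware divergence: each codon is replaced
by a random different-amino-acid codon with probability 0.15 or a
synonymous codon with probability 0.38.  This reproduces the typical
mitochondrial pattern in which amino-acid identity (~85%) far exceeds
nucleotide identity (~74%).  The conserved motifs are planted identically
in both species inside otherwise independently drawn noncoding regions,
with the single base flanking each motif fixed to different values in
the two species so that identical blocks end exactly at the planted
boundaries.  All randomness flows from one seeded NumPy generator; a
given seed reproduces byte-identical FASTA output.

What passing tests on this generator do **not** show about real data:
alignment-ambiguity effects at region boundaries and inside repeats
(deliberately excluded, see above), PCR chimera formation and
recombination-driven heteroplasmy (not modelled), and base-composition
or codon-usage realism (uniform random background).  The pipeline's
correctness claims are therefore about its algorithms under the stated
generative model, checked against independent oracles (exhaustive
alignment enumeration, a naive nested-loop repeat DP, generating trees
for neighbor joining, and planted ground truth end to end).

## Problem sizes and numerical choices

The test suite and the acceptance script run at the scale of the study
itself: 1.9-kb circles, 12–30 clones of ~970 bp, 20 seeded replicates
for the rate-recovery check (30 clones, 591 coding bp, per-site rate
0.002, with the mean of called coding sites required to fall inside the
95% interval of the corresponding binomial mean).  Exhaustive oracles
run at reduced sizes where enumeration is tractable: all pairs of four
seeded 8-mers for the aligner (the alignment space of an 8-mer pair
already exceeds 2.6 × 10⁵ alignments) and fifty seeded 60–80-mers for
the repeat detector.

Degenerate inputs are defined rather than left to chance: empty
sequences are rejected at construction; a wrap requested on a linear
sequence is a topology error; an amplicon with no junction overlap is
"no circularity evidence" and multiple placements are an ambiguity
error; a repeat search on a sequence shorter than two minimum arms warns
and returns nothing; p-distance between rows with no comparable columns
is an error rather than zero.  Ties are never resolved by hash order or
randomness: alignment traceback, repeat-hit ranking and the
neighbor-joining pair choice all carry explicit deterministic tie-break
rules, and two runs on identical inputs produce byte-identical output
bundles.
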