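# Methods

## Coordinate model

Annotations are 1-based, fully closed intervals stored with `start <= end`
and an explicit strand flag (H/L); the 5′→3′ reading of an L-strand gene is
recovered on output by writing its span high-to-low.  The signed 3′ spacer
after feature *i* (features in ascending-start order) is
`start(i+1) − end(i) − 1`, the last one wrapping through the origin as
`start(0) + L − end(last) − 1`.  Because spacers are derived from the same
coordinates, Σ(size + spacer) telescopes to the genome length by identity —
that sum is the circle-recovery check.  The genuinely falsifiable check is
the same sum over the *published* size and spacer columns, which the
fixtures carry as reference metadata: for *N.* cf. *mirabilis* it exceeds
the genome length by 10 because the published atp6 size (700) disagrees
with its own coordinates (11443–12132 → 690 nt); both flanking spacers (40
after atp8, 5 before trnC) confirm the coordinates, so we treat the size as
a 10-nt typo.  Every other printed size and spacer across both genomes (76
rows) reproduces exactly.

The AT-rich region is stored as a noncoding-class feature so the closure
accounting covers the full circle; smaller unassigned gaps remain implicit
in the spacers.  Overlapping features are legal (both genomes have them);
only duplicate names are rejected.  One source caveat: the text paragraph
describing the non-coding regions swaps the two species relative to the
annotation table (it attributes the 838-nt nad3–trnS2 block to the wrong
genome); the package follows the table.

## Strand skews and rounding

AT-skew = (A − T)/(A + T), GC-skew = (G − C)/(G + C), computed on the
strand carrying most genes (the sequence as deposited).  Percentages print
to 1 decimal, skews to 3, rounding half away from zero; internal math is
full precision.  IUPAC ambiguity codes are excluded from all denominators
and reported as a separate count (whether the published percentages did the
same is unstated; the choice is echoed in output metadata).  Recomputing the
twelve published skews from the published percentages reproduces ten
exactly; the other two (GC-skew 0.178 for *Cephalothrix* sp., where the
percentages give 0.177, and 0.322 for *P.* cf. *peregrina*, where they give
0.327) cannot be obtained from their own printed percentages at any
rounding and were presumably computed from unrounded counts.  The sliding
window profile defaults to a 100-bp window with step 1 (the source states
only the window), optionally wrapping the circle.

## Codon usage

NCBI translation table 5 (invertebrate mitochondrial): 62 sense codons,
stops TAA/TAG only.  A CDS whose length is ≡1 or ≡2 (mod 3) carries an
incomplete stop ("T"/"TA"); extraction drops the trailing fragment and a
terminal full stop, and any internal in-frame stop is an error naming the
codon.  CDspT normalizes synonymous-family counts to codons per thousand
non-stop codons.  RSCU divides a codon's count by its family's mean; the
default family structure splits Leu and Ser by anticodon (Leu1=CUN,
Leu2=UUR, Ser1=UCN, Ser2=AGN) to match the source's family labels, with the
merged amino-acid grouping available as `family_mode="merged"` (that is the
default of some desktop packages, so the choice is echoed in metadata).
Codons absent from a family that is otherwise used score RSCU 0.0; a family
never used is undefined (None), a distinct state.

## %INUC and compensatory changes

%INUC counts alignment columns in which every row carries the same non-gap
symbol, printed to 2 decimals (half away from zero; 21/72 → 29.17).  A
column containing any gap is never identical — the strictest reading of an
unstated convention, echoed in metadata; the original alignments are not
recoverable without the deposited accessions, so their gap policy is
unknowable.  All 22 published (length, identical) pairs reproduce their
printed percentages under this rule.  Conservation bands follow the
published grouping: >50, 40 ≤ x ≤ 50 (both ends closed, so exactly 50.00
falls here), 30 < x < 40, ≤ 30.

Stem substitutions are classified against a designated reference row over a
user-supplied pairing mask (dot-bracket or explicit column pairs — the
package does not fold tRNAs): identical; cbc when both positions changed
and both pairs are canonical; hemi-cbc when exactly one changed and both
canonical; mismatch_introduced when a canonical reference pair becomes
non-canonical; other when the reference itself is non-canonical.  The
canonical set includes the G·T/G·U wobble, without which the source's own
hemi-cbc example (T-A vs T-G) would not count.

## Repeat scanners

Tandem repeats: at each start position, every period p in
[min_period, max_period] is extended maximally (`s[j] == s[j−p]`); among
periods reaching `min_copies` full copies the longest total span wins, with
the smallest period breaking ties (so a unit never reports as its own
doubling); scanning is leftmost-first and non-overlapping, and a trailing
partial copy is included in the span.  The longest-span rule (rather than
smallest-period-first) is what keeps a long planted unit from being eaten
by the 2-bp micro-repeats inside it.  Defaults min_period 2, max_period 60,
min_copies 3 cover the published motifs (periods 5–52, copies 2–10); the
two-copy motif needs `min_copies=2`, exposed as a parameter.  Homopolymers
are maximal single-base runs ≥ 6 nt by default.  Hairpins are pure
inverted-repeat matches (arm2 = reverse complement of arm1 up to a mismatch
budget; stems never end on a mismatch; loop length 3–30 by default) —
string matching, not thermodynamic folding, so the published secondary-
structure drawings are out of scope.  Circular scanning doubles the
sequence and de-duplicates hits modulo the origin.  Every hit is
self-validating: its span re-read from the sequence equals unit × copies
(+ partial).  All three scanners are tested for exact agreement with
independent brute-force re-implementations on hundreds of seeded random
sequences.

## Gene-order measures

Gene orders are signed circular permutations (sign = strand), extracted
from annotations in ascending-start order with noncoding features dropped
and, for the non-tRNA set, tRNAs dropped (leaving 13 protein + 2 rRNA
genes).  Equality is up to rotation and reflection-with-negation.  Pairs
with unequal gene sets are first restricted to the shared genes, preserving
relative order.

**Common intervals** (a similarity: gene sets contiguous in both circles,
signs ignored).  Published counting conventions for circular genomes vary;
ours is pinned by calibration against the published pairwise matrix.  Both
circles are rotated so a shared anchor gene is first, gene sets of size
2..n−2 contiguous in both linearizations are counted, and the count is
reported doubled (the two readings of the circle).  A self-comparison then
scores n(n−1) − 6, reproducing every published diagonal (1326, 1254, 864,
204 for n = 37, 36, 30, 15).  The count is rotation-invariant but depends
on the anchor (intervals spanning the cut junction differ); the anchors
that reproduce all seven checkable published values are cox2 for the
all-genes set (1124 between the two nemertean patterns; 20 and 20 against
the bilaterian ground pattern) and atp6 for the non-tRNA set (178; 44 and
52).  These are the defaults keyed to the gene-set tag, overridable and
echoed in output metadata.  No single anchor reproduces both gene sets'
published values, consistent with the original tool having been run
separately per gene set with different input rotations; the residual
ambiguity is documented rather than resolved.

**Breakpoints.**  An adjacency (a, b) of one circle is conserved in the
other iff it contains (a, b) or (−b, −a); the distance is the number of
non-conserved adjacencies among the n circular junctions (no linear-end
correction — the genomes are circles).

**Reversal distance.**  Exact Hannenhalli–Pevzner on the signed circular
orders: fix an anchor gene (rotate to front, orient positive, reflecting
the circle if needed), relabel by the second order, and solve the linear
(n−1)-element problem as d = b − c + h + f on the framed breakpoint graph
(b black edges, c cycles, h hurdles, f fortress).  A gray edge is oriented
iff its endpoint positions share parity; components are connected sets of
interleaving nontrivial cycles; hurdles are unoriented components occupying
a single run in the circular compression of component labels along the
frame; a fortress requires an odd number of hurdles, all superhurdles
(removal of the hurdle promotes a protected component to hurdle).  The
implementation matches a breadth-first-search oracle over the complete
reversal graph for every signed permutation up to 6 elements (the unit and
acceptance suites run this exhaustively); fortresses are too large to reach
by BFS and rely on the classical characterization.  The distance is
independent of the anchor choice (asserted in tests).  The bilaterian
ground pattern is a reconstruction of the classic ancestral (human-like)
arrangement — the original figure is a drawing — and is validated by the
published distances it reproduces: 31 breakpoints to both nemertean
patterns and 28 reversals to the hoplonemertean one.  From the published
coordinates the heteronemertean pattern is 29 reversals from the ground
pattern, not the published 28; a variant placing trnW before trnS2
(plausibly the original figure's heteronemertean drawing) gives 28 and 31,
so the source's figure likely differs from its own annotation table by one
tRNA placement there.  We follow the coordinates.

## Synthetic data

The generator lays out 37 genes in the hoplonemertean reference arrangement
with the coordinate-derived sizes, zero spacers, everything on H except
trnP/trnT, and an AT-rich block absorbing the remaining length (840 nt at
the default 15 365-nt genome, since the real spacers are folded into it).
Background and structural RNA sequence is i.i.d. at the planted base
composition (defaults: the published whole-genome percentages A 21.8 /
T 48.5 / C 10.5 / G 19.2); CDSs are ATG + codons sampled from a codon
distribution (default: product of base frequencies over sense codons) +
full or incomplete stop as the gene length dictates; an
`incomplete_stop_fraction` rewires stops to the "T" form.  The AT-rich
block targets 81.5% A+T and carries the three published repeat motifs, two
homopolymer tracts and one hairpin as planted ground truth, each wrapped in
3-nt guard bases chosen so no repeat period or stem can extend across a
plant boundary (keeping planted coordinates exact for the recovery tests).
One integer seed drives named PCG64 substreams (background, cds, atrich,
scramble, stops), so identical configs are byte-identical and adding a
component never perturbs the others.

What the generator does *not* emulate: real codon autocorrelation and
amino-acid composition, tRNA secondary structure, non-random spacer
placement, and mutation along a phylogeny.  Passing recovery tests
therefore demonstrates that the analytics recover what was planted under
i.i.d. noise at realistic sizes — not that they would resolve biological
signal in new data.

Tolerances in the recovery suites come from the multinomial sampling
oracle: a base at proportion p in an n-nt i.i.d. region has standard error
100·sqrt(p(1−p)/n) percentage points (≈0.33 pp for A at the full genome
size, ≈1.5 pp for AT% of a 702-nt block), and property tests bound errors
at 3σ; fixed-seed checks at the study conditions additionally hold the
half-point band used in the acceptance suite.  Repeat, homopolymer and
hairpin recovery is exact by construction.

## Determinism and provenance

All randomness flows from explicit integer seeds; pipeline reruns are
byte-identical (tested).  Every report bundle echoes the decisions that
could differ between implementations: the %INUC gap policy, the RSCU family
mode, and the common-interval anchors.

## Known limitations

- Quantities requiring the deposited sequences (whole-genome composition,
  the ~3700-codon totals, published repeat copy numbers, the published
  CDspT aggregate) are demonstrated on synthetic data only.
- The common-interval anchor convention is a calibration, not a derivation;
  other conventions reproduce the diagonals but not the published
  off-diagonals (or vice versa).
- Fortress detection in the reversal distance follows the classical
  characterization but is beyond the exhaustive oracle's reach; mitogenome
  comparisons do not produce fortresses.
- The hairpin scanner reports all maximal stems; in AT-rich sequence this
  is deliberately permissive (hundreds of short stems), and downstream
  filtering by stem length is expected.
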