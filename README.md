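# mitocomp

Comparative analytics for circular mitochondrial genomes, built around the
two newly sequenced nemertean (ribbon worm) mitogenomes of *Nectonemertes*
cf. *mirabilis* (15 365 bp) and *Zygeupolia rubens* (15 513 bp) and their
comparison with four other nemerteans and the putative bilaterian ancestral
gene arrangement.  It is aimed at researchers doing mitogenome descriptions
and gene-order phylogenetics who want every number in such a paper — gene
sizes and spacers, strand skews, codon usage, tRNA conservation,
control-region repeats, rearrangement distances — recomputable from the
annotation tables and sequences, offline and under test.

## What it computes

**Annotation analytics** (`mitocomp.annotation`).  A circular gene map of
1-based closed intervals with strand flags.  Gene size = end − start + 1;
the signed 3′ spacer after a feature is start(next) − end − 1 (negative =
overlap), wrapping through the origin; circular closure requires
Σ(size + spacer) to telescope to the genome length.

**Strand asymmetry** (`mitocomp.composition`).

    AT-skew = (A − T) / (A + T)        GC-skew = (G − C) / (G + C)

computed on the coding strand, with percentages to 1 decimal and skews to 3
(half-away-from-zero).  Sliding-window A/T profiles use a 100-bp window.

**Codon usage** (`mitocomp.codon_usage`).  Counts over the 62 sense codons
of the invertebrate mitochondrial code (NCBI table 5; TGA = Trp, AGR = Ser,
ATA = Met), codons-per-thousand (CDspT) by synonymous family, and relative
synonymous codon usage

    RSCU(c) = count(c) / (family_total / |family|)

with the mitochondrial anticodon split (Leu1 = CUN, Leu2 = UUR, Ser1 = UCN,
Ser2 = AGN) as the default family grouping.  Incomplete stops ("T"/"TA",
completed by polyadenylation) and full stops are excluded from all counts.

**tRNA conservation** (`mitocomp.alignment`).  %INUC = percent of alignment
columns where all sequences carry the same non-gap nucleotide, and
classification of stem substitutions as fully compensatory base changes
(cbc, e.g. G-C → A-T), hemi-cbc (e.g. T-A → T-G; G·T wobble counts as a
pair), introduced mismatches, or other.

**Control-region repeats** (`mitocomp.noncoding`).  Exact scanners for
tandem repeats (leftmost-longest, smallest period on ties), homopolymer
tracts, and inverted-repeat hairpins with a mismatch budget.

**Gene-order rearrangement** (`mitocomp.gene_order`).  Signed circular gene
orders compared by: common intervals (gene sets contiguous in both circles;
counted under an anchored-linearization convention calibrated so that a
self-comparison of n genes scores n(n−1) − 6), signed breakpoint distance,
and exact Hannenhalli–Pevzner reversal distance (breakpoint-graph cycles,
hurdles and fortress, after the standard circular→linear reduction),
validated against a breadth-first-search oracle over the full reversal
graph.

**Synthetic genomes** (`mitocomp.synthetic`).  A ground-truth generator —
37 genes in the hoplonemertean arrangement, trnP/trnT on the L strand,
AT-rich block with planted repeat motifs, codon-sampled CDSs, gene orders
scrambled by k known reversals — so every stage is testable without
downloading the deposited accessions (HQ997772, HQ997773).

## Worked example

```python
from mitocomp.fixtures import table_fixture_loader
from mitocomp.annotation import closure_check, overlap_pairs
from mitocomp.gene_order import order_from_annotation, common_intervals, \
    breakpoint_distance, reversal_distance, restrict_to_shared

mir = table_fixture_loader("nmirabilis_table1")
rub = table_fixture_loader("zrubens_table1")

closure_check(mir)["sum_sizes_plus_spacers"]   # 15365 — the circle closes
overlap_pairs(rub)[0]                          # ('nad6', 'cob', 8)

om, orb = order_from_annotation(mir), order_from_annotation(rub)
common_intervals(om, orb)                      # 1124 (all 37 genes)
common_intervals(om, om)                       # 1326 = 37*36 - 6, the maximum

gp = table_fixture_loader("gene_orders")["bilaterian_ground_pattern"]
a, g = restrict_to_shared(om, gp)
breakpoint_distance(a, g)                      # 31
reversal_distance(a, g)                        # 28
```

The two genomes' orders differ only by a translocation of the trnS2/nad2
block (3 breakpoints, reversal distance 3); both sit 31 breakpoints from
the bilaterian ground pattern.

The numbered scripts under `analysis/` run the full study: annotation-table
recomputation, skews, codon usage, tRNA conservation, repeat scans, and the
pairwise distance matrices.  Each writes its tables to `results/`, e.g.

```
python analysis/06_gene_order_distances.py
```

A `mitocomp` CLI exposes the same stages (`annot-stats`, `composition`,
`codon-usage`, `order-dist`, `inuc`, `repeats`, `simulate`, `report`).

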