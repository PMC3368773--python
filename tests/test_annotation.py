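import pytest
from hypothesis import given, settings, strategies as st

from mitocomp.annotation import (
    AnnotationError,
    GeneFeature,
    MitogenomeAnnotation,
    closure_check,
    gene_size,
    normalize_gene_name,
    overlap_pairs,
    parse_annotation_tsv,
    spacer_after,
    write_annotation_tsv,
)

MINI = """#genome_id=mini
#length=400
#circular=true
name\tspan
g1\t1-100
g2\t150-101
g3\t141-390
"""


class TestParsing:
    def test_l_strand_span_is_normalized(self):
        ann = parse_annotation_tsv(MINI)
        g2 = ann.feature("g2")
        assert (g2.start, g2.end, g2.strand, g2.size) == (101, 150, "L", 50)

    def test_h_strand_and_single_base_span(self):
        ann = parse_annotation_tsv("#genome_id=x\n#length=9\nname\tspan\na\t5-5\n")
        f = ann.feature("a")
        assert (f.strand, f.size) == ("H", 1)

    @pytest.mark.parametrize(
        "row, message",
        [
            ("a\t1-5\na\t6-9", "duplicate"),
            ("a\t1-20", "outside"),
            ("a\t1-5\t\t9", "size column"),
        ],
    )
    def test_rejects_bad_rows(self, row, message):
        text = "#genome_id=x\n#length=10\nname\tspan\tclass\tsize\n" + row + "\n"
        with pytest.raises(AnnotationError, match=message):
            parse_annotation_tsv(text)

    def test_missing_header_rejected(self):
        with pytest.raises(AnnotationError, match="header"):
            parse_annotation_tsv("name\tspan\na\t1-5\n")

    def test_trnp_row_from_published_table(self, mirabilis):
        f = mirabilis.feature("trnP")
        assert (f.name, f.strand, f.start, f.end, f.size) == ("trnP", "L", 63, 125, 63)

    def test_round_trip_is_field_identical(self, mirabilis, rubens):
        for ann in (mirabilis, rubens):
            again = parse_annotation_tsv(write_annotation_tsv(ann))
            assert [
                (f.name, f.gene_class, f.strand, f.start, f.end) for f in again.features
            ] == [(f.name, f.gene_class, f.strand, f.start, f.end) for f in ann.features]
            assert again.genome_length == ann.genome_length


class TestDerivedQuantities:
    def test_gene_sizes_match_published_examples(self, mirabilis, rubens):
        assert gene_size(rubens.feature("nad5")) == 1732
        assert gene_size(mirabilis.feature("trnH")) == 60
        assert gene_size(mirabilis.feature("nad4L")) == 303

    def test_overlap_spacer(self, mirabilis):
        nad4l = mirabilis.feature("nad4L")
        nad4 = mirabilis.feature("nad4")
        assert spacer_after(nad4l, nad4, mirabilis.genome_length) == -7

    def test_wraparound_spacer(self, mirabilis):
        nad1 = mirabilis.feature("nad1")
        trny = mirabilis.feature("trnY")
        assert spacer_after(nad1, trny, 15365) == 4

    def test_abutting_features_have_zero_spacer(self):
        a = GeneFeature("a", "protein", "H", 1, 100)
        b = GeneFeature("b", "protein", "H", 101, 200)
        assert spacer_after(a, b, 300) == 0

    def test_gene_size_is_strand_independent(self):
        h = GeneFeature("x", "tRNA", "H", 10, 73)
        l = GeneFeature("x", "tRNA", "L", 10, 73)
        assert gene_size(h) == gene_size(l) == 64


class TestClosure:
    def test_both_published_tables_close_to_genome_length(self, mirabilis, rubens):
        for ann, length in ((mirabilis, 15365), (rubens, 15513)):
            rep = closure_check(ann)
            assert rep["ok"] and rep["sum_sizes_plus_spacers"] == length

    def test_single_feature_spanning_circle(self):
        ann = MitogenomeAnnotation("one", 500, [GeneFeature("g", "rRNA", "H", 1, 500)])
        rep = closure_check(ann)
        assert rep["ok"] and ann.spacers() == [0]

    def test_printed_column_inconsistency_is_reported_not_raised(self, mirabilis):
        # the published table's atp6 size (700) disagrees with its own
        # coordinates (690); the printed-value closure flags it
        rep = closure_check(mirabilis)
        assert rep["ok"]  # coordinates close the circle
        assert not rep["ok_printed"]
        assert ("atp6", "size", 700, 690) in rep["printed_mismatches"]
        assert rep["sum_printed"] == 15375

    @given(st.lists(st.integers(min_value=-5, max_value=40), min_size=2, max_size=12),
           st.lists(st.integers(min_value=20, max_value=90), min_size=12, max_size=12))
    @settings(derandomize=True, max_examples=60)
    def test_planted_spacers_recovered(self, spacers, sizes):
        # lay features around a circle with known signed gaps
        feats, pos = [], 1
        for i, gap in enumerate(spacers):
            size = sizes[i]
            feats.append(GeneFeature(f"g{i}", "protein", "H", pos, pos + size - 1))
            pos += size + gap
        length = pos - 1  # so the trailing gap wraps to feature 0 exactly
        # starts must stay ascending and in range for the construction to be valid
        if any(f.end > length for f in feats) or length < feats[-1].end:
            return
        starts = [f.start for f in feats]
        if starts != sorted(starts) or len(set(starts)) != len(starts):
            return
        ann = MitogenomeAnnotation("p", length, feats)
        assert ann.spacers() == spacers
        assert closure_check(ann)["ok"]


class TestOverlapPairs:
    def test_published_overlaps_found(self, mirabilis, rubens):
        assert ("nad6", "cob", 8) in overlap_pairs(rubens)
        assert ("nad4L", "nad4", 7) in overlap_pairs(mirabilis)
        assert ("nad4L", "nad4", 7) in overlap_pairs(rubens)

    def test_no_overlaps_gives_empty_list(self):
        ann = MitogenomeAnnotation(
            "x", 300,
            [GeneFeature("a", "protein", "H", 1, 100),
             GeneFeature("b", "protein", "H", 105, 290)],
        )
        assert overlap_pairs(ann) == []


class TestGenBankReader:
    @pytest.fixture()
    def genbank_text(self):
        # a minimal two-feature record built with Biopython at test time
        import io

        from Bio import SeqIO
        from Bio.Seq import Seq
        from Bio.SeqFeature import SeqFeature, SimpleLocation
        from Bio.SeqRecord import SeqRecord

        rec = SeqRecord(Seq("ACGT" * 50), id="toy", annotations={"molecule_type": "DNA"})
        rec.features = [
            SeqFeature(SimpleLocation(0, 60, strand=1), type="CDS",
                       qualifiers={"gene": ["COX1"]}),
            SeqFeature(SimpleLocation(70, 130, strand=-1), type="tRNA",
                       qualifiers={"product": ["tRNA-Leu(CUN)"]}),
        ]
        buf = io.StringIO()
        SeqIO.write(rec, buf, "genbank")
        return buf.getvalue()

    def test_features_coordinates_and_strands(self, genbank_text):
        import io

        from mitocomp.annotation import read_genbank

        ann = read_genbank(io.StringIO(genbank_text))
        assert ann.genome_length == 200
        cox1 = ann.feature("cox1")
        assert (cox1.start, cox1.end, cox1.strand, cox1.gene_class) == (1, 60, "H", "protein")
        leu = ann.feature("trnL1")
        assert (leu.start, leu.end, leu.strand) == (71, 130, "L")

    def test_join_locations_rejected(self, genbank_text):
        import io

        from mitocomp.annotation import AnnotationError, read_genbank

        joined = genbank_text.replace("1..60", "join(1..30,40..60)")
        with pytest.raises(AnnotationError, match="join"):
            read_genbank(io.StringIO(joined))


class TestNameNormalization:
    @pytest.mark.parametrize(
        "raw, expected",
        [
            ("tRNA-Leu(CUN)", "trnL1"),
            ("tRNA-Ser(AGN)", "trnS2"),
            ("COX1", "cox1"),
            ("COI", "cox1"),
            ("12S rRNA", "rrnS"),
            ("ND4L", "nad4L"),
            ("CYTB", "cob"),
        ],
    )
    def test_genbank_names_map_to_canonical(self, raw, expected):
        assert normalize_gene_name(raw) == expected

    def test_unknown_name_passes_through_with_warning(self):
        with pytest.warns(UserWarning, match="unrecognized"):
            assert normalize_gene_name("mystery7") == "mystery7"
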