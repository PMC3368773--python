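"""Data model and parsers for circular mitogenome annotations.

A mitochondrial genome is a closed circle of DNA carrying (for bilaterians)
37 genes on two strands.  This module holds the gene map: 1-based, fully
closed coordinate intervals with an explicit strand flag, plus the derived
quantities an annotation table reports — gene sizes, 3' intergenic spacers
(negative values are overlaps), and the circular-closure identity that the
sizes and spacers of all features must telescope to the genome length.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field, replace

__all__ = [
    "GeneFeature",
    "MitogenomeAnnotation",
    "AnnotationError",
    "parse_annotation_tsv",
    "write_annotation_tsv",
    "read_genbank",
    "gene_size",
    "spacer_after",
    "closure_check",
    "overlap_pairs",
    "normalize_gene_name",
]

GENE_CLASSES = ("protein", "rRNA", "tRNA", "noncoding")

#: canonical 37-gene mitochondrial nomenclature
PROTEIN_GENES = (
    "atp6", "atp8", "cob", "cox1", "cox2", "cox3",
    "nad1", "nad2", "nad3", "nad4", "nad4L", "nad5", "nad6",
)
RRNA_GENES = ("rrnS", "rrnL")
TRNA_GENES = (
    "trnA", "trnC", "trnD", "trnE", "trnF", "trnG", "trnH", "trnI", "trnK",
    "trnL1", "trnL2", "trnM", "trnN", "trnP", "trnQ", "trnR", "trnS1",
    "trnS2", "trnT", "trnV", "trnW", "trnY",
)

# GenBank product/qualifier spellings -> canonical names.  tRNA-Leu/Ser are
# disambiguated by codon family: L1=CUN, L2=UUR, S1=UCN, S2=AGN.
_AA3_TO_1 = {
    "ala": "A", "cys": "C", "asp": "D", "glu": "E", "phe": "F", "gly": "G",
    "his": "H", "ile": "I", "lys": "K", "met": "M", "asn": "N", "pro": "P",
    "gln": "Q", "arg": "R", "thr": "T", "val": "V", "trp": "W", "tyr": "Y",
}
_NAME_SYNONYMS = {
    "cox1": "cox1", "coi": "cox1", "co1": "cox1", "coxi": "cox1",
    "cox2": "cox2", "coii": "cox2", "co2": "cox2", "coxii": "cox2",
    "cox3": "cox3", "coiii": "cox3", "co3": "cox3", "coxiii": "cox3",
    "cob": "cob", "cytb": "cob", "cyt b": "cob",
    "atp6": "atp6", "atpase6": "atp6", "atp8": "atp8", "atpase8": "atp8",
    "nad1": "nad1", "nd1": "nad1", "nad2": "nad2", "nd2": "nad2",
    "nad3": "nad3", "nd3": "nad3", "nad4": "nad4", "nd4": "nad4",
    "nad4l": "nad4L", "nd4l": "nad4L", "nad5": "nad5", "nd5": "nad5",
    "nad6": "nad6", "nd6": "nad6",
    "rrns": "rrnS", "12s": "rrnS", "s-rrna": "rrnS", "12s rrna": "rrnS",
    "12s ribosomal rna": "rrnS", "small subunit ribosomal rna": "rrnS",
    "rrnl": "rrnL", "16s": "rrnL", "l-rrna": "rrnL", "16s rrna": "rrnL",
    "16s ribosomal rna": "rrnL", "large subunit ribosomal rna": "rrnL",
}


def normalize_gene_name(raw: str) -> str:
    """Map a GenBank-style gene/product label to the canonical short name.

    Unknown labels pass through verbatim with a warning.
    """
    key = raw.strip()
    low = key.lower()
    if low in _NAME_SYNONYMS:
        return _NAME_SYNONYMS[low]
    if low.startswith("trna-") or low.startswith("trn"):
        body = key.split("-", 1)[1] if "-" in key else key[3:]
        aa = body[:3].lower()
        codon = ""
        if "(" in body and ")" in body:
            codon = body[body.index("(") + 1 : body.index(")")].upper().replace("T", "U")
        if aa == "leu":
            if codon == "CUN":
                return "trnL1"
            if codon == "UUR":
                return "trnL2"
        elif aa == "ser":
            if codon == "UCN":
                return "trnS1"
            if codon == "AGN":
                return "trnS2"
        elif aa in _AA3_TO_1:
            return "trn" + _AA3_TO_1[aa]
        if len(body) <= 2 and body[:1].upper() in _AA3_TO_1.values():
            return "trn" + body  # already one-letter form, e.g. trnL1
    if key in PROTEIN_GENES or key in RRNA_GENES or key in TRNA_GENES:
        return key
    warnings.warn(f"unrecognized gene name {raw!r} passed through verbatim")
    return key


def infer_gene_class(name: str) -> str:
    if name in PROTEIN_GENES:
        return "protein"
    if name in RRNA_GENES:
        return "rRNA"
    if name in TRNA_GENES or name.startswith("trn"):
        return "tRNA"
    return "noncoding"


class AnnotationError(ValueError):
    """Raised for malformed or inconsistent annotation input."""


@dataclass(frozen=True)
class GeneFeature:
    """One annotated feature on the circle.

    ``start <= end`` always; the 5'->3' reading direction is recovered from
    ``strand`` ("H" reads start->end, "L" reads end->start).
    """

    name: str
    gene_class: str
    strand: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.strand not in ("H", "L"):
            raise AnnotationError(f"{self.name}: strand must be 'H' or 'L'")
        if self.gene_class not in GENE_CLASSES:
            raise AnnotationError(f"{self.name}: unknown gene class {self.gene_class!r}")
        if not (1 <= self.start <= self.end):
            raise AnnotationError(
                f"{self.name}: invalid span {self.start}-{self.end} (need 1 <= start <= end)"
            )

    @property
    def size(self) -> int:
        return self.end - self.start + 1


@dataclass
class MitogenomeAnnotation:
    """A circular genome's ordered gene map (features sorted by start)."""

    genome_id: str
    genome_length: int
    features: list[GeneFeature] = field(default_factory=list)
    circular: bool = True
    #: reference values carried from a published table, for cross-checking
    printed: dict[str, tuple[int | None, int | None]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.features = sorted(self.features, key=lambda f: (f.start, f.end))
        names = [f.name for f in self.features]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise AnnotationError(f"duplicate gene names: {sorted(dupes)}")
        for f in self.features:
            if f.end > self.genome_length:
                raise AnnotationError(
                    f"{f.name}: coordinates {f.start}-{f.end} outside "
                    f"[1, {self.genome_length}]"
                )

    def feature(self, name: str) -> GeneFeature:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(name)

    def spacers(self) -> list[int]:
        """3' spacer after each feature, in ascending-start order (wraps)."""
        n = len(self.features)
        return [
            spacer_after(
                self.features[i],
                self.features[(i + 1) % n],
                self.genome_length,
                wrap=(i == n - 1),
            )
            for i in range(n)
        ]


def gene_size(f: GeneFeature) -> int:
    """Feature length in nucleotides (strand-independent)."""
    return f.end - f.start + 1


def spacer_after(
    f: GeneFeature, g: GeneFeature, genome_length: int, wrap: bool | None = None
) -> int:
    """Signed gap between feature ``f`` and the next feature ``g``.

    Negative values are overlaps.  When ``g`` is the first feature of the
    circle the gap wraps through the origin; by default wrapping is inferred
    from the coordinates (``g`` starting at or before ``f``), pass ``wrap``
    explicitly for tied starts.
    """
    if wrap is None:
        wrap = g.start <= f.start
    start_g = g.start + genome_length if wrap else g.start
    return start_g - f.end - 1


def closure_check(a: MitogenomeAnnotation) -> dict:
    """Verify that sizes + spacers telescope to the genome length.

    The sum over coordinate-derived values is the circle-recovery check.
    When the annotation carries published size/spacer columns, the same sum
    over the *printed* values is reported too — that one genuinely tests the
    source table's self-consistency and is not guaranteed to close.
    Inconsistency is a report outcome, not an exception.
    """
    spacers = a.spacers()
    rows = [
        {"name": f.name, "size": f.size, "spacer": s}
        for f, s in zip(a.features, spacers)
    ]
    total = sum(r["size"] + r["spacer"] for r in rows)
    report = {
        "genome_id": a.genome_id,
        "sum_sizes_plus_spacers": total,
        "genome_length": a.genome_length,
        "ok": total == a.genome_length,
        "features": rows,
    }
    if a.printed:
        printed_total = 0
        mismatches = []
        for row in rows:
            psize, pspacer = a.printed.get(row["name"], (None, None))
            psize = row["size"] if psize is None else psize
            pspacer = row["spacer"] if pspacer is None else pspacer
            printed_total += psize + pspacer
            if psize != row["size"]:
                mismatches.append((row["name"], "size", psize, row["size"]))
            if pspacer != row["spacer"]:
                mismatches.append((row["name"], "spacer", pspacer, row["spacer"]))
        report["sum_printed"] = printed_total
        report["ok_printed"] = printed_total == a.genome_length
        report["printed_mismatches"] = mismatches
    return report


def overlap_pairs(a: MitogenomeAnnotation) -> list[tuple[str, str, int]]:
    """All consecutive feature pairs with negative spacer (overlap in nt > 0)."""
    out = []
    n = len(a.features)
    for i, s in enumerate(a.spacers()):
        if s < 0:
            out.append((a.features[i].name, a.features[(i + 1) % n].name, -s))
    return out


# ---------------------------------------------------------------------------
# TSV dialect
# ---------------------------------------------------------------------------

def _parse_span(text: str) -> tuple[int, int, str]:
    try:
        a, b = (int(x) for x in text.split("-"))
    except Exception as exc:  # noqa: BLE001
        raise AnnotationError(f"malformed span {text!r}") from exc
    if a > b:  # written high-to-low: L strand
        return b, a, "L"
    return a, b, "H"


def parse_annotation_tsv(text: str | io.TextIOBase) -> MitogenomeAnnotation:
    """Parse the annotation TSV dialect.

    Header lines ``#genome_id=``, ``#length=``, ``#circular=``; a column
    header row; then one feature per row.  Spans written high-to-low denote
    L-strand features and are normalized to ``start <= end``.  A ``size``
    column, when present, is validated against the coordinates.  Columns
    ``size_printed``/``spacer_printed`` are carried as reference metadata.
    """
    if hasattr(text, "read"):
        text = text.read()
    genome_id = None
    length = None
    circular = True
    header: list[str] | None = None
    feats: list[GeneFeature] = []
    printed: dict[str, tuple[int | None, int | None]] = {}
    for lineno, line in enumerate(str(text).splitlines(), 1):
        line = line.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith("#"):
            body = line[1:].strip()
            if "=" in body:
                k, v = body.split("=", 1)
                k = k.strip().lower()
                if k == "genome_id":
                    genome_id = v.strip()
                elif k == "length":
                    length = int(v)
                elif k == "circular":
                    circular = v.strip().lower() in ("true", "1", "yes")
            continue
        cells = line.split("\t")
        if header is None:
            header = [c.strip() for c in cells]
            if header[:2] != ["name", "span"]:
                raise AnnotationError("TSV must start with columns 'name', 'span'")
            continue
        row = dict(zip(header, cells))
        name = row["name"].strip()
        start, end, strand = _parse_span(row["span"].strip())
        klass = row.get("class", "").strip() or infer_gene_class(name)
        if length is not None and end > length:
            raise AnnotationError(
                f"line {lineno}: {name} coordinates {start}-{end} outside [1, {length}]"
            )
        if row.get("size", "").strip():
            stated = int(row["size"])
            actual = end - start + 1
            if stated != actual:
                raise AnnotationError(
                    f"line {lineno}: {name} size column says {stated} but "
                    f"coordinates {start}-{end} give {actual}"
                )
        sp = row.get("size_printed", "").strip()
        spc = row.get("spacer_printed", "").strip()
        if sp or spc:
            printed[name] = (int(sp) if sp else None, int(spc) if spc else None)
        feats.append(GeneFeature(name, klass, strand, start, end))
    if genome_id is None or length is None:
        raise AnnotationError("header must declare #genome_id= and #length=")
    return MitogenomeAnnotation(genome_id, length, feats, circular, printed)


def write_annotation_tsv(a: MitogenomeAnnotation) -> str:
    """Emit the TSV dialect; L-strand spans are written high-to-low."""
    lines = [
        f"#genome_id={a.genome_id}",
        f"#length={a.genome_length}",
        f"#circular={'true' if a.circular else 'false'}",
        "name\tspan\tclass",
    ]
    for f in a.features:
        span = f"{f.end}-{f.start}" if f.strand == "L" else f"{f.start}-{f.end}"
        lines.append(f"{f.name}\t{span}\t{f.gene_class}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# GenBank flat files
# ---------------------------------------------------------------------------

def read_genbank(handle) -> MitogenomeAnnotation:
    """Build an annotation from a GenBank record's CDS/rRNA/tRNA features.

    ``complement(a..b)`` locations map to the L strand.  ``join()`` spans are
    rejected — they do not occur in these genomes.
    """
    from Bio import SeqIO

    rec = SeqIO.read(handle, "genbank")
    feats: list[GeneFeature] = []
    for ft in rec.features:
        if ft.type not in ("CDS", "rRNA", "tRNA"):
            continue
        if len(ft.location.parts) > 1:
            raise AnnotationError(f"join() locations not supported ({ft})")
        raw = (
            ft.qualifiers.get("gene", [None])[0]
            or ft.qualifiers.get("product", [None])[0]
            or ft.type
        )
        name = normalize_gene_name(raw)
        klass = {"CDS": "protein", "rRNA": "rRNA", "tRNA": "tRNA"}[ft.type]
        start = int(ft.location.start) + 1  # Biopython is 0-based half-open
        end = int(ft.location.end)
        strand = "L" if ft.location.strand == -1 else "H"
        feats.append(GeneFeature(name, klass, strand, start, end))
    return MitogenomeAnnotation(rec.id or rec.name, len(rec.seq), feats)
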