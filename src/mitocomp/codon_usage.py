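"""Codon counting, codons-per-thousand, and relative synonymous codon usage.

All computations use the invertebrate mitochondrial genetic code (NCBI
translation table 5: TGA=Trp, AGR=Ser, ATA=Met; 62 sense codons).  Stop
codons — including the incomplete stops ("T"/"TA") completed to TAA by
polyadenylation of the transcript — are excluded from every count.

Synonymous families default to the mitochondrial anticodon-based split:
Leu1 (CUN) and Leu2 (UUR) are separate families, as are Ser1 (UCN) and
Ser2 (AGN).  The merged six/eight-fold amino-acid grouping is available via
``family_mode="merged"``.

RSCU(c) = count(c) / (family_total / |family|): 1.0 means a codon is used
exactly as often as expected under uniform usage within its family.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Data import CodonTable

__all__ = [
    "CodingSequence",
    "CodonUsageTable",
    "CodonUsageError",
    "extract_codons",
    "validate_start",
    "codon_usage",
    "rscu",
    "count_used_codons",
    "codon_families",
    "SENSE_CODONS",
    "STOP_CODONS",
]

_TABLE5 = CodonTable.unambiguous_dna_by_id[5]
STOP_CODONS = tuple(sorted(_TABLE5.stop_codons))  # ('TAA', 'TAG')
SENSE_CODONS = tuple(sorted(_TABLE5.forward_table))  # 62 codons
AMINO_ACID = dict(_TABLE5.forward_table)

_SPLIT_OVERRIDES = {
    "CTT": "Leu1", "CTC": "Leu1", "CTA": "Leu1", "CTG": "Leu1",
    "TTA": "Leu2", "TTG": "Leu2",
    "TCT": "Ser1", "TCC": "Ser1", "TCA": "Ser1", "TCG": "Ser1",
    "AGT": "Ser2", "AGC": "Ser2", "AGA": "Ser2", "AGG": "Ser2",
}
_AA_NAME = {
    "A": "Ala", "C": "Cys", "D": "Asp", "E": "Glu", "F": "Phe", "G": "Gly",
    "H": "His", "I": "Ile", "K": "Lys", "L": "Leu", "M": "Met", "N": "Asn",
    "P": "Pro", "Q": "Gln", "R": "Arg", "S": "Ser", "T": "Thr", "V": "Val",
    "W": "Trp", "Y": "Tyr",
}


def codon_families(family_mode: str = "split") -> dict[str, tuple[str, ...]]:
    """Family name -> member codons under the chosen grouping."""
    if family_mode not in ("split", "merged"):
        raise ValueError("family_mode must be 'split' or 'merged'")
    fams: dict[str, list[str]] = {}
    for codon in SENSE_CODONS:
        if family_mode == "split" and codon in _SPLIT_OVERRIDES:
            fam = _SPLIT_OVERRIDES[codon]
        else:
            fam = _AA_NAME[AMINO_ACID[codon]]
        fams.setdefault(fam, []).append(codon)
    return {k: tuple(sorted(v)) for k, v in fams.items()}


_FAMILY_OF = {
    mode: {c: fam for fam, codons in codon_families(mode).items() for c in codons}
    for mode in ("split", "merged")
}


class CodonUsageError(ValueError):
    pass


@dataclass(frozen=True)
class CodingSequence:
    """An in-frame CDS read 5'->3' on its own coding strand."""

    gene: str
    nt_seq: str
    start_codon: str = ""
    stop: str = ""  # TAA / TAG / T_incomplete / TA_incomplete

    @classmethod
    def from_nt(cls, gene: str, seq: str) -> "CodingSequence":
        s = seq.upper().replace("U", "T")
        rem = len(s) % 3
        if rem == 0:
            stop = s[-3:] if s[-3:] in STOP_CODONS else ""
        else:
            stop = {1: "T_incomplete", 2: "TA_incomplete"}[rem]
        return cls(gene=gene, nt_seq=s, start_codon=s[:3], stop=stop)


def extract_codons(cds: CodingSequence) -> list[str]:
    """Split a CDS into sense codons.

    Trailing 1-2 nt (an incomplete stop) and a terminal TAA/TAG are dropped.
    An in-frame stop anywhere else is an error naming the codon position.
    """
    s = cds.nt_seq.upper().replace("U", "T")
    if len(s) < 6:
        raise CodonUsageError(f"{cds.gene}: CDS shorter than 6 nt")
    s = s[: len(s) - len(s) % 3]
    codons = [s[i : i + 3] for i in range(0, len(s), 3)]
    if codons and codons[-1] in STOP_CODONS:
        codons.pop()
    for pos, c in enumerate(codons, 1):
        if c in STOP_CODONS:
            raise CodonUsageError(f"{cds.gene}: internal stop codon {c} at codon {pos}")
    return codons


def validate_start(cds: CodingSequence, allowed: frozenset[str] = frozenset({"GTG", "GTT"})) -> str:
    """Classify the initiation codon: canonical ATG, alternative, or invalid."""
    start = cds.nt_seq[:3].upper().replace("U", "T")
    if start == "ATG":
        return "canonical"
    if start in allowed:
        return "alternative"
    return "invalid"


@dataclass
class CodonUsageTable:
    counts: dict[str, int]
    total_cds: int
    family_mode: str = "split"
    errors: dict[str, str] = field(default_factory=dict)

    @property
    def families(self) -> dict[str, tuple[str, ...]]:
        return codon_families(self.family_mode)

    def family_counts(self) -> dict[str, int]:
        return {
            fam: sum(self.counts.get(c, 0) for c in codons)
            for fam, codons in self.families.items()
        }

    def per_thousand(self) -> dict[str, float]:
        """Codons per thousand codons (CDspT) by synonymous family."""
        if self.total_cds == 0:
            raise CodonUsageError("no codons")
        return {
            fam: 1000.0 * n / self.total_cds for fam, n in self.family_counts().items()
        }


def codon_usage(
    cds_set: list[CodingSequence], family_mode: str = "split"
) -> CodonUsageTable:
    """Count sense codons over a set of CDSs.

    Per-gene extraction failures are collected in ``errors`` rather than
    aborting the whole table; an empty result is an error.
    """
    counts = {c: 0 for c in SENSE_CODONS}
    errors: dict[str, str] = {}
    total = 0
    for cds in cds_set:
        try:
            for codon in extract_codons(cds):
                if codon not in counts:
                    raise CodonUsageError(f"{cds.gene}: non-ACGT codon {codon!r}")
                counts[codon] += 1
                total += 1
        except CodonUsageError as exc:
            errors[cds.gene] = str(exc)
    if total == 0:
        raise CodonUsageError("no codons")
    return CodonUsageTable(counts=counts, total_cds=total, family_mode=family_mode, errors=errors)


def rscu(table: CodonUsageTable) -> dict[str, float | None]:
    """RSCU per codon; families with zero total map to None (undefined)."""
    out: dict[str, float | None] = {}
    for fam, codons in table.families.items():
        fam_total = sum(table.counts.get(c, 0) for c in codons)
        for c in codons:
            if fam_total == 0:
                out[c] = None
            else:
                out[c] = table.counts.get(c, 0) / (fam_total / len(codons))
    return out


def count_used_codons(table: CodonUsageTable) -> int:
    """Number of the 62 sense codons observed at least once."""
    return sum(1 for c in SENSE_CODONS if table.counts.get(c, 0) > 0)
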