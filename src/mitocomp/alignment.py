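"""Conservation statistics on tRNA multiple alignments.

%INUC is the percent of alignment columns in which every sequence carries
the same nucleotide.  Columns containing any gap are never identical (the
strictest reading; echoed in output metadata).  Stem substitutions relative
to a reference sequence are classified as fully compensatory base changes
(cbc: both positions of a pair change, pairing preserved, e.g. G-C vs A-T)
or hemi-cbc (one position changes, pairing preserved, e.g. T-A vs T-G).
The canonical pair set includes the G-T/G-U wobble.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .composition import round_half_away

__all__ = [
    "AlignmentProfile",
    "StemSubstitution",
    "percent_inuc",
    "conservation_rank",
    "classify_stem_pair",
    "stem_substitution_scan",
    "parse_fasta_alignment",
    "CANONICAL_PAIRS",
    "DEFAULT_BANDS",
]

CANONICAL_PAIRS = frozenset(
    {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G")}
)

#: (label, lower, upper, lower_closed, upper_closed) — the published bands
DEFAULT_BANDS = (
    (">50", 50.0, 100.0, False, True),
    ("40-50", 40.0, 50.0, True, True),
    ("30-40", 30.0, 40.0, False, False),
    "<=30",
)


@dataclass(frozen=True)
class AlignmentProfile:
    gene: str
    n_seqs: int
    aln_length: int
    identical_positions: int

    @property
    def pct_inuc(self) -> float:
        return round_half_away(100.0 * self.identical_positions / self.aln_length, 2)


@dataclass(frozen=True)
class StemSubstitution:
    position_pair: tuple[int, int]
    pair_ref: tuple[str, str]
    pair_obs: tuple[str, str]
    klass: str
    sequence: str = ""


def _norm(base: str) -> str:
    return base.upper().replace("U", "T")


def parse_fasta_alignment(text: str) -> dict[str, str]:
    """Minimal aligned-FASTA reader returning {id: row} in file order."""
    rows: dict[str, str] = {}
    name = None
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            name = line[1:].split()[0]
            rows[name] = ""
        elif name is not None:
            rows[name] += line
    return rows


def percent_inuc(aln: dict[str, str] | list[str], gene: str = "") -> AlignmentProfile:
    """Count fully identical (non-gap) columns of a multiple alignment."""
    rows = list(aln.values()) if isinstance(aln, dict) else list(aln)
    if len(rows) < 2:
        raise ValueError("alignment needs at least 2 sequences")
    lengths = {len(r) for r in rows}
    if len(lengths) != 1:
        raise ValueError(f"ragged alignment: row lengths {sorted(lengths)}")
    (length,) = lengths
    rows = [_norm(r) for r in rows]
    identical = 0
    for col in zip(*rows):
        if col[0] not in "-." and len(set(col)) == 1:
            identical += 1
    return AlignmentProfile(gene, len(rows), length, identical)


def conservation_rank(
    profiles: list[AlignmentProfile], bands=DEFAULT_BANDS
) -> dict[str, list[str]]:
    """Assign each profile to a conservation band.

    Default bands follow the published grouping: >50, 40 <= x <= 50 (both
    ends closed, so exactly 50.00 ranks in the middle band), 30 < x < 40,
    and <= 30.
    """
    if not profiles:
        raise ValueError("no profiles")
    out: dict[str, list[str]] = {}
    fallback = bands[-1] if isinstance(bands[-1], str) else "unbanded"
    for label in [b[0] for b in bands if not isinstance(b, str)] + [fallback]:
        out[label] = []
    for p in profiles:
        x = p.pct_inuc
        for band in bands:
            if isinstance(band, str):
                out[band].append(p.gene)
                break
            label, lo, hi, lo_closed, hi_closed = band
            ok_lo = x >= lo if lo_closed else x > lo
            ok_hi = x <= hi if hi_closed else x < hi
            if ok_lo and ok_hi:
                out[label].append(p.gene)
                break
    return out


def classify_stem_pair(pair_ref: tuple[str, str], pair_obs: tuple[str, str]) -> str:
    """Classify an observed stem base pair against the reference pair."""
    ref = (_norm(pair_ref[0]), _norm(pair_ref[1]))
    obs = (_norm(pair_obs[0]), _norm(pair_obs[1]))
    for b in ref + obs:
        if b not in "ACGT":
            raise ValueError(f"non-nucleotide symbol {b!r} in stem pair")
    if obs == ref:
        return "identical"
    ref_canon = ref in CANONICAL_PAIRS
    obs_canon = obs in CANONICAL_PAIRS
    changed = (ref[0] != obs[0]) + (ref[1] != obs[1])
    if ref_canon and obs_canon:
        return "cbc" if changed == 2 else "hemi_cbc"
    if ref_canon and not obs_canon:
        return "mismatch_introduced"
    return "other"


def stem_substitution_scan(
    aln: dict[str, str],
    pairing_mask: list[tuple[int, int]],
    reference: str,
) -> list[StemSubstitution]:
    """Classify every (sequence, stem pair) against the reference row.

    ``pairing_mask`` holds 1-based column index pairs.  Pairs touching a gap
    in the reference are skipped with a warning; gaps in a query yield a
    skipped pair for that query only.
    """
    if reference not in aln:
        raise ValueError(f"reference {reference!r} not in alignment")
    ref_row = _norm(aln[reference])
    out: list[StemSubstitution] = []
    for (i, j) in pairing_mask:
        if not (1 <= i <= len(ref_row) and 1 <= j <= len(ref_row)):
            raise ValueError(f"mask pair ({i},{j}) outside alignment")
        r = (ref_row[i - 1], ref_row[j - 1])
        if "-" in r or "." in r:
            warnings.warn(f"mask pair ({i},{j}) touches a gap in the reference; skipped")
            continue
        for name, row in aln.items():
            if name == reference:
                continue
            row = _norm(row)
            q = (row[i - 1], row[j - 1])
            if "-" in q or "." in q:
                warnings.warn(f"{name}: gap at masked pair ({i},{j}); skipped")
                continue
            out.append(
                StemSubstitution((i, j), r, q, classify_stem_pair(r, q), sequence=name)
            )
    return out


def parse_pairing_mask(text: str) -> list[tuple[int, int]]:
    """Pairing mask from a dot-bracket string or an (i, j) TSV (1-based)."""
    text = text.strip()
    if set(text) <= set("().<>-: \t\n") and "(" in text:
        stack: list[int] = []
        pairs = []
        for idx, ch in enumerate(text, 1):
            if ch in "(<":
                stack.append(idx)
            elif ch in ")>":
                if not stack:
                    raise ValueError("unbalanced dot-bracket string")
                pairs.append((stack.pop(), idx))
        if stack:
            raise ValueError("unbalanced dot-bracket string")
        return sorted(pairs)
    pairs = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        i, j = line.split()[:2]
        pairs.append((int(i), int(j)))
    return pairs
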