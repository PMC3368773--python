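"""Base composition, strand-skew statistics, and sliding-window profiles.

AT-skew = (A - T)/(A + T) and GC-skew = (G - C)/(G + C), computed on the
strand carrying most genes (the sequence as deposited).  Mitochondrial
genomes show pronounced strand asymmetry — one strand rich in A and C, the
other in T and G — and these two dimensionless numbers summarize it.

Percentages are reported to 1 decimal and skews to 3 decimals (internal math
is full precision; rounding is half-away-from-zero).  IUPAC ambiguity codes
are excluded from all denominators and tracked as a separate count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .annotation import GeneFeature

__all__ = [
    "CompositionStats",
    "base_composition",
    "at_skew",
    "gc_skew",
    "sliding_window_profile",
    "region_at_content",
    "round_half_away",
]

_COMPLEMENT = str.maketrans("ACGTRYKMBVDHNacgtrykmbvdhn",
                            "TGCAYRMKVBHDNtgcayrmkvbhdn")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def round_half_away(x: float, ndigits: int) -> float:
    """Round half away from zero (the convention of printed tables)."""
    factor = 10 ** ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


@dataclass(frozen=True)
class CompositionStats:
    total_nt: int
    pct_T: float
    pct_C: float
    pct_A: float
    pct_G: float
    pct_AT: float
    at_skew: float
    gc_skew: float
    n_ambiguous: int = 0


def at_skew(pct_a: float, pct_t: float) -> float:
    """(A - T)/(A + T), to 3 decimals."""
    denom = pct_a + pct_t
    if denom <= 0:
        raise ValueError("AT skew undefined: A + T is zero")
    return round_half_away((pct_a - pct_t) / denom, 3)


def gc_skew(pct_g: float, pct_c: float) -> float:
    """(G - C)/(G + C), to 3 decimals."""
    denom = pct_g + pct_c
    if denom <= 0:
        raise ValueError("GC skew undefined: G + C is zero")
    return round_half_away((pct_g - pct_c) / denom, 3)


def base_composition(seq: str) -> CompositionStats:
    """Composition summary of one strand of a nucleotide sequence.

    Non-ACGT symbols are excluded from the denominator and counted
    separately.  Raises on sequences with no informative bases.
    """
    s = seq.upper().replace("U", "T")
    counts = {b: s.count(b) for b in "ACGT"}
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no informative bases")
    ambiguous = len(s) - total - s.count("-")
    pct = {b: 100.0 * counts[b] / total for b in "ACGT"}
    return CompositionStats(
        total_nt=total,
        pct_T=round_half_away(pct["T"], 1),
        pct_C=round_half_away(pct["C"], 1),
        pct_A=round_half_away(pct["A"], 1),
        pct_G=round_half_away(pct["G"], 1),
        pct_AT=round_half_away(pct["A"] + pct["T"], 1),
        at_skew=at_skew(pct["A"], pct["T"]) if pct["A"] + pct["T"] > 0 else 0.0,
        gc_skew=gc_skew(pct["G"], pct["C"]) if pct["G"] + pct["C"] > 0 else 0.0,
        n_ambiguous=ambiguous,
    )


def sliding_window_profile(
    seq: str,
    window: int = 100,
    step: int = 1,
    letters: str = "AT",
    circular: bool = False,
) -> list[tuple[int, float]]:
    """Percent of ``letters`` per window; positions are 1-based window starts.

    With ``circular=True`` windows wrap through the origin so every position
    of the circle starts one window.
    """
    if window < 1 or step < 1:
        raise ValueError("window and step must be >= 1")
    s = seq.upper()
    n = len(s)
    if window > n:
        raise ValueError("window larger than sequence")
    wanted = set(letters.upper())
    src = s + s[: window - 1] if circular else s
    last = n if circular else n - window + 1
    out = []
    for i in range(0, last, step):
        win = src[i : i + window]
        out.append((i + 1, 100.0 * sum(c in wanted for c in win) / window))
    return out


def region_at_content(seq: str, feature: GeneFeature) -> float:
    """AT percentage of the subsequence covered by ``feature`` (1-based)."""
    if feature.end > len(seq):
        raise ValueError(
            f"{feature.name}: span {feature.start}-{feature.end} exceeds sequence "
            f"length {len(seq)}"
        )
    sub = seq[feature.start - 1 : feature.end].upper()
    acgt = sum(sub.count(b) for b in "ACGT")
    if acgt == 0:
        raise ValueError("no informative bases in region")
    return 100.0 * (sub.count("A") + sub.count("T")) / acgt
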