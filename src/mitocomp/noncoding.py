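"""Repeat architecture of AT-rich non-coding (control) regions.

Animal mitochondrial control regions accumulate tandem repeats, homopolymer
tracts and short inverted repeats able to fold into stem-loops.  The three
scanners here are exact string algorithms, not thermodynamic folding:

* tandem repeats — maximal, non-overlapping runs of a repeated unit; at each
  start the period reaching ``min_copies`` with the longest total span wins
  (smallest period on ties), scanning is leftmost-first, and a trailing
  partial copy is included in the span;
* homopolymers — maximal single-base runs of at least ``min_len``;
* hairpins — inverted repeats (arm2 = reverse complement of arm1 up to
  ``max_mismatch``) with loop length within bounds, reported for every
  maximal stem, overlaps allowed.

Every reported hit is self-validating: re-reading its span from the sequence
reproduces unit x copies (+ partial).  Circular genomes are scanned by
doubling the sequence and de-duplicating hits modulo the origin.
"""

from __future__ import annotations

from dataclasses import dataclass

from .annotation import MitogenomeAnnotation
from .composition import region_at_content

__all__ = [
    "RepeatHit",
    "HairpinHit",
    "find_tandem_repeats",
    "find_homopolymers",
    "find_hairpins",
    "atrich_region_report",
]


@dataclass(frozen=True)
class RepeatHit:
    unit: str
    period: int
    copies: int
    partial: int  # extra matching nt beyond the last full copy
    start: int  # 1-based inclusive
    end: int
    kind: str  # "tandem" | "homopolymer"

    @property
    def span_length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class HairpinHit:
    stem_len: int
    loop_len: int
    arm1_span: tuple[int, int]  # 1-based inclusive
    arm2_span: tuple[int, int]
    mismatches: int


def _repeat_span(s: str, i: int, p: int) -> int:
    """Length of the maximal run starting at i with period p."""
    j = i + p
    while j < len(s) and s[j] == s[j - p]:
        j += 1
    return j - i


def find_tandem_repeats(
    seq: str,
    min_period: int = 2,
    max_period: int = 60,
    min_copies: int = 3,
    circular: bool = False,
) -> list[RepeatHit]:
    if min_period < 1:
        raise ValueError("min_period must be >= 1")
    if max_period >= len(seq):
        raise ValueError("max_period must be smaller than the sequence")
    s = seq.upper()
    n = len(s)
    if circular:
        return _dedup_circular(
            find_tandem_repeats(s + s, min_period, max_period, min_copies), n
        )
    hits: list[RepeatHit] = []
    i = 0
    while i < n:
        found = None
        # leftmost-longest: at each start the qualifying period with the
        # longest total span wins; ties go to the smallest period (so a unit
        # never masquerades as its own doubling)
        for p in range(min_period, min(max_period, (n - i) // 2) + 1):
            span = _repeat_span(s, i, p)
            copies, partial = divmod(span, p)
            if copies >= min_copies and (found is None or span > found.span_length):
                found = RepeatHit(
                    unit=s[i : i + p],
                    period=p,
                    copies=copies,
                    partial=partial,
                    start=i + 1,
                    end=i + span,
                    kind="tandem",
                )
        if found:
            hits.append(found)
            i = found.end  # non-overlapping: resume after the hit
        else:
            i += 1
    return hits


def find_homopolymers(
    seq: str, min_len: int = 6, circular: bool = False
) -> list[RepeatHit]:
    if min_len < 2:
        raise ValueError("min_len must be >= 2")
    s = seq.upper()
    n = len(s)
    if circular:
        return _dedup_circular(find_homopolymers(s + s, min_len), n)
    hits = []
    i = 0
    while i < n:
        j = i + 1
        while j < n and s[j] == s[i]:
            j += 1
        if j - i >= min_len:
            hits.append(
                RepeatHit(s[i], 1, j - i, 0, i + 1, j, "homopolymer")
            )
        i = j
    return hits


def _dedup_circular(hits: list[RepeatHit], n: int) -> list[RepeatHit]:
    """Map hits on a doubled sequence back to the circle."""
    out = []
    seen = set()
    for h in hits:
        if h.start > n or h.span_length > n:
            continue
        key = ((h.start - 1) % n, h.period, h.kind, h.span_length)
        if key in seen:
            continue
        seen.add(key)
        out.append(h)
    return out


def find_hairpins(
    seq: str,
    min_stem: int = 5,
    max_loop: int = 30,
    max_mismatch: int = 1,
    min_loop: int = 3,
) -> list[HairpinHit]:
    """All maximal inverted repeats (pure base-pair matching, G-T not scored).

    Arms must not overlap; the loop is the gap between them.  A stem is
    maximal when it cannot be extended outward within the mismatch budget.
    Hits are sorted by stem length, longest first; overlaps are reported.
    """
    if min_stem < 3:
        raise ValueError("min_stem must be >= 3")
    s = seq.upper()
    n = len(s)
    comp = {"A": "T", "T": "A", "G": "C", "C": "G"}
    hits = []
    for loop_start in range(1, n):  # 0-based position after arm1
        for loop_len in range(min_loop, max_loop + 1):
            a = loop_start - 1  # last base of arm1
            b = loop_start + loop_len  # first base of arm2
            if b >= n:
                break
            stem = 0
            mism = 0
            k = 0
            last_match = -1
            while a - k >= 0 and b + k < n:
                if comp.get(s[a - k]) == s[b + k]:
                    last_match = k
                elif mism < max_mismatch:
                    mism += 1
                else:
                    break
                k += 1
            stem = last_match + 1  # stem never ends on a mismatch
            if stem >= min_stem:
                used_mism = sum(
                    1 for t in range(stem) if comp.get(s[a - t]) != s[b + t]
                )
                hits.append(
                    HairpinHit(
                        stem_len=stem,
                        loop_len=loop_len,
                        arm1_span=(a - stem + 2, a + 1),
                        arm2_span=(b + 1, b + stem),
                        mismatches=used_mism,
                    )
                )
    # keep only maximal stems per (arm1 end, arm2 start)
    best: dict[tuple[int, int], HairpinHit] = {}
    for h in hits:
        key = (h.arm1_span[1], h.arm2_span[0])
        if key not in best or h.stem_len > best[key].stem_len:
            best[key] = h
    return sorted(best.values(), key=lambda h: (-h.stem_len, h.arm1_span))


def atrich_region_report(
    annotation: MitogenomeAnnotation,
    genome_seq: str | None = None,
    min_copies: int = 3,
    min_homopolymer: int = 6,
    min_stem: int = 5,
) -> dict:
    """Locate the AT-rich noncoding feature and scan it.

    Works from coordinates alone (span and length); with a genome sequence
    it additionally reports AT% and the repeat/homopolymer/hairpin scans.
    """
    noncoding = [f for f in annotation.features if f.gene_class == "noncoding"]
    if not noncoding:
        gaps = [
            (annotation.features[i].name, s)
            for i, s in enumerate(annotation.spacers())
            if s > 30
        ]
        raise ValueError(
            f"{annotation.genome_id}: no noncoding feature annotated; "
            f"candidate gaps (feature, 3' spacer): {gaps}"
        )
    region = max(noncoding, key=lambda f: f.size)
    report: dict = {
        "genome_id": annotation.genome_id,
        "region": region.name,
        "span": (region.start, region.end),
        "length": region.size,
    }
    if genome_seq is not None:
        sub = genome_seq[region.start - 1 : region.end]
        report["at_percent"] = region_at_content(genome_seq, region)
        report["tandem_repeats"] = find_tandem_repeats(sub, min_copies=min_copies)
        report["homopolymers"] = find_homopolymers(sub, min_len=min_homopolymer)
        report["hairpins"] = find_hairpins(sub, min_stem=min_stem)
    return report
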