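"""Synthetic annotated mitogenomes with known ground truth.

The generator emulates the study system: a circular genome of 37 genes
(13 protein-coding, 22 tRNA, 2 rRNA) laid out in the hoplonemertean-like
reference arrangement, everything on the H strand except trnP and trnT, an
AT-rich non-coding block carrying planted tandem repeats, homopolymer tracts
and hairpins, protein-coding genes drawn codon-by-codon from a configurable
codon distribution (with ATG starts and full or incomplete stops), and gene
orders derived from the reference by a known number of random reversals.

Default parameters mirror the observed study conditions: genome length
15365 nt, base composition A=21.8 / T=48.5 / C=10.5 / G=19.2 (the published
whole-genome values), an AT-rich block targeting 81.5% A+T, and the three
published repeat motifs planted in it.

Every stochastic choice flows from a single integer seed through fixed,
named substreams, so adding one component never perturbs the others and
identical configs give byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .annotation import GeneFeature, MitogenomeAnnotation
from .codon_usage import SENSE_CODONS
from .composition import reverse_complement
from .gene_order import GeneOrder

__all__ = [
    "SimConfig",
    "generate_mitogenome",
    "scramble_gene_order",
    "sample_sequence",
    "REFERENCE_LAYOUT",
]

# reference layout: (name, class, size) in circle order, AT-rich block included.
# Sizes follow the N. cf. mirabilis annotation (coordinate-derived).
REFERENCE_LAYOUT: tuple[tuple[str, str, int], ...] = (
    ("trnY", "tRNA", 62), ("trnP", "tRNA", 63), ("nad6", "protein", 456),
    ("cob", "protein", 1137), ("trnS1", "tRNA", 61), ("trnT", "tRNA", 66),
    ("nad4L", "protein", 303), ("nad4", "protein", 1362), ("trnH", "tRNA", 60),
    ("nad5", "protein", 1746), ("trnE", "tRNA", 63), ("trnG", "tRNA", 63),
    ("cox3", "protein", 780), ("trnK", "tRNA", 67), ("trnA", "tRNA", 63),
    ("trnF", "tRNA", 66), ("trnQ", "tRNA", 67), ("trnR", "tRNA", 66),
    ("trnN", "tRNA", 63), ("trnI", "tRNA", 66), ("nad3", "protein", 354),
    ("cox1", "protein", 1536), ("trnW", "tRNA", 65),
    ("AT-rich", "noncoding", 0),  # absorbs all slack up to genome_length
    ("trnS2", "tRNA", 68), ("nad2", "protein", 1008), ("cox2", "protein", 681),
    ("trnD", "tRNA", 65), ("atp8", "protein", 157), ("atp6", "protein", 690),
    ("trnC", "tRNA", 61), ("trnM", "tRNA", 65), ("rrnS", "rRNA", 805),
    ("trnV", "tRNA", 62), ("rrnL", "rRNA", 1178), ("trnL1", "tRNA", 64),
    ("trnL2", "tRNA", 62), ("nad1", "protein", 924),
)

_SUBSTREAMS = {"background": 0, "cds": 1, "atrich": 2, "scramble": 3, "stops": 4}

#: published control-region motifs used as planting defaults
DEFAULT_REPEATS = (
    ("AAAAATATAAGATTTTTCAAATTCCAAAAATATAAAAT", 3),
    ("TTTTG", 10),
    ("TTTTTC", 7),
)
DEFAULT_HOMOPOLYMERS = (("A", 8), ("T", 9))
DEFAULT_HAIRPINS = ((7, 9, 0),)


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    genome_length: int = 15365
    #: target base percentages on the coding strand, summing to 100
    composition: tuple[float, float, float, float] = (21.8, 48.5, 10.5, 19.2)  # A,T,C,G
    at_rich_percent: float = 81.5
    l_strand_genes: frozenset[str] = frozenset({"trnP", "trnT"})
    planted_repeats: tuple[tuple[str, int], ...] = DEFAULT_REPEATS
    planted_homopolymers: tuple[tuple[str, int], ...] = DEFAULT_HOMOPOLYMERS
    planted_hairpins: tuple[tuple[int, int, int], ...] = DEFAULT_HAIRPINS
    codon_freqs: tuple[tuple[str, float], ...] | None = None
    incomplete_stop_fraction: float = 0.0
    scramble_k: int = 0

    def rng(self, component: str) -> np.random.Generator:
        return np.random.Generator(
            np.random.PCG64(np.random.SeedSequence(self.seed, spawn_key=(_SUBSTREAMS[component],)))
        )


def sample_sequence(
    composition: tuple[float, float, float, float],
    length: int,
    rng: np.random.Generator | int,
) -> str:
    """i.i.d. nucleotide draws at the stated (A, T, C, G) percentages."""
    if isinstance(rng, int):
        rng = np.random.default_rng(rng)
    if length == 0:
        return ""
    p = np.asarray(composition, dtype=float)
    if not np.isclose(p.sum(), 100.0):
        raise ValueError("composition must sum to 100")
    return "".join(rng.choice(list("ATCG"), size=length, p=p / p.sum()))


def _codon_probs(cfg: SimConfig) -> tuple[list[str], np.ndarray]:
    if cfg.codon_freqs is not None:
        codons = [c for c, _ in cfg.codon_freqs]
        w = np.array([f for _, f in cfg.codon_freqs], dtype=float)
    else:
        # weight each sense codon by the product of its base frequencies
        base_p = dict(zip("ATCG", np.asarray(cfg.composition) / 100.0))
        codons = list(SENSE_CODONS)
        w = np.array([base_p[c[0]] * base_p[c[1]] * base_p[c[2]] for c in codons])
    return codons, w / w.sum()


def _make_cds(size: int, codons: list[str], probs: np.ndarray, rng) -> tuple[str, str]:
    """A CDS of exactly `size` nt: ATG + sense codons + stop.

    size % 3 == 0 -> full TAA/TAG stop; == 1 -> incomplete 'T'; == 2 -> 'TA'.
    """
    rem = size % 3
    stop = {0: ("TAA" if rng.random() < 0.5 else "TAG"), 1: "T", 2: "TA"}[rem]
    n_codons = (size - 3 - len(stop)) // 3
    body = "".join(rng.choice(codons, size=n_codons, p=probs))
    return "ATG" + body + stop, {0: stop, 1: "T_incomplete", 2: "TA_incomplete"}[rem]


def _atrich_block(cfg: SimConfig, size: int) -> tuple[str, dict]:
    """AT-rich block with planted motifs at recorded offsets (0-based)."""
    rng = cfg.rng("atrich")
    at = cfg.at_rich_percent
    a_share = cfg.composition[0] / (cfg.composition[0] + cfg.composition[1])
    comp = (at * a_share, at * (1 - a_share), (100 - at) / 2, (100 - at) / 2)
    plants: list[tuple[str, str, dict]] = []  # (kind, seq, info)
    for unit, copies in cfg.planted_repeats:
        plants.append(("tandem", unit * copies, {"unit": unit, "copies": copies}))
    for base, length in cfg.planted_homopolymers:
        plants.append(("homopolymer", base * length, {"unit": base, "copies": length}))
    for stem, loop, mism in cfg.planted_hairpins:
        arm = "".join(rng.choice(list("GC"), size=stem))  # GC arms: no accidental match
        arm2 = list(reverse_complement(arm))
        for i in rng.choice(stem, size=mism, replace=False):
            arm2[i] = {"G": "A", "C": "T"}[arm2[i]]  # break the pair
        plants.append(
            ("hairpin", arm + sample_sequence(comp, loop, rng) + "".join(arm2),
             {"stem_len": stem, "loop_len": loop, "mismatches": mism}),
        )
    def _pick(exclude: set[str]) -> str:
        for c in "GC":
            if c not in exclude:
                return c
        return "G"

    def _guards(kind: str, s: str, info: dict) -> tuple[str, str]:
        # Guard bases are chosen so that no repeat period or hairpin stem can
        # extend across the plant boundary, keeping planted coordinates exact.
        if kind == "tandem":
            unit = info["unit"]
            return "GC" + _pick({unit[-1]}), _pick({unit[0]}) + "CG"
        if kind == "homopolymer":
            return "GC" + _pick({s[0]}), _pick({s[0]}) + "CG"
        # hairpin: flanking bases must not form an extra outer stem pair
        return "GCG", "GCG"

    need = sum(len(s) + 6 for _, s, _ in plants)  # 3 nt guard each side
    if need > size:
        raise ValueError(f"planted motifs need {need} nt but block has {size}")
    spare = size - need
    n_gaps = len(plants) + 1
    gaps = [spare // n_gaps] * n_gaps
    gaps[-1] += spare - sum(gaps)
    parts: list[str] = []
    truth: list[dict] = []
    pos = 0
    for gap, (kind, s, info) in zip(gaps, plants):
        left, right = _guards(kind, s, info)
        filler = sample_sequence(comp, gap, rng)
        parts += [filler, left, s, right]
        pos += gap + len(left)
        truth.append({"kind": kind, "offset": pos, "length": len(s), **info})
        pos += len(s) + len(right)
    parts.append(sample_sequence(comp, gaps[-1], rng))
    return "".join(parts), {"target_at_percent": at, "plants": truth}


def generate_mitogenome(cfg: SimConfig) -> tuple[str, MitogenomeAnnotation, dict]:
    """Build (sequence, annotation, ground_truth) for one synthetic genome."""
    sizes = {name: size for name, _, size in REFERENCE_LAYOUT}
    stop_rng = cfg.rng("stops")
    incomplete: dict[str, bool] = {}
    for name, klass, _ in REFERENCE_LAYOUT:
        if klass == "protein":
            make_inc = stop_rng.random() < cfg.incomplete_stop_fraction
            incomplete[name] = make_inc
            if make_inc and sizes[name] % 3 == 0:
                sizes[name] -= 2  # drop stop to the incomplete 'T' form
    fixed = sum(sizes[n] for n, k, _ in REFERENCE_LAYOUT if k != "noncoding")
    block_size = cfg.genome_length - fixed
    if block_size < 0:
        raise ValueError(
            f"genes need {fixed} nt but genome_length is {cfg.genome_length}"
        )
    sizes["AT-rich"] = block_size

    bg_rng = cfg.rng("background")
    cds_rng = cfg.rng("cds")
    codons, probs = _codon_probs(cfg)
    block, block_truth = _atrich_block(cfg, block_size)

    seq_parts: list[str] = []
    feats: list[GeneFeature] = []
    truth_cds: dict[str, dict] = {}
    pos = 1
    for name, klass, _ in REFERENCE_LAYOUT:
        size = sizes[name]
        if klass == "protein":
            gene_seq, stop_kind = _make_cds(size, codons, probs, cds_rng)
            truth_cds[name] = {"stop": stop_kind, "length": size}
        elif klass == "noncoding":
            gene_seq = block
        else:
            gene_seq = sample_sequence(cfg.composition, size, bg_rng)
        strand = "L" if name in cfg.l_strand_genes else "H"
        if strand == "L":
            gene_seq = reverse_complement(gene_seq)
        seq_parts.append(gene_seq)
        if size > 0:
            feats.append(GeneFeature(name, klass, strand, pos, pos + size - 1))
        pos += size
    sequence = "".join(seq_parts)
    assert len(sequence) == cfg.genome_length
    annotation = MitogenomeAnnotation("synthetic", cfg.genome_length, feats)

    block_start = annotation.feature("AT-rich").start
    for p in block_truth["plants"]:
        p["start"] = block_start + p.pop("offset")  # 1-based genome coordinate
        p["end"] = p["start"] + p["length"] - 1
    order = GeneOrder(
        "synthetic",
        tuple(
            ("-" + n if n in cfg.l_strand_genes else n)
            for n, k, _ in REFERENCE_LAYOUT
            if k != "noncoding"
        ),
    )
    truth = {
        "config": cfg,
        "composition": cfg.composition,
        "at_rich": {"span": (block_start, block_start + block_size - 1), **block_truth},
        "cds": truth_cds,
        "gene_order": order,
        "codon_probs": dict(zip(codons, probs.tolist())),
    }
    return sequence, annotation, truth


def scramble_gene_order(order: GeneOrder, k: int, seed: int) -> tuple[GeneOrder, list]:
    """Apply k uniformly random signed reversals on the circle.

    Returns the scrambled order and the list of applied (start, length) arcs;
    reversal distance back to the input is therefore at most k.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    rng = np.random.Generator(
        np.random.PCG64(np.random.SeedSequence(seed, spawn_key=(_SUBSTREAMS["scramble"],)))
    )
    genes = list(order.genes)
    n = len(genes)
    ops = []
    for _ in range(k):
        start = int(rng.integers(0, n))
        length = int(rng.integers(1, n))  # 1..n-1: never the full circle
        idx = [(start + t) % n for t in range(length)]
        seg = [genes[i] for i in idx]
        seg = [("-" + t if not t.startswith("-") else t[1:]) for t in reversed(seg)]
        for i, t in zip(idx, seg):
            genes[i] = t
        ops.append((start, length))
    return replace(order, genes=tuple(genes)), ops
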