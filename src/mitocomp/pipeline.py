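"""Stage orchestration: run analysis stages over inputs, emit TSV/JSON.

Every report carries a provenance block echoing the decisions that could
differ between implementations (gap policy for %INUC, RSCU family mode,
common-interval anchors) plus the seed, so re-running a config reproduces
byte-identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .annotation import MitogenomeAnnotation, closure_check, overlap_pairs, parse_annotation_tsv
from .codon_usage import CodingSequence, codon_usage, rscu, count_used_codons, AMINO_ACID, _FAMILY_OF
from .composition import base_composition
from .gene_order import (
    ALL_GENES_ANCHOR,
    NON_TRNA_ANCHOR,
    distance_matrix,
    order_from_annotation,
    parse_gene_orders,
)
from .alignment import parse_fasta_alignment, percent_inuc, conservation_rank
from .noncoding import atrich_region_report
from .composition import reverse_complement

STAGES = ("annot", "composition", "codons", "order", "inuc", "repeats")


@dataclass
class RunConfig:
    stages: tuple[str, ...]
    output_dir: str
    annotations: tuple[str, ...] = ()
    fasta: str | None = None
    gene_orders: str | None = None
    alignments: tuple[str, ...] = ()
    gene_set: str = "all_genes"
    measure: str = "common_intervals"
    family_mode: str = "split"
    seed: int = 0
    params: dict = field(default_factory=dict)

    def validate(self) -> None:
        if not self.stages:
            raise ValueError("no stages requested")
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        needs = {
            "annot": self.annotations,
            "order": self.annotations or self.gene_orders,
            "composition": self.fasta,
            "codons": self.fasta and self.annotations,
            "inuc": self.alignments,
            "repeats": self.fasta and self.annotations,
        }
        for stage in self.stages:
            if not needs[stage]:
                raise ValueError(f"stage {stage!r}: required inputs missing")


def provenance(cfg: RunConfig) -> dict:
    return {
        "tool": f"mitocomp {__version__}",
        "seed": cfg.seed,
        "inuc_gap_policy": "column with any gap is non-identical",
        "rscu_family_mode": cfg.family_mode,
        "common_interval_convention": (
            "anchored linearization, sizes 2..n-2, doubled; "
            f"anchors: all_genes={ALL_GENES_ANCHOR}, non_tRNA={NON_TRNA_ANCHOR}"
        ),
    }


def _read_fasta(path: str) -> dict[str, str]:
    return parse_fasta_alignment(Path(path).read_text())


def _cds_from_annotation(ann: MitogenomeAnnotation, seq: str) -> list[CodingSequence]:
    out = []
    for f in ann.features:
        if f.gene_class != "protein":
            continue
        sub = seq[f.start - 1 : f.end]
        if f.strand == "L":
            sub = reverse_complement(sub)
        out.append(CodingSequence.from_nt(f.name, sub))
    return out


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute requested stages; per-stage failures are isolated in the bundle."""
    cfg.validate()
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle: dict = {"provenance": provenance(cfg), "stages": {}, "failures": {}}

    annotations = [parse_annotation_tsv(Path(p).read_text()) for p in cfg.annotations]
    seqs = _read_fasta(cfg.fasta) if cfg.fasta else {}

    for stage in cfg.stages:
        try:
            result = _run_stage(stage, cfg, annotations, seqs, outdir)
            bundle["stages"][stage] = result
        except Exception as exc:  # noqa: BLE001 — isolate stage failures
            bundle["failures"][stage] = str(exc)
    (outdir / "summary.json").write_text(json.dumps(bundle, indent=2, default=str))
    return bundle


def _run_stage(stage, cfg, annotations, seqs, outdir) -> dict:
    if stage == "annot":
        out = {}
        for ann in annotations:
            rep = closure_check(ann)
            rep["overlaps"] = overlap_pairs(ann)
            out[ann.genome_id] = rep
            pd.DataFrame(rep["features"]).to_csv(
                outdir / f"annot_{ann.genome_id}.tsv", sep="\t", index=False
            )
        return out

    if stage == "composition":
        rows = []
        for name, seq in seqs.items():
            st = base_composition(seq)
            rows.append({"species": name, "total_nt": st.total_nt, "T": st.pct_T,
                         "C": st.pct_C, "A": st.pct_A, "G": st.pct_G,
                         "A+T": st.pct_AT, "AT_skew": st.at_skew, "GC_skew": st.gc_skew})
        pd.DataFrame(rows).to_csv(outdir / "composition.tsv", sep="\t", index=False)
        return {"n_sequences": len(rows), "rows": rows}

    if stage == "codons":
        ann = annotations[0]
        seq = next(iter(seqs.values()))
        table = codon_usage(_cds_from_annotation(ann, seq), cfg.family_mode)
        r = rscu(table)
        fam_of = _FAMILY_OF[cfg.family_mode]
        cdspt = table.per_thousand()
        rows = [
            {"codon": c, "amino_acid": AMINO_ACID[c], "family": fam_of[c],
             "count": table.counts[c], "CDspT": round(cdspt[fam_of[c]], 2),
             "RSCU": (round(r[c], 3) if r[c] is not None else "NA")}
            for c in sorted(table.counts, key=lambda c: (fam_of[c], c))
        ]
        pd.DataFrame(rows).to_csv(outdir / "codon_usage.tsv", sep="\t", index=False)
        return {"total_cds": table.total_cds, "used_codons": count_used_codons(table),
                "errors": table.errors}

    if stage == "order":
        if cfg.gene_orders:
            orders = parse_gene_orders(Path(cfg.gene_orders).read_text(), cfg.gene_set)
        else:
            orders = [order_from_annotation(a, cfg.gene_set) for a in annotations]
        mat = distance_matrix(orders, cfg.measure)
        df = pd.DataFrame(mat.values, index=mat.taxa, columns=mat.taxa)
        df.to_csv(outdir / f"order_{cfg.measure}_{cfg.gene_set}.tsv", sep="\t")
        return {"measure": cfg.measure, "gene_set": cfg.gene_set,
                "taxa": mat.taxa, "values": mat.values}

    if stage == "inuc":
        profiles = []
        for path in cfg.alignments:
            aln = parse_fasta_alignment(Path(path).read_text())
            profiles.append(percent_inuc(aln, gene=Path(path).stem))
        bands = conservation_rank(profiles)
        pd.DataFrame(
            [{"gene": p.gene, "n_seqs": p.n_seqs, "aln_length": p.aln_length,
              "identical": p.identical_positions, "pct_inuc": p.pct_inuc}
             for p in profiles]
        ).to_csv(outdir / "inuc.tsv", sep="\t", index=False)
        return {"profiles": [(p.gene, p.pct_inuc) for p in profiles], "bands": bands}

    if stage == "repeats":
        ann = annotations[0]
        seq = next(iter(seqs.values()))
        rep = atrich_region_report(ann, seq)
        (outdir / "atrich_report.json").write_text(json.dumps(rep, indent=2, default=str))
        return {"span": rep["span"], "length": rep["length"],
                "n_tandem": len(rep.get("tandem_repeats", [])),
                "n_homopolymers": len(rep.get("homopolymers", [])),
                "n_hairpins": len(rep.get("hairpins", []))}

    raise ValueError(stage)
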