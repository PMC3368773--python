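"""Packaged reference tables (annotation tables, composition, %INUC, orders).

The annotation tables carry the published size and 3'-spacer columns as
reference metadata so self-consistency can be re-checked offline; the
composition and %INUC tables are packaged verbatim.  The bilaterian ground
pattern gene order is a reconstruction of the classic ancestral arrangement
(the original figure is a drawing) and is labelled as such in the data file.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .annotation import MitogenomeAnnotation, parse_annotation_tsv
from .alignment import AlignmentProfile
from .gene_order import GeneOrder, parse_gene_orders

__all__ = ["table_fixture_loader", "FIXTURE_NAMES"]

FIXTURE_NAMES = (
    "nmirabilis_table1",
    "zrubens_table1",
    "table2",
    "table3",
    "gene_orders",
)


def _read(fname: str) -> str:
    return (resources.files("mitocomp") / "data" / fname).read_text()


def table_fixture_loader(name: str):
    """Load a packaged fixture into its module type.

    =================  =====================================================
    name               returns
    =================  =====================================================
    nmirabilis_table1  MitogenomeAnnotation (38 features incl. AT-rich)
    zrubens_table1     MitogenomeAnnotation (38 features incl. AT-rich)
    table2             pandas.DataFrame of published composition rows
    table3             list[AlignmentProfile] (22 tRNA alignment summaries)
    gene_orders        dict[str, GeneOrder] incl. the ground-pattern
                       reconstruction
    =================  =====================================================
    """
    if name == "nmirabilis_table1":
        return parse_annotation_tsv(_read("table1_nmirabilis.tsv"))
    if name == "zrubens_table1":
        return parse_annotation_tsv(_read("table1_zrubens.tsv"))
    if name == "table2":
        import io

        return pd.read_csv(io.StringIO(_read("table2.tsv")), sep="\t")
    if name == "table3":
        import io

        df = pd.read_csv(io.StringIO(_read("table3.tsv")), sep="\t")
        profiles = [
            AlignmentProfile(
                gene=row.gene,
                n_seqs=6,
                aln_length=int(row.aln_length),
                identical_positions=int(row.identical),
            )
            for row in df.itertuples()
        ]
        return profiles, df
    if name == "gene_orders":
        return {o.genome_id: o for o in parse_gene_orders(_read("gene_orders.txt"))}
    raise KeyError(f"unknown fixture {name!r}; available: {FIXTURE_NAMES}")
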