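"""Promoter-window mapping of CpGs to genes and DMG calling.

A gene is a differentially methylated gene (DMG) when at least one
differentially methylated locus (DML) lies inside a promoter window of any
of its transcripts. The window spans -2500 to +500 bases around the TSS,
oriented in the direction of transcription, with inclusive ends.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd
from intervaltree import IntervalTree

from .io_formats import GeneModel

logger = logging.getLogger(__name__)

__all__ = [
    "PromoterWindow",
    "DMGSet",
    "promoter_window",
    "map_loci_to_genes",
    "call_dmgs",
    "write_dmg_set",
]


@dataclass(frozen=True)
class PromoterWindow:
    transcript_id: str
    chromosome: str
    start: int  # 1-based inclusive
    end: int
    strand: str


def promoter_window(
    model: GeneModel, up: int = 2500, down: int = 500
) -> PromoterWindow:
    """Promoter window of one transcript, oriented by strand.

    ``+`` strand: [tss - up, tss + down]; ``-`` strand: [tss - down, tss + up].
    A window reaching below position 1 is clipped with a warning.
    """
    if model.strand == "+":
        start, end = model.tss - up, model.tss + down
    else:
        start, end = model.tss - down, model.tss + up
    if start < 1:
        logger.warning(
            "promoter window of %s clipped at chromosome start", model.transcript_id
        )
        start = 1
    return PromoterWindow(model.transcript_id, model.chromosome, start, end, model.strand)


def map_loci_to_genes(
    annot: pd.DataFrame,
    models: list[GeneModel],
    up: int = 2500,
    down: int = 500,
) -> dict[str, set[str]]:
    """Map each CpG to the genes whose promoter windows contain it.

    ``annot`` is the CpG annotation frame (locus_id, chromosome, position).
    A locus maps to gene G when its position lies within any transcript
    window of G (inclusive ends); one locus may map to several genes.
    """
    trees: dict[str, IntervalTree] = {}
    for m in models:
        w = promoter_window(m, up=up, down=down)
        # interval end is exclusive in intervaltree
        trees.setdefault(w.chromosome, IntervalTree()).addi(
            w.start, w.end + 1, m.gene_symbol
        )
    multimap: dict[str, set[str]] = {}
    for locus, chrom, pos in annot[["locus_id", "chromosome", "position"]].itertuples(
        index=False
    ):
        tree = trees.get(chrom)
        if tree is None:
            continue
        hits = {iv.data for iv in tree.at(pos)}
        if hits:
            multimap[locus] = hits
    return multimap


@dataclass
class DMGSet:
    """Genes with >= 1 DML in a promoter window, with direction status.

    ``hyper``/``hypo`` when all supporting DMLs agree, ``mixed`` when the
    promoter carries both directions.
    """

    comparison_name: str
    genes: dict[str, str] = field(default_factory=dict)
    supporting: dict[str, list[tuple[str, str]]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.genes)


def _status(directions: set[str]) -> str:
    return directions.pop() if len(directions) == 1 else "mixed"


def call_dmgs(
    dml_table: pd.DataFrame,
    multimap: dict[str, set[str]],
    comparison_name: str = "",
) -> DMGSet:
    """Label DMGs from a locus test table and a locus->gene promoter map."""
    supporting: dict[str, list[tuple[str, str]]] = {}
    dml = dml_table[dml_table["is_dml"]]
    for locus, direction in dml["direction"].items():
        for gene in multimap.get(locus, ()):
            supporting.setdefault(gene, []).append((locus, direction))
    genes = {
        g: _status({d for _, d in loci}) for g, loci in supporting.items()
    }
    return DMGSet(comparison_name, genes, supporting)


def write_dmg_set(dmg: DMGSet, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# comparison: {dmg.comparison_name}\n")
        fh.write("gene\tstatus\tn_supporting\tsupporting_loci\n")
        for gene in sorted(dmg.genes):
            loci = dmg.supporting[gene]
            fh.write(
                f"{gene}\t{dmg.genes[gene]}\t{len(loci)}\t"
                + ",".join(f"{l}:{d}" for l, d in loci)
                + "\n"
            )
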