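"""Variant effect annotation against gene models.

Every variant receives exactly one region (CDS / intron / UTR5 / UTR3 /
intergenic) and one effect class.  Coding SNPs are re-translated with the
standard genetic code, strand-aware; the large-effect classes — premature
stop (stop_gain), initiator-methionine loss (start_loss), splice donor or
acceptor disruption (splice_disrupt) and annotated-stop loss (stop_loss) —
take precedence over the plain synonymous / non-synonymous split.  Coding
indels are frameshift when their length is not a multiple of three,
in-frame otherwise.  PAV and CNV calls are annotated at the gene level: a
gene is PAV-affected when an absence call overlaps its CDS by at least one
base, and CNV-affected when a call overlaps the gene body.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd
from Bio.Seq import Seq

from .models import (
    CnvCall,
    GeneModel,
    IndelCall,
    PavCall,
    SnpCall,
    VariantEffect,
)

log = logging.getLogger(__name__)

_STOPS = {"TAA", "TAG", "TGA"}
_COMP = str.maketrans("ACGT", "TGCA")


class GeneIndex:
    """Per-chromosome sorted gene lookup."""

    def __init__(self, genes: Sequence[GeneModel]):
        self.by_chrom: dict[str, list[GeneModel]] = {}
        for g in sorted(genes, key=lambda g: (g.chrom, g.start)):
            self.by_chrom.setdefault(g.chrom, []).append(g)
        self.by_id = {g.gene_id: g for g in genes}

    def overlapping(self, chrom: str, start: int, end: int) -> list[GeneModel]:
        out = []
        for g in self.by_chrom.get(chrom, []):
            if g.start < end and g.end > start:
                out.append(g)
            elif g.start >= end:
                break
        return out

    def at(self, chrom: str, pos: int) -> GeneModel | None:
        """Gene containing ``pos``; with overlapping annotations the gene
        with the longest CDS (canonical) wins."""
        hits = self.overlapping(chrom, pos, pos + 1)
        if not hits:
            return None
        return max(hits, key=lambda g: g.cds_length)


def locate_variant(
    chrom: str, pos: int, index: GeneIndex
) -> tuple[str | None, str]:
    """(gene_id, region) of a point position; splice dinucleotides count as
    intron (they are the first/last two intron bases)."""
    gene = index.at(chrom, pos)
    if gene is None:
        return None, "intergenic"
    return gene.gene_id, gene.region_of(pos)


def classify_snp_effect(
    snp: SnpCall,
    index: GeneIndex,
    reference: dict[str, str],
) -> VariantEffect:
    gene = index.at(snp.chrom, snp.pos)
    if gene is None:
        return VariantEffect(snp, None, None, "intergenic", "none")
    region = gene.region_of(snp.pos)

    if region == "intron":
        if snp.pos in gene.splice_site_positions():
            return VariantEffect(
                snp, gene.gene_id, gene.category, "intron", "splice_disrupt"
            )
        return VariantEffect(snp, gene.gene_id, gene.category, "intron", "none")
    if region in ("UTR5", "UTR3", "intergenic"):
        return VariantEffect(snp, gene.gene_id, gene.category, region, "none")

    # coding SNP: re-translate the affected codon
    if gene.cds_length % 3 != 0:
        log.warning("gene %s CDS length not divisible by 3; region-only annotation",
                    gene.gene_id)
        return VariantEffect(snp, gene.gene_id, gene.category, "CDS", "none")
    off = gene.cds_offset(snp.pos)
    cds = gene.cds_sequence(reference)
    ci = off // 3
    n_codons = len(cds) // 3
    codon = cds[3 * ci : 3 * ci + 3]
    alt_cds_base = snp.alt_base if gene.strand == "+" else snp.alt_base.translate(_COMP)
    within = off % 3
    new_codon = codon[:within] + alt_cds_base + codon[within + 1 :]
    change = f"{codon}>{new_codon}"

    if ci == 0:
        effect = "start_loss"
    elif ci == n_codons - 1:
        effect = "stop_loss" if new_codon not in _STOPS else "synonymous"
    elif new_codon in _STOPS:
        effect = "stop_gain"
    elif str(Seq(codon).translate()) == str(Seq(new_codon).translate()):
        effect = "synonymous"
    else:
        effect = "non_synonymous"
    return VariantEffect(snp, gene.gene_id, gene.category, "CDS", effect, change)


def classify_indel_effect(indel: IndelCall, index: GeneIndex) -> VariantEffect:
    gene = index.at(indel.chrom, indel.pos)
    if gene is None:
        return VariantEffect(indel, None, None, "intergenic", "none")
    region = gene.region_of(indel.pos)
    if region == "CDS":
        effect = "frameshift" if indel.length % 3 != 0 else "inframe_indel"
        return VariantEffect(indel, gene.gene_id, gene.category, "CDS", effect)
    if region == "intron":
        footprint = range(indel.pos, indel.pos + (indel.length if indel.type == "del" else 1))
        splice = gene.splice_site_positions()
        if any(p in splice for p in footprint):
            return VariantEffect(
                indel, gene.gene_id, gene.category, "intron", "splice_disrupt"
            )
        return VariantEffect(indel, gene.gene_id, gene.category, "intron", "none")
    return VariantEffect(indel, gene.gene_id, gene.category, region, "none")


@dataclass
class GeneSvRecord:
    gene_id: str
    gene_category: str
    pav_lines: set[str] = field(default_factory=set)
    cnv_gain_lines: set[str] = field(default_factory=set)
    cnv_loss_lines: set[str] = field(default_factory=set)


def annotate_sv_genes(
    pavs: Sequence[PavCall],
    cnvs: Sequence[CnvCall],
    genes: Sequence[GeneModel],
) -> pd.DataFrame:
    """Gene-level PAV/CNV annotation table.

    A gene is PAV-affected when an absence interval overlaps ≥1 base of its
    CDS; CNV-affected when a CNV overlaps the gene body.  Gain and loss
    directions are recorded per line, so a gene lost in some lines and
    amplified in others shows both.
    """
    index = GeneIndex(genes)
    records: dict[str, GeneSvRecord] = {}

    def rec(g: GeneModel) -> GeneSvRecord:
        return records.setdefault(g.gene_id, GeneSvRecord(g.gene_id, g.category))

    for pav in pavs:
        if pav.type != "absence":
            continue
        for g in index.overlapping(pav.chrom, pav.start, pav.end):
            if any(s < pav.end and e > pav.start for s, e in g.cds):
                rec(g).pav_lines.add(pav.line)
    for cnv in cnvs:
        for g in index.overlapping(cnv.chrom, cnv.start, cnv.end):
            if cnv.cnv_class == "gain":
                rec(g).cnv_gain_lines.add(cnv.line)
            else:
                rec(g).cnv_loss_lines.add(cnv.line)

    rows = []
    for r in sorted(records.values(), key=lambda r: r.gene_id):
        rows.append(
            {
                "gene_id": r.gene_id,
                "gene_category": r.gene_category,
                "pav_affected": bool(r.pav_lines),
                "pav_lines": ",".join(sorted(r.pav_lines)),
                "cnv_affected": bool(r.cnv_gain_lines or r.cnv_loss_lines),
                "cnv_gain_lines": ",".join(sorted(r.cnv_gain_lines)),
                "cnv_loss_lines": ",".join(sorted(r.cnv_loss_lines)),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "gene_category",
            "pav_affected",
            "pav_lines",
            "cnv_affected",
            "cnv_gain_lines",
            "cnv_loss_lines",
        ],
    )


def annotate_snps(
    snps: Sequence[SnpCall],
    genes: Sequence[GeneModel] | GeneIndex,
    reference: dict[str, str],
) -> list[VariantEffect]:
    index = genes if isinstance(genes, GeneIndex) else GeneIndex(genes)
    return [classify_snp_effect(s, index, reference) for s in snps]


def annotate_indels(
    indels: Sequence[IndelCall], genes: Sequence[GeneModel] | GeneIndex
) -> list[VariantEffect]:
    index = genes if isinstance(genes, GeneIndex) else GeneIndex(genes)
    return [classify_indel_effect(i, index) for i in indels]
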