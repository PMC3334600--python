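"""Selection of genes differentiating the sweet lines from the grain line.

Three channels feed the differentiating-gene set, with the reference
treated as a grain genome:

* **SNP channel** — a gene qualifies when it carries at least one site
  with the same position and alternate allele called non-synonymous in
  every sweet line; any gene that also contains a non-synonymous SNP in a
  grain line (at any position) is then removed.
* **Indel channel** — an identical coding indel (position, type, length,
  sequence) present in all sweet lines and absent from all grain lines.
* **PAV channel** — a CDS-overlapping absence shared (≥50% reciprocal
  overlap) by all sweet lines with no overlapping absence in any grain
  line.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .effects import GeneIndex
from .models import GeneModel, IndelCall, PavCall, VariantEffect


@dataclass(frozen=True)
class LineDesign:
    sweet_lines: tuple[str, ...]
    grain_lines: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.sweet_lines or not self.grain_lines:
            raise ValueError("sweet and grain line sets must be non-empty")
        if set(self.sweet_lines) & set(self.grain_lines):
            raise ValueError("sweet and grain line sets overlap")
        if len(self.sweet_lines) < 2:
            raise ValueError("at least two sweet lines are required")


@dataclass
class SweetGeneSet:
    by_snp: set[str] = field(default_factory=set)
    by_indel: set[str] = field(default_factory=set)
    by_pav: set[str] = field(default_factory=set)

    @property
    def union(self) -> set[str]:
        return self.by_snp | self.by_indel | self.by_pav

    def provenance(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for gene in sorted(self.union):
            chans = []
            if gene in self.by_snp:
                chans.append("snp")
            if gene in self.by_indel:
                chans.append("indel")
            if gene in self.by_pav:
                chans.append("pav")
            out[gene] = chans
        return out


def _nonsyn_sites_by_line(
    effects: Sequence[VariantEffect], large_effect_mode: bool = False
) -> dict[str, dict[str, set[tuple]]]:
    """line → gene → {(chrom, pos, alt)} of qualifying SNP sites."""
    qualifying = (
        {"stop_gain", "start_loss", "splice_disrupt", "stop_loss"}
        if large_effect_mode
        else {"non_synonymous"}
    )
    out: dict[str, dict[str, set[tuple]]] = {}
    for eff in effects:
        if eff.effect not in qualifying or eff.gene_id is None:
            continue
        v = eff.variant
        out.setdefault(v.line, {}).setdefault(eff.gene_id, set()).add(
            (v.chrom, v.pos, v.alt_base)
        )
    return out


def shared_sweet_snp_genes(
    effects: Sequence[VariantEffect],
    design: LineDesign,
    large_effect_mode: bool = False,
) -> set[str]:
    """Genes with a shared qualifying SNP (same site and allele) in every
    sweet line."""
    by_line = _nonsyn_sites_by_line(effects, large_effect_mode)
    first, *others = design.sweet_lines
    candidates: set[str] = set()
    for gene, sites in by_line.get(first, {}).items():
        shared = set(sites)
        for line in others:
            shared &= by_line.get(line, {}).get(gene, set())
        if shared:
            candidates.add(gene)
    return candidates


def exclude_grain(
    candidates: set[str],
    effects: Sequence[VariantEffect],
    design: LineDesign,
    large_effect_mode: bool = False,
) -> set[str]:
    """Drop candidates containing any qualifying SNP in any grain line
    (gene-level exclusion, regardless of position)."""
    by_line = _nonsyn_sites_by_line(effects, large_effect_mode)
    excluded: set[str] = set()
    for line in design.grain_lines:
        excluded |= set(by_line.get(line, {}))
    return candidates - excluded


def _reciprocal_overlap(a: tuple[int, int], b: tuple[int, int]) -> float:
    inter = min(a[1], b[1]) - max(a[0], b[0])
    if inter <= 0:
        return 0.0
    return min(inter / (a[1] - a[0]), inter / (b[1] - b[0]))


def sweet_by_indel_pav(
    indels: Mapping[str, Sequence[IndelCall]],
    pavs: Mapping[str, Sequence[PavCall]],
    genes: Sequence[GeneModel] | GeneIndex,
    design: LineDesign,
    min_reciprocal: float = 0.5,
) -> tuple[set[str], set[str]]:
    """Indel- and PAV-channel differentiating genes.

    ``indels``/``pavs`` map line → calls.  Indel sharing is exact identity
    of (chrom, pos, type, length, sequence); PAV sharing is ≥
    ``min_reciprocal`` reciprocal interval overlap.  Grain exclusion is
    call-level within the gene's CDS footprint.
    """
    index = genes if isinstance(genes, GeneIndex) else GeneIndex(genes)

    # --- indel channel -----------------------------------------------------
    def indel_key(c: IndelCall) -> tuple:
        return (c.chrom, c.pos, c.type, c.length, c.sequence)

    sweet_sets = [
        {indel_key(c) for c in indels.get(line, [])} for line in design.sweet_lines
    ]
    shared = set.intersection(*sweet_sets) if sweet_sets else set()
    grain_keys = {
        indel_key(c) for line in design.grain_lines for c in indels.get(line, [])
    }
    by_indel: set[str] = set()
    for key in shared - grain_keys:
        chrom, pos, typ, length, seq = key
        gene = index.at(chrom, pos)
        if gene is None or gene.region_of(pos) != "CDS":
            continue
        # grain exclusion at call level inside this gene's CDS footprint
        grain_hit = False
        for line in design.grain_lines:
            for c in indels.get(line, []):
                if c.chrom == chrom and index.at(c.chrom, c.pos) is gene and gene.region_of(c.pos) == "CDS":
                    grain_hit = True
        if not grain_hit:
            by_indel.add(gene.gene_id)

    # --- PAV channel -------------------------------------------------------
    by_pav: set[str] = set()
    first, *others = design.sweet_lines
    for pav in pavs.get(first, []):
        if pav.type != "absence":
            continue
        iv = (pav.start, pav.end)
        shared_all = all(
            any(
                p.chrom == pav.chrom
                and p.type == "absence"
                and _reciprocal_overlap(iv, (p.start, p.end)) >= min_reciprocal
                for p in pavs.get(line, [])
            )
            for line in others
        )
        if not shared_all:
            continue
        for gene in index.overlapping(pav.chrom, pav.start, pav.end):
            if not any(s < pav.end and e > pav.start for s, e in gene.cds):
                continue
            grain_hit = any(
                p.chrom == gene.chrom
                and p.type == "absence"
                and any(s < p.end and e > p.start for s, e in gene.cds)
                for line in design.grain_lines
                for p in pavs.get(line, [])
            )
            if not grain_hit:
                by_pav.add(gene.gene_id)
    return by_indel, by_pav


def select_sweet_genes(
    effects: Sequence[VariantEffect],
    indels: Mapping[str, Sequence[IndelCall]],
    pavs: Mapping[str, Sequence[PavCall]],
    genes: Sequence[GeneModel] | GeneIndex,
    design: LineDesign,
    large_effect_mode: bool = False,
    min_reciprocal: float = 0.5,
) -> SweetGeneSet:
    """Full three-channel selection of sweet-vs-grain differentiating genes."""
    candidates = shared_sweet_snp_genes(effects, design, large_effect_mode)
    by_snp = exclude_grain(candidates, effects, design, large_effect_mode)
    by_indel, by_pav = sweet_by_indel_pav(indels, pavs, genes, design, min_reciprocal)
    return SweetGeneSet(by_snp=by_snp, by_indel=by_indel, by_pav=by_pav)
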