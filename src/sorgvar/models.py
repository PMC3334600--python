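"""Core domain types shared across the variation-discovery pipeline.

Coordinates are 0-based, half-open everywhere inside the package; the I/O
layer (`sorgvar.alignio`) converts at the boundaries of 1-based formats
(SAM, VCF, GFF3).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

from Bio.Seq import Seq

GENE_CATEGORIES = ("bona_fide", "low_confidence", "transposon", "pseudogene")

#: SNP / indel effect classes.  ``LARGE_EFFECT`` classes are those predicted
#: to disable a gene product outright.
LARGE_EFFECT = ("stop_gain", "start_loss", "splice_disrupt", "stop_loss")

EFFECTS = (
    "synonymous",
    "non_synonymous",
    *LARGE_EFFECT,
    "frameshift",
    "inframe_indel",
    "gene_absent",
    "copy_change",
    "none",
)

REGIONS = ("CDS", "intron", "UTR5", "UTR3", "intergenic")


# ---------------------------------------------------------------------------
# Gene models
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneModel:
    """A protein-coding gene model on the reference genome.

    ``exons`` and ``cds`` are lists of 0-based half-open genomic intervals,
    sorted by genomic coordinate regardless of strand.  For minus-strand
    genes the coding sequence is the reverse complement of the concatenated
    ``cds`` intervals read right to left.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds: tuple[tuple[int, int], ...]
    category: str = "bona_fide"
    pfam: tuple[str, ...] = ()
    pathways: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if self.category not in GENE_CATEGORIES:
            raise ValueError(f"unknown gene category {self.category!r}")

    # -- derived structure -------------------------------------------------

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        """Genomic intervals between consecutive exons."""
        out = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 > e1:
                out.append((e1, s2))
        return tuple(out)

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds)

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def cds_sequence(self, reference: dict[str, str]) -> str:
        """Spliced coding sequence in translation order (5'→3' of the mRNA)."""
        chrom_seq = reference[self.chrom]
        parts = [chrom_seq[s:e] for s, e in self.cds]
        seq = "".join(parts)
        if self.strand == "-":
            seq = str(Seq(seq).reverse_complement())
        return seq

    def cds_offset(self, pos: int) -> int | None:
        """Map a genomic position to its 0-based offset in the coding sequence.

        Returns ``None`` when ``pos`` does not fall inside an annotated CDS
        interval.
        """
        off = 0
        if self.strand == "+":
            for s, e in self.cds:
                if s <= pos < e:
                    return off + (pos - s)
                off += e - s
            return None
        for s, e in reversed(self.cds):
            if s <= pos < e:
                return off + (e - 1 - pos)
            off += e - s
        return None

    def genomic_pos(self, cds_offset: int) -> int:
        """Inverse of :meth:`cds_offset` (raises when out of range)."""
        off = cds_offset
        if self.strand == "+":
            for s, e in self.cds:
                if off < e - s:
                    return s + off
                off -= e - s
        else:
            for s, e in reversed(self.cds):
                if off < e - s:
                    return e - 1 - off
                off -= e - s
        raise IndexError(f"CDS offset {cds_offset} outside gene {self.gene_id}")

    def region_of(self, pos: int) -> str:
        """Region label of a genomic position relative to this gene."""
        if not (self.start <= pos < self.end):
            return "intergenic"
        for s, e in self.cds:
            if s <= pos < e:
                return "CDS"
        for s, e in self.introns:
            if s <= pos < e:
                return "intron"
        # inside an exon but not CDS → UTR; side depends on strand
        cds_start = self.cds[0][0]
        cds_end = self.cds[-1][1]
        if pos < cds_start:
            return "UTR5" if self.strand == "+" else "UTR3"
        if pos >= cds_end:
            return "UTR3" if self.strand == "+" else "UTR5"
        return "intron"  # exon-annotation gap; treat as intronic

    def splice_site_positions(self) -> set[int]:
        """Genomic positions of the canonical donor/acceptor dinucleotides.

        The first and last two bases of every intron (GT…AG on the coding
        strand).
        """
        out: set[int] = set()
        for s, e in self.introns:
            if e - s >= 4:
                out.update((s, s + 1, e - 2, e - 1))
        return out


# ---------------------------------------------------------------------------
# Variant calls
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SnpCall:
    chrom: str
    pos: int  # 0-based
    ref_base: str
    alt_base: str
    line: str
    zygosity: str  # "hom_alt" | "het"
    genotype_quality: float
    depth: int
    novel_allele_mean_quality: float
    mean_mapping_multiplicity: float
    ref_support: int = 0
    alt_support: int = 0

    def __post_init__(self) -> None:
        if self.alt_base == self.ref_base:
            raise ValueError("alt allele equals reference")
        if self.depth < 1:
            raise ValueError("SNP call with zero depth")
        if self.zygosity == "het" and (self.ref_support < 3 or self.alt_support < 3):
            raise ValueError("heterozygous call without >=3 reads per allele")


@dataclass(frozen=True)
class IndelCall:
    chrom: str
    pos: int  # 0-based position of the first deleted base / insertion point
    type: str  # "ins" | "del"
    length: int
    sequence: str
    line: str
    gapped_support: int = 0
    crossing_ungapped: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.length <= 10:
            raise ValueError(f"indel length {self.length} outside [1, 10]")
        if self.type not in ("ins", "del"):
            raise ValueError(f"bad indel type {self.type!r}")
        if len(self.sequence) != self.length:
            raise ValueError("indel sequence length mismatch")


@dataclass(frozen=True)
class PavCall:
    chrom: str
    start: int
    end: int
    type: str  # "absence" | "insertion_signal"
    supporting_pairs: int
    line: str

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("empty PAV interval")
        if self.supporting_pairs < 6:
            raise ValueError("final PAV with fewer than 6 supporting pairs")


@dataclass(frozen=True)
class CnvCall:
    chrom: str
    start: int
    end: int
    mean_depth_ratio: float
    p_value: float
    cnv_class: str  # "gain" | "loss"
    line: str

    @property
    def length(self) -> int:
        return self.end - self.start

    def __post_init__(self) -> None:
        if self.length <= 2000:
            raise ValueError("CNV not longer than 2 kb")
        if self.p_value > 0.35:
            raise ValueError("CNV p-value above 0.35")
        if 0.5 <= self.mean_depth_ratio <= 2.0:
            raise ValueError("CNV depth ratio inside the normal band")
        if self.cnv_class not in ("gain", "loss"):
            raise ValueError(f"bad CNV class {self.cnv_class!r}")


@dataclass(frozen=True)
class VariantEffect:
    """Gene-level consequence of a single variant call."""

    variant: object
    gene_id: str | None
    gene_category: str | None
    region: str
    effect: str
    codon_change: str | None = None  # "ACG>ATG" style, coding SNPs only

    def __post_init__(self) -> None:
        if self.region not in REGIONS:
            raise ValueError(f"unknown region {self.region!r}")
        if self.effect not in EFFECTS:
            raise ValueError(f"unknown effect {self.effect!r}")

    @property
    def is_large_effect(self) -> bool:
        return self.effect in LARGE_EFFECT


# ---------------------------------------------------------------------------
# Truth bookkeeping for the simulator
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TruthSnp:
    line: str
    chrom: str
    pos: int
    ref_base: str
    alt_base: str
    zygosity: str  # "hom" | "het"
    region: str = "intergenic"
    effect: str = "none"
    gene_id: str | None = None


@dataclass(frozen=True)
class TruthIndel:
    line: str
    chrom: str
    pos: int
    type: str  # "ins" | "del"
    length: int
    sequence: str
    region: str = "intergenic"
    gene_id: str | None = None


@dataclass(frozen=True)
class TruthPav:
    line: str
    chrom: str
    start: int
    end: int


@dataclass(frozen=True)
class TruthCnv:
    line: str
    chrom: str
    start: int
    end: int
    copy_ratio: float


@dataclass
class TruthSet:
    """Planted variants — the oracle every caller is graded against."""

    snps: list[TruthSnp] = field(default_factory=list)
    indels: list[TruthIndel] = field(default_factory=list)
    pavs: list[TruthPav] = field(default_factory=list)
    cnvs: list[TruthCnv] = field(default_factory=list)
    #: gene_id → channel ("snp" | "indel" | "pav") for the planted
    #: sweet-vs-grain contrast
    sweet_genes: dict[str, str] = field(default_factory=dict)

    def validate(self, chrom_lengths: dict[str, int]) -> None:
        for s in self.snps:
            if not 0 <= s.pos < chrom_lengths[s.chrom]:
                raise ValueError(f"SNP outside genome: {s}")
        for i in self.indels:
            if not 1 <= i.length <= 10:
                raise ValueError(f"indel length outside [1,10]: {i}")
            if not 0 <= i.pos < chrom_lengths[i.chrom]:
                raise ValueError(f"indel outside genome: {i}")
        for p in self.pavs:
            if p.end - p.start < 1000:
                raise ValueError(f"PAV shorter than 1 kb: {p}")
            if not 0 <= p.start < p.end <= chrom_lengths[p.chrom]:
                raise ValueError(f"PAV outside genome: {p}")
        for c in self.cnvs:
            if c.end - c.start < 2000:
                raise ValueError(f"CNV segment shorter than 2 kb: {c}")
            if not 0 <= c.start < c.end <= chrom_lengths[c.chrom]:
                raise ValueError(f"CNV outside genome: {c}")
        self._check_no_same_class_overlap()

    def _check_no_same_class_overlap(self) -> None:
        def overlaps(ivs: list[tuple[str, str, int, int]]) -> None:
            by_key: dict[tuple[str, str], list[tuple[int, int]]] = {}
            for line, chrom, s, e in ivs:
                by_key.setdefault((line, chrom), []).append((s, e))
            for key, spans in by_key.items():
                spans.sort()
                for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                    if s2 < e1:
                        raise ValueError(
                            f"overlapping planted variants of one class in {key}"
                        )

        overlaps([(s.line, s.chrom, s.pos, s.pos + 1) for s in self.snps])
        overlaps(
            [
                (i.line, i.chrom, i.pos, i.pos + (i.length if i.type == "del" else 1))
                for i in self.indels
            ]
        )
        overlaps([(p.line, p.chrom, p.start, p.end) for p in self.pavs])
        overlaps([(c.line, c.chrom, c.start, c.end) for c in self.cnvs])


# ---------------------------------------------------------------------------
# Alignment substrate
# ---------------------------------------------------------------------------


@dataclass
class AlignmentRecord:
    """One aligned read of a proper pair, in reference coordinates.

    ``cigar`` is a list of ``(op, length)`` with ops in {"M", "I", "D"};
    at most one I or D of length 1–10 occurs per read (gapped alignment).
    """

    read_id: str
    chrom: str
    pos: int  # 0-based leftmost reference position
    strand: str  # "+" | "-"
    cigar: list[tuple[str, int]]
    seq: str
    quals: list[int]
    mate_chrom: str
    mate_pos: int
    observed_span: int  # outer fragment span on the reference
    is_read1: bool = True
    duplicate: bool = False
    multiplicity: int = 1  # count of equally-good placements ("mappable sites")

    @property
    def ref_end(self) -> int:
        """0-based exclusive end on the reference."""
        return self.pos + sum(n for op, n in self.cigar if op in "MD")

    @property
    def gap(self) -> tuple[str, int, int, str] | None:
        """(type, ref_pos, length, sequence) of the alignment gap, if any."""
        rpos = self.pos
        qpos = 0
        for op, n in self.cigar:
            if op == "M":
                rpos += n
                qpos += n
            elif op == "D":
                return ("del", rpos, n, "")
            elif op == "I":
                return ("ins", rpos, n, self.seq[qpos : qpos + n])
        return None


@dataclass
class BaseEvidence:
    count: int = 0
    quality_sum: float = 0.0
    forward: int = 0

    @property
    def reverse(self) -> int:
        return self.count - self.forward

    @property
    def mean_quality(self) -> float:
        return self.quality_sum / self.count if self.count else 0.0


@dataclass
class PileupColumn:
    """Per-site evidence for one line: allele counts, qualities, strands."""

    chrom: str
    pos: int
    ref_base: str
    bases: dict[str, BaseEvidence] = field(default_factory=dict)
    multiplicity_sum: float = 0.0

    @property
    def depth(self) -> int:
        return sum(b.count for b in self.bases.values())

    @property
    def mean_multiplicity(self) -> float:
        d = self.depth
        return self.multiplicity_sum / d if d else 0.0

    def top_alt(self) -> tuple[str, int]:
        """Most frequent non-reference base and its count (ties → lexical)."""
        best, n = "", 0
        for base in sorted(self.bases):
            if base == self.ref_base:
                continue
            c = self.bases[base].count
            if c > n:
                best, n = base, c
        return best, n
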