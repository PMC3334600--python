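"""Format I/O and pileup construction.

Reads and writes the standard formats the pipeline touches — FASTA, GFF3,
SAM, VCF 4.x, BED — and converts between their coordinate conventions and
the package's internal 0-based half-open coordinates.  Also builds the
per-site pileups that SNP calling consumes, and flags redundant (duplicate)
read pairs so every caller counts non-redundant evidence.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import (
    AlignmentRecord,
    BaseEvidence,
    CnvCall,
    GeneModel,
    IndelCall,
    PavCall,
    PileupColumn,
    SnpCall,
)

log = logging.getLogger(__name__)

_BASES = "ACGT"
_BASE_CODE = {b: i for i, b in enumerate(_BASES)}

#: custom SAM tag carrying the number of equally-good placements of a read
MULTIPLICITY_TAG = "XM"


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def load_reference(path: str | Path) -> dict[str, str]:
    """Load a FASTA into a dict of upper-cased sequences keyed by name."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seqs[rec.id] = str(rec.seq).upper()
    if not seqs:
        raise ValueError(f"no FASTA records in {path}")
    return seqs


def write_reference(seqs: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# GFF3 gene models
# ---------------------------------------------------------------------------


def write_gene_models(genes: Sequence[GeneModel], path: str | Path) -> None:
    """Write gene models as GFF3 (1-based inclusive coordinates).

    Category, Pfam families and pathway memberships travel as attributes of
    the gene feature.
    """
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.chrom, g.start)):
            attrs = [f"ID={g.gene_id}", f"category={g.category}"]
            if g.pfam:
                attrs.append("pfam=" + ",".join(g.pfam))
            if g.pathways:
                attrs.append("pathway=" + ",".join(g.pathways))
            fh.write(
                f"{g.chrom}\tsorgvar\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\t{';'.join(attrs)}\n"
            )
            mrna = f"{g.gene_id}.1"
            fh.write(
                f"{g.chrom}\tsorgvar\tmRNA\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={mrna};Parent={g.gene_id}\n"
            )
            for s, e in g.exons:
                fh.write(
                    f"{g.chrom}\tsorgvar\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                    f"Parent={mrna}\n"
                )
            for s, e in g.cds:
                fh.write(
                    f"{g.chrom}\tsorgvar\tCDS\t{s + 1}\t{e}\t.\t{g.strand}\t0\t"
                    f"Parent={mrna}\n"
                )


def load_gene_models(path: str | Path) -> list[GeneModel]:
    """Parse GFF3 gene/mRNA/exon/CDS features into :class:`GeneModel` objects.

    Genes lacking a ``category`` attribute default to ``bona_fide`` (with a
    logged warning).  Overlapping CDS segments within one mRNA are an error,
    as is a CDS interval not contained in an exon.
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    genes: list[GeneModel] = []
    for g in db.features_of_type("gene"):
        gene_id = g.id
        category = g.attributes.get("category", [None])[0]
        if category is None:
            log.warning("gene %s missing category attribute; assuming bona_fide", gene_id)
            category = "bona_fide"
        def attr_list(key: str) -> tuple[str, ...]:
            out: list[str] = []
            for v in g.attributes.get(key, []):
                out.extend(x for x in v.split(",") if x)
            return tuple(out)

        pfam = attr_list("pfam")
        pathways = attr_list("pathway")
        mrnas = list(db.children(g, featuretype="mRNA"))
        best: tuple[int, tuple, tuple] | None = None
        for m in mrnas or [g]:
            exons = sorted(
                (f.start - 1, f.end) for f in db.children(m, featuretype="exon")
            )
            cds = sorted((f.start - 1, f.end) for f in db.children(m, featuretype="CDS"))
            for (s1, e1), (s2, e2) in zip(cds, cds[1:]):
                if s2 < e1:
                    raise ValueError(f"overlapping CDS segments in {gene_id}")
            for s, e in cds:
                if not any(xs <= s and e <= xe for xs, xe in exons):
                    raise ValueError(f"CDS outside exon bounds in {gene_id}")
            cds_len = sum(e - s for s, e in cds)
            # canonical transcript = longest CDS
            if best is None or cds_len > best[0]:
                best = (cds_len, tuple(exons), tuple(cds))
        if best is None or not best[2]:
            continue
        genes.append(
            GeneModel(
                gene_id=gene_id,
                chrom=g.seqid,
                start=g.start - 1,
                end=g.end,
                strand=g.strand,
                exons=best[1],
                cds=best[2],
                category=category,
                pfam=pfam,
                pathways=pathways,
            )
        )
    return genes


# ---------------------------------------------------------------------------
# SAM
# ---------------------------------------------------------------------------


def _sam_header(chrom_lengths: dict[str, int]) -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": c, "LN": n} for c, n in chrom_lengths.items()],
        }
    )


def write_sam(
    records: Iterable[AlignmentRecord],
    chrom_lengths: dict[str, int],
    path: str | Path,
) -> None:
    """Write coordinate-sorted alignment records as SAM."""
    header = _sam_header(chrom_lengths)
    tid = {c: i for i, c in enumerate(chrom_lengths)}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for rec in records:
            a = pysam.AlignedSegment(header)
            a.query_name = rec.read_id
            a.reference_id = tid[rec.chrom]
            a.reference_start = rec.pos
            a.mapping_quality = 60
            a.cigarstring = "".join(f"{n}{op}" for op, n in rec.cigar)
            a.query_sequence = rec.seq
            a.query_qualities = pysam.qualitystring_to_array(
                "".join(chr(q + 33) for q in rec.quals)
            )
            flag = 0x1 | 0x2  # paired, proper pair
            if rec.strand == "-":
                flag |= 0x10
            else:
                flag |= 0x20  # mate reverse for FR pairs
            flag |= 0x40 if rec.is_read1 else 0x80
            if rec.strand == "-":
                flag &= ~0x20
            if rec.duplicate:
                flag |= 0x400
            a.flag = flag
            a.next_reference_id = tid[rec.mate_chrom]
            a.next_reference_start = rec.mate_pos
            a.template_length = rec.observed_span if rec.pos <= rec.mate_pos else -rec.observed_span
            a.set_tag(MULTIPLICITY_TAG, rec.multiplicity)
            out.write(a)


def iter_sam(path: str | Path) -> Iterator[AlignmentRecord]:
    """Stream alignment records from a SAM/BAM file."""
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for a in fh:
            if a.is_unmapped:
                continue
            cigar = [( "MIDNSHP=X"[op], n) for op, n in a.cigartuples or []]
            quals = list(a.query_qualities) if a.query_qualities is not None else []
            yield AlignmentRecord(
                read_id=a.query_name,
                chrom=a.reference_name,
                pos=a.reference_start,
                strand="-" if a.is_reverse else "+",
                cigar=cigar,
                seq=a.query_sequence or "",
                quals=quals,
                mate_chrom=a.next_reference_name or a.reference_name,
                mate_pos=a.next_reference_start,
                observed_span=abs(a.template_length),
                is_read1=a.is_read1,
                duplicate=a.is_duplicate,
                multiplicity=int(a.get_tag(MULTIPLICITY_TAG))
                if a.has_tag(MULTIPLICITY_TAG)
                else 1,
            )


def load_sam(path: str | Path) -> list[AlignmentRecord]:
    return list(iter_sam(path))


def mark_duplicates(records: Sequence[AlignmentRecord]) -> int:
    """Flag redundant pairs in place; returns the number flagged.

    Pairs with identical (chrom, start, mate start, strand of the leftmost
    read) beyond the first are duplicates.  All callers downstream count
    non-redundant pairs only.
    """
    seen: set[tuple] = set()
    dup_ids: set[str] = set()
    for rec in records:
        if not rec.is_read1:
            continue
        key = (rec.chrom, rec.pos, rec.mate_chrom, rec.mate_pos, rec.strand)
        if key in seen:
            dup_ids.add(rec.read_id)
        else:
            seen.add(key)
    n = 0
    for rec in records:
        if rec.read_id in dup_ids:
            rec.duplicate = True
            n += 1
    return n


# ---------------------------------------------------------------------------
# Pileup
# ---------------------------------------------------------------------------


class PileupArrays:
    """Dense per-base pileup for one line and one chromosome.

    Built in one vectorised pass; duplicate-flagged reads are excluded.
    ``counts[b, i]`` is the number of reads with base code ``b`` at position
    ``i``; ``qual_sums`` and ``forward`` are parallel; ``mult_sums`` holds
    the summed mapping multiplicity of covering reads.
    """

    def __init__(self, chrom: str, length: int) -> None:
        self.chrom = chrom
        self.length = length
        self.counts = np.zeros((4, length), dtype=np.int32)
        self.qual_sums = np.zeros((4, length), dtype=np.float64)
        self.forward = np.zeros((4, length), dtype=np.int32)
        self.mult_sums = np.zeros(length, dtype=np.float64)

    @property
    def depth(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def column(self, pos: int, ref_base: str) -> PileupColumn:
        col = PileupColumn(chrom=self.chrom, pos=pos, ref_base=ref_base)
        for code, base in enumerate(_BASES):
            c = int(self.counts[code, pos])
            if c:
                col.bases[base] = BaseEvidence(
                    count=c,
                    quality_sum=float(self.qual_sums[code, pos]),
                    forward=int(self.forward[code, pos]),
                )
        col.multiplicity_sum = float(self.mult_sums[pos])
        return col


def _encode(seq: str) -> np.ndarray:
    codes = np.frombuffer(seq.encode(), dtype=np.uint8)
    out = np.full(codes.shape, 255, dtype=np.uint8)
    for base, code in _BASE_CODE.items():
        out[codes == ord(base)] = code
    return out


def pileup_arrays(
    records: Sequence[AlignmentRecord], chrom: str, length: int
) -> PileupArrays:
    """Accumulate a full-chromosome pileup with `np.bincount` batching."""
    pa = PileupArrays(chrom, length)
    pos_chunks: list[np.ndarray] = []
    code_chunks: list[np.ndarray] = []
    qual_chunks: list[np.ndarray] = []
    fwd_chunks: list[np.ndarray] = []
    mult_chunks: list[np.ndarray] = []
    for rec in records:
        if rec.duplicate or rec.chrom != chrom:
            continue
        rpos = rec.pos
        qpos = 0
        for op, n in rec.cigar:
            if op == "M":
                positions = np.arange(rpos, rpos + n, dtype=np.int64)
                codes = _encode(rec.seq[qpos : qpos + n])
                quals = np.asarray(rec.quals[qpos : qpos + n], dtype=np.float64)
                valid = codes != 255
                pos_chunks.append(positions[valid])
                code_chunks.append(codes[valid].astype(np.int64))
                qual_chunks.append(quals[valid])
                fwd_chunks.append(
                    np.full(int(valid.sum()), 1 if rec.strand == "+" else 0, dtype=np.int64)
                )
                mult_chunks.append(
                    np.full(int(valid.sum()), rec.multiplicity, dtype=np.float64)
                )
                rpos += n
                qpos += n
            elif op == "D":
                rpos += n  # deleted reference bases get no base contribution
            elif op == "I":
                qpos += n
    if not pos_chunks:
        return pa
    positions = np.concatenate(pos_chunks)
    codes = np.concatenate(code_chunks)
    quals = np.concatenate(qual_chunks)
    fwd = np.concatenate(fwd_chunks)
    mult = np.concatenate(mult_chunks)
    flat = codes * length + positions
    n4 = 4 * length
    pa.counts = np.bincount(flat, minlength=n4).reshape(4, length).astype(np.int32)
    pa.qual_sums = np.bincount(flat, weights=quals, minlength=n4).reshape(4, length)
    pa.forward = (
        np.bincount(flat, weights=fwd, minlength=n4).reshape(4, length).astype(np.int32)
    )
    pa.mult_sums = np.bincount(positions, weights=mult, minlength=length)
    return pa


def build_pileup(
    records: Sequence[AlignmentRecord],
    reference: dict[str, str],
    region: tuple[str, int, int] | None = None,
) -> Iterator[PileupColumn]:
    """Yield one :class:`PileupColumn` per covered reference base.

    ``records`` must be coordinate-sorted; duplicate-flagged reads are
    excluded.  ``region`` is (chrom, start, end), 0-based half-open; when
    omitted, every covered chromosome is scanned in order.
    """
    last = (None, -1)
    for rec in records:
        key = (rec.chrom, rec.pos)
        if rec.duplicate:
            continue
        if last[0] == rec.chrom and rec.pos < last[1]:
            raise ValueError("alignments are not coordinate-sorted")
        last = key

    chroms = [region[0]] if region else sorted({r.chrom for r in records})
    for chrom in chroms:
        length = len(reference[chrom])
        pa = pileup_arrays(records, chrom, length)
        depth = pa.depth
        if region:
            lo, hi = region[1], region[2]
        else:
            lo, hi = 0, length
        covered = np.nonzero(depth[lo:hi])[0] + lo
        ref = reference[chrom]
        for pos in covered:
            yield pa.column(int(pos), ref[pos])


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------


def write_snp_vcf(
    calls: Sequence[SnpCall],
    reference: dict[str, str],
    path: str | Path,
    line: str | None = None,
) -> None:
    """Write SNP calls for one line as VCF 4.2 (INFO DP/NQ/MM, FORMAT GT:GQ)."""
    sample = line or (calls[0].line if calls else "sample")
    header = pysam.VariantHeader()
    for chrom, seq in reference.items():
        header.contigs.add(chrom, length=len(seq))
    header.add_meta(
        "INFO", items=[("ID", "DP"), ("Number", 1), ("Type", "Integer"), ("Description", "Depth")]
    )
    header.add_meta(
        "INFO",
        items=[("ID", "NQ"), ("Number", 1), ("Type", "Float"), ("Description", "Novel allele mean quality")],
    )
    header.add_meta(
        "INFO",
        items=[("ID", "MM"), ("Number", 1), ("Type", "Float"), ("Description", "Mean mapping multiplicity")],
    )
    header.add_meta(
        "FORMAT", items=[("ID", "GT"), ("Number", 1), ("Type", "String"), ("Description", "Genotype")]
    )
    header.add_meta(
        "FORMAT", items=[("ID", "GQ"), ("Number", 1), ("Type", "Integer"), ("Description", "Genotype quality")]
    )
    header.add_sample(sample)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for c in sorted(calls, key=lambda c: (c.chrom, c.pos)):
            pos = c.pos  # 0-based; pysam writes start as 0-based internally
            rec = out.new_record(
                contig=c.chrom,
                start=pos,
                stop=pos + 1,
                alleles=(c.ref_base, c.alt_base),
            )
            rec.info["DP"] = c.depth
            rec.info["NQ"] = round(c.novel_allele_mean_quality, 2)
            rec.info["MM"] = round(c.mean_mapping_multiplicity, 4)
            rec.samples[sample]["GT"] = (0, 1) if c.zygosity == "het" else (1, 1)
            rec.samples[sample]["GQ"] = int(min(c.genotype_quality, 2147483647))
            out.write(rec)


def read_snp_vcf(path: str | Path) -> list[SnpCall]:
    calls: list[SnpCall] = []
    with pysam.VariantFile(str(path)) as fh:
        sample = list(fh.header.samples)[0]
        for rec in fh:
            gt = rec.samples[sample]["GT"]
            zyg = "het" if gt == (0, 1) else "hom_alt"
            calls.append(
                SnpCall(
                    chrom=rec.contig,
                    pos=rec.start,
                    ref_base=rec.ref,
                    alt_base=rec.alts[0],
                    line=sample,
                    zygosity=zyg,
                    genotype_quality=float(rec.samples[sample]["GQ"]),
                    depth=int(rec.info["DP"]),
                    novel_allele_mean_quality=float(rec.info["NQ"]),
                    mean_mapping_multiplicity=float(rec.info["MM"]),
                    ref_support=3 if zyg == "het" else 0,
                    alt_support=3 if zyg == "het" else 0,
                )
            )
    return calls


def write_indel_vcf(
    calls: Sequence[IndelCall],
    reference: dict[str, str],
    path: str | Path,
    line: str | None = None,
) -> None:
    """Write indel calls as VCF with the anchored-base REF/ALT convention.

    A deletion of k bases at 0-based pos p is written at 1-based POS=p with
    REF of k+1 bases (anchor + deleted) and a 1-base ALT.
    """
    sample = line or (calls[0].line if calls else "sample")
    header = pysam.VariantHeader()
    for chrom, seq in reference.items():
        header.contigs.add(chrom, length=len(seq))
    header.add_meta(
        "INFO", items=[("ID", "GS"), ("Number", 1), ("Type", "Integer"), ("Description", "Gapped support")]
    )
    header.add_meta(
        "INFO",
        items=[("ID", "CU"), ("Number", 1), ("Type", "Integer"), ("Description", "Crossing ungapped reads")],
    )
    header.add_sample(sample)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for c in sorted(calls, key=lambda c: (c.chrom, c.pos)):
            anchor_pos = c.pos - 1  # 0-based anchor base before the event
            ref_seq = reference[c.chrom]
            anchor = ref_seq[anchor_pos]
            if c.type == "del":
                ref_allele = anchor + ref_seq[c.pos : c.pos + c.length]
                alt_allele = anchor
            else:
                ref_allele = anchor
                alt_allele = anchor + c.sequence
            rec = out.new_record(
                contig=c.chrom,
                start=anchor_pos,
                stop=anchor_pos + len(ref_allele),
                alleles=(ref_allele, alt_allele),
            )
            rec.info["GS"] = c.gapped_support
            rec.info["CU"] = c.crossing_ungapped
            out.write(rec)


def read_indel_vcf(path: str | Path) -> list[IndelCall]:
    calls: list[IndelCall] = []
    with pysam.VariantFile(str(path)) as fh:
        sample = list(fh.header.samples)[0] if list(fh.header.samples) else "sample"
        for rec in fh:
            ref_a, alt_a = rec.ref, rec.alts[0]
            if len(ref_a) > len(alt_a):
                typ, length, seq = "del", len(ref_a) - 1, ref_a[1:]
            else:
                typ, length, seq = "ins", len(alt_a) - 1, alt_a[1:]
            calls.append(
                IndelCall(
                    chrom=rec.contig,
                    pos=rec.start + 1,
                    type=typ,
                    length=length,
                    sequence=seq,
                    line=sample,
                    gapped_support=int(rec.info["GS"]),
                    crossing_ungapped=int(rec.info["CU"]),
                )
            )
    return calls


# ---------------------------------------------------------------------------
# BED (PAV / CNV)
# ---------------------------------------------------------------------------


def write_sv_bed(
    pavs: Sequence[PavCall], cnvs: Sequence[CnvCall], path: str | Path
) -> None:
    """Write PAVs and CNVs as BED6+ (0-based half-open).

    name = class; score = supporting pairs (PAV) or p-value (CNV); column 7
    carries the line, column 8 the CNV depth ratio (. for PAVs).
    """
    rows = []
    for p in pavs:
        rows.append((p.chrom, p.start, p.end, p.type, p.supporting_pairs, "+", p.line, "."))
    for c in cnvs:
        rows.append(
            (c.chrom, c.start, c.end, c.cnv_class, repr(c.p_value), "+", c.line, repr(c.mean_depth_ratio))
        )
    rows.sort(key=lambda r: (r[0], r[1]))
    with open(path, "w") as fh:
        for r in rows:
            fh.write("\t".join(str(x) for x in r) + "\n")


def read_sv_bed(path: str | Path) -> tuple[list[PavCall], list[CnvCall]]:
    pavs: list[PavCall] = []
    cnvs: list[CnvCall] = []
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "name", "score", "strand", "line", "ratio"],
        dtype={"chrom": str, "name": str, "line": str},
    )
    for row in df.itertuples(index=False):
        if row.name in ("absence", "insertion_signal"):
            pavs.append(
                PavCall(
                    chrom=row.chrom,
                    start=int(row.start),
                    end=int(row.end),
                    type=row.name,
                    supporting_pairs=int(row.score),
                    line=row.line,
                )
            )
        else:
            cnvs.append(
                CnvCall(
                    chrom=row.chrom,
                    start=int(row.start),
                    end=int(row.end),
                    cnv_class=row.name,
                    p_value=float(row.score),
                    mean_depth_ratio=float(row.ratio),
                    line=row.line,
                )
            )
    return pavs, cnvs


def write_bedgraph(depth: np.ndarray, chrom: str, path: str | Path) -> None:
    """Write a per-base depth track as bedGraph (run-length compressed)."""
    change = np.nonzero(np.diff(depth))[0] + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [len(depth)]))
    with open(path, "w") as fh:
        for s, e in zip(starts, ends):
            fh.write(f"{chrom}\t{s}\t{e}\t{int(depth[s])}\n")


def parse_region(text: str) -> tuple[str, int, int]:
    """Parse a 1-based inclusive ``chrom:start-end`` into 0-based half-open."""
    chrom, _, span = text.partition(":")
    if not span:
        raise ValueError(f"bad region {text!r}")
    lo, _, hi = span.partition("-")
    start, end = int(lo.replace(",", "")) - 1, int(hi.replace(",", ""))
    if start < 0 or end <= start:
        raise ValueError(f"bad region {text!r}")
    return chrom, start, end
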