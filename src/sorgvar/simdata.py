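"""Synthetic resequencing data generator.

Emulates the study design the callers are built for: three resequenced
diploid inbred sorghum-like lines at ~12× depth of 44-bp paired-end reads
with ~500-bp inserts, aligned against a reference genome that carries
annotated gene models.  Each line's genome differs from the reference by
planted SNPs (with a small residual-heterozygosity rate, as expected for
inbreds), 1–10-bp indels, kb-scale absences (PAVs) and ≥2-kb copy-number
segments.  The generator emits already-aligned, coordinate-sorted SAM
records rather than FASTQ, so no external aligner is needed; alignment
noise is modelled by the base error rate and a configurable fraction of
multi-mappable reads.

All outputs are deterministic functions of the :class:`SimConfig`
(including its seed).
"""

from __future__ import annotations

import dataclasses
from bisect import bisect_right, bisect_left
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from Bio.Seq import Seq
from intervaltree import IntervalTree

from .models import (
    AlignmentRecord,
    GeneModel,
    TruthCnv,
    TruthIndel,
    TruthPav,
    TruthSet,
    TruthSnp,
)

_BASES = "ACGT"
_STOPS = ("TAA", "TAG", "TGA")
_SENSE_CODONS = tuple(
    a + b + c
    for a in _BASES
    for b in _BASES
    for c in _BASES
    if a + b + c not in _STOPS
)

_COMP = str.maketrans("ACGT", "TGCA")


def _revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


def _translate(cds: str) -> str:
    return str(Seq(cds).translate())


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class SimConfig:
    """Study-design parameters of the simulation.

    Read geometry and depth default to the sequencing design the callers
    target: 44-bp paired-end reads, ~500-bp inserts, ~12× per line.
    """

    genome_length: int = 1_000_000
    n_chromosomes: int = 2
    gc_fraction: float = 0.44
    n_genes: int = 150
    gene_category_mix: tuple[float, float, float, float] = (0.8, 0.1, 0.05, 0.05)
    intron_mean: float = 444.0  # mean intron size (sorghum-like)
    read_length: int = 44
    insert_mean: int = 500
    insert_sd: float = 50.0
    depth_per_line: float = 12.0
    base_error_rate: float = 0.005
    residual_het: float = 0.02  # fraction of planted SNPs left heterozygous
    duplicate_rate: float = 0.02
    multimap_fraction: float = 0.05
    lines: tuple[str, ...] = ("grain1", "sweet1", "sweet2")
    sweet_lines: tuple[str, ...] = ("sweet1", "sweet2")
    # planted variant budget, per line
    snps_per_line: int = 600
    coding_nonsyn_per_line: int = 25
    coding_syn_per_line: int = 20
    indels_per_line: int = 50
    coding_indels_per_line: int = 8
    intergenic_pavs_per_line: int = 2
    genic_pavs_per_line: int = 1
    cnv_ratios: tuple[float, ...] = (0.0, 3.0, 2.5)
    # sweet-vs-grain planted contrast: genes with shared variants in exactly
    # the sweet lines, split across the three detection channels
    sweet_snp_genes: int = 6
    sweet_indel_genes: int = 2
    sweet_pav_genes: int = 2
    #: plant one SNP of each large-effect class per line (off only for
    #: empty-landscape runs)
    guarantee_effect_classes: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.genome_length <= 0:
            raise ValueError("genome_length must be positive")
        if self.n_chromosomes <= 0:
            raise ValueError("n_chromosomes must be positive")
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise ValueError("gc_fraction outside [0, 1]")
        if abs(sum(self.gene_category_mix) - 1.0) > 1e-9:
            raise ValueError("gene_category_mix must sum to 1")
        if self.read_length >= self.insert_mean:
            raise ValueError("read_length must be smaller than insert_mean")
        if self.depth_per_line <= 0:
            raise ValueError("depth_per_line must be positive")
        if len(self.lines) < 2:
            raise ValueError("at least two lines required")
        if not set(self.sweet_lines) < set(self.lines):
            raise ValueError("sweet_lines must be a proper subset of lines")

    @property
    def grain_lines(self) -> tuple[str, ...]:
        return tuple(l for l in self.lines if l not in self.sweet_lines)

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        fields = {f.name: f for f in dataclasses.fields(cls)}
        kwargs = {}
        for k, v in d.items():
            if k not in fields:
                raise ValueError(f"unknown config key {k!r}")
            if isinstance(v, list):
                v = tuple(v)
            kwargs[k] = v
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg


def _chrom_lengths(config: SimConfig) -> dict[str, int]:
    n = config.n_chromosomes
    base = config.genome_length // n
    lengths = [base] * n
    lengths[-1] += config.genome_length - base * n
    return {f"chr{i + 1}": L for i, L in enumerate(lengths)}


# ---------------------------------------------------------------------------
# Genome
# ---------------------------------------------------------------------------


def simulate_genome(config: SimConfig) -> dict[str, str]:
    """Random reference sequences with the configured GC content."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    gc = config.gc_fraction
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    out: dict[str, str] = {}
    for chrom, length in _chrom_lengths(config).items():
        codes = rng.choice(4, size=length, p=p)
        out[chrom] = "".join(_BASES[c] for c in codes) if length < 10000 else (
            np.frombuffer(b"ACGT", dtype=np.uint8)[codes].tobytes().decode()
        )
    return out


# ---------------------------------------------------------------------------
# Gene models
# ---------------------------------------------------------------------------

PFAM_FAMILIES = tuple(f"PF{i:04d}" for i in range(1, 26))
PATHWAYS = tuple(f"sbi{100 + 10 * i:05d}" for i in range(12))


def sample_intron_length(rng: np.random.Generator, mean: float = 444.0) -> int:
    """Intron length: 60-bp floor plus an exponential tail, mean == ``mean``."""
    return 60 + int(rng.exponential(mean - 60))


def _build_gene_sequence(
    rng: np.random.Generator, config: SimConfig
) -> tuple[str, list[tuple[int, int]], list[tuple[int, int]]]:
    """One gene in gene-local plus-strand coordinates.

    Returns (sequence, exon intervals, CDS intervals); the CDS starts ATG,
    ends with a stop codon, and introns have canonical GT/AG boundaries.
    """
    n_codons = int(rng.integers(80, 320))
    cds = "ATG" + "".join(
        _SENSE_CODONS[i] for i in rng.integers(0, len(_SENSE_CODONS), n_codons - 2)
    ) + _STOPS[rng.integers(0, 3)]
    n_introns = min(int(rng.poisson(2.0)), 6)
    cds_len = len(cds)
    # split CDS into n_introns+1 pieces, each at least 30 bases
    while True:
        cuts = sorted(rng.integers(30, cds_len - 30, n_introns)) if n_introns else []
        if all(b - a >= 30 for a, b in zip([0] + cuts, cuts + [cds_len])):
            break
    utr5 = "".join(_BASES[c] for c in rng.integers(0, 4, int(rng.integers(40, 200))))
    utr3 = "".join(_BASES[c] for c in rng.integers(0, 4, int(rng.integers(60, 250))))
    pieces = []
    prev = 0
    for cut in list(cuts) + [cds_len]:
        pieces.append(cds[prev:cut])
        prev = cut

    seq_parts = [utr5]
    exons: list[tuple[int, int]] = []
    cds_ivs: list[tuple[int, int]] = []
    cursor = len(utr5)
    first_exon_start = 0
    for i, piece in enumerate(pieces):
        cds_ivs.append((cursor, cursor + len(piece)))
        seq_parts.append(piece)
        cursor += len(piece)
        if i < len(pieces) - 1:
            exons.append((first_exon_start, cursor))
            ilen = sample_intron_length(rng, config.intron_mean)
            intron = (
                "GT"
                + "".join(_BASES[c] for c in rng.integers(0, 4, ilen - 4))
                + "AG"
            )
            seq_parts.append(intron)
            cursor += ilen
            first_exon_start = cursor
    seq_parts.append(utr3)
    cursor += len(utr3)
    exons.append((first_exon_start, cursor))
    return "".join(seq_parts), exons, cds_ivs


def simulate_gene_models(
    config: SimConfig, genome: dict[str, str]
) -> tuple[list[GeneModel], dict[str, str]]:
    """Place non-overlapping gene models and write their sequence into the
    genome.

    Returns the gene models and the updated reference (gene loci replace the
    random background sequence so coding invariants hold on the reference).
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 1)
    lengths = _chrom_lengths(config)
    total = sum(lengths.values())
    per_chrom = {
        c: max(1, round(config.n_genes * L / total)) for c, L in lengths.items()
    }
    # adjust rounding drift
    drift = config.n_genes - sum(per_chrom.values())
    first = next(iter(per_chrom))
    per_chrom[first] += drift

    categories = rng.choice(
        4, size=config.n_genes, p=list(config.gene_category_mix)
    )
    cat_names = ("bona_fide", "low_confidence", "transposon", "pseudogene")

    genes: list[GeneModel] = []
    new_genome = dict(genome)
    gi = 0
    for chrom, n in per_chrom.items():
        L = lengths[chrom]
        built = []
        for _ in range(n):
            built.append(_build_gene_sequence(rng, config))
        span = sum(len(s) for s, _, _ in built)
        # budget: 300-bp chromosome-end margins, a fixed 200-bp spacer per
        # gene, and the random intergenic gaps
        free = L - span - 600 - 200 * n
        if free < 100 * (n + 1):
            raise ValueError(
                f"genome too small for {n} genes on {chrom} "
                f"(need {span + 600 + 300 * n} bases, have {L})"
            )
        gaps = rng.exponential(1.0, n + 1)
        gaps = np.floor(gaps / gaps.sum() * free).astype(int)
        seq = list(new_genome[chrom])
        cursor = 300 + int(gaps[0])
        for k, (gseq, exons, cds_ivs) in enumerate(built):
            strand = "+" if rng.random() < 0.5 else "-"
            glen = len(gseq)
            if strand == "-":
                gseq = _revcomp(gseq)
                exons = sorted((glen - e, glen - s) for s, e in exons)
                cds_ivs = sorted((glen - e, glen - s) for s, e in cds_ivs)
            start = cursor
            seq[start : start + glen] = gseq
            genes.append(
                GeneModel(
                    gene_id=f"SbS{gi + 1:05d}",
                    chrom=chrom,
                    start=start,
                    end=start + glen,
                    strand=strand,
                    exons=tuple((start + s, start + e) for s, e in exons),
                    cds=tuple((start + s, start + e) for s, e in cds_ivs),
                    category=cat_names[categories[gi]],
                    pfam=_sample_pfam(rng),
                    pathways=_sample_pathways(rng),
                )
            )
            gi += 1
            cursor += glen + 200 + int(gaps[k + 1])
        new_genome[chrom] = "".join(seq)
    return genes, new_genome


def _sample_pfam(rng: np.random.Generator) -> tuple[str, ...]:
    k = rng.choice([0, 1, 2], p=[0.3, 0.55, 0.15])
    if k == 0:
        return ()
    # skewed family sizes: low-index families are large
    w = np.array([1.0 / (i + 1) for i in range(len(PFAM_FAMILIES))])
    w /= w.sum()
    idx = rng.choice(len(PFAM_FAMILIES), size=k, replace=False, p=w)
    return tuple(sorted(PFAM_FAMILIES[i] for i in idx))


def _sample_pathways(rng: np.random.Generator) -> tuple[str, ...]:
    k = rng.choice([0, 1, 2], p=[0.45, 0.45, 0.1])
    if k == 0:
        return ()
    idx = rng.choice(len(PATHWAYS), size=k, replace=False)
    return tuple(sorted(PATHWAYS[i] for i in idx))


# ---------------------------------------------------------------------------
# Variant planting
# ---------------------------------------------------------------------------


@dataclass
class _Allocator:
    """Tracks occupied intervals so planted variants never collide."""

    per_line: dict[tuple[str, str], IntervalTree] = field(default_factory=dict)
    global_structural: dict[str, IntervalTree] = field(default_factory=dict)

    def line_tree(self, line: str, chrom: str) -> IntervalTree:
        return self.per_line.setdefault((line, chrom), IntervalTree())

    def struct_tree(self, chrom: str) -> IntervalTree:
        return self.global_structural.setdefault(chrom, IntervalTree())

    def free_for_line(self, line: str, chrom: str, start: int, end: int) -> bool:
        return not self.line_tree(line, chrom).overlap(start, end) and not self.struct_tree(
            chrom
        ).overlap(start, end)

    def reserve_line(self, line: str, chrom: str, start: int, end: int) -> None:
        self.line_tree(line, chrom).addi(start, end)

    def reserve_struct(self, chrom: str, start: int, end: int) -> None:
        self.struct_tree(chrom).addi(start, end)


_SNP_PAD = 8  # planted SNPs of one line keep at least this spacing
_INDEL_PAD = 60  # indels keep clear of reads over neighbouring variants
_STRUCT_MARGIN = 650  # structural events keep > insert size from anything else


class _Crafter:
    """Crafts coding SNPs of a requested effect class inside a gene."""

    def __init__(self, reference: dict[str, str], rng: np.random.Generator):
        self.ref = reference
        self.rng = rng

    def snp(self, gene: GeneModel, kind: str) -> tuple[int, str, str] | None:
        """Return (genomic pos, ref base, alt base) or None if impossible."""
        if kind == "splice_disrupt":
            return self._splice(gene)
        cds = gene.cds_sequence(self.ref)
        n_codons = len(cds) // 3
        if kind == "start_loss":
            idx_pool = [0]
        elif kind == "stop_loss":
            idx_pool = [n_codons - 1]
        else:
            idx_pool = list(self.rng.permutation(np.arange(1, n_codons - 1)))
        for ci in idx_pool:
            codon = cds[3 * ci : 3 * ci + 3]
            for off in self.rng.permutation(3):
                for alt in self.rng.permutation(list(_BASES)):
                    if alt == codon[off]:
                        continue
                    new = codon[:off] + alt + codon[off + 1 :]
                    if not self._matches(kind, codon, new, ci, n_codons):
                        continue
                    cds_off = 3 * ci + int(off)
                    pos = gene.genomic_pos(cds_off)
                    ref_base = self.ref[gene.chrom][pos]
                    alt_base = alt if gene.strand == "+" else _revcomp(alt)
                    return pos, ref_base, alt_base
        return None

    @staticmethod
    def _matches(kind: str, old: str, new: str, ci: int, n_codons: int) -> bool:
        old_stop, new_stop = old in _STOPS, new in _STOPS
        if kind == "synonymous":
            return (
                not old_stop
                and not new_stop
                and _translate(old) == _translate(new)
            )
        if kind == "non_synonymous":
            return (
                not old_stop
                and not new_stop
                and _translate(old) != _translate(new)
            )
        if kind == "stop_gain":
            return not old_stop and new_stop and ci < n_codons - 1
        if kind == "start_loss":
            return ci == 0
        if kind == "stop_loss":
            return old_stop and not new_stop
        raise ValueError(kind)

    def _splice(self, gene: GeneModel) -> tuple[int, str, str] | None:
        introns = gene.introns
        if not introns:
            return None
        order = self.rng.permutation(len(introns))
        for i in order:
            s, e = introns[i]
            positions = [s, s + 1, e - 2, e - 1]
            pos = positions[self.rng.integers(0, 4)]
            ref_base = self.ref[gene.chrom][pos]
            alts = [b for b in _BASES if b != ref_base]
            return pos, ref_base, alts[self.rng.integers(0, 3)]
        return None


def plant_variants(
    config: SimConfig,
    genome: dict[str, str],
    genes: list[GeneModel],
) -> TruthSet:
    """Choose and record every planted variant for every line.

    Guarantees per line: at least one SNP of each large-effect class
    (premature stop, initiator-ATG loss, splice-site disruption, stop-codon
    loss) and of the synonymous / non-synonymous classes; indels spanning
    all lengths 1–10; PAV absences ≥1 kb; CNV segments ≥2 kb.  A configured
    subset of genes carries shared variants in exactly the sweet lines and
    none in the grain line, split across the SNP / indel / PAV channels.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 2)
    lengths = _chrom_lengths(config)
    truth = TruthSet()
    alloc = _Allocator()
    crafter = _Crafter(genome, rng)
    genes_by_id = {g.gene_id: g for g in genes}

    bona = [g for g in genes if g.category == "bona_fide"]
    with_introns = [g for g in bona if g.introns]
    if len(bona) < config.sweet_snp_genes + config.sweet_indel_genes + config.sweet_pav_genes + 8:
        raise ValueError("not enough bona fide genes for the requested planting")

    # ---- sweet-contrast genes (reserved from all other planting) ----------
    pool = [str(x) for x in rng.permutation([g.gene_id for g in bona if g.cds_length >= 240])]
    sweet_snp = [pool.pop() for _ in range(config.sweet_snp_genes)]
    sweet_indel = [pool.pop() for _ in range(config.sweet_indel_genes)]
    sweet_pav = [pool.pop() for _ in range(config.sweet_pav_genes)]
    for gid in sweet_snp + sweet_indel + sweet_pav:
        g = genes_by_id[gid]
        alloc.reserve_struct(g.chrom, g.start - _STRUCT_MARGIN, g.end + _STRUCT_MARGIN)
    for gid in sweet_snp:
        truth.sweet_genes[gid] = "snp"
    for gid in sweet_indel:
        truth.sweet_genes[gid] = "indel"
    for gid in sweet_pav:
        truth.sweet_genes[gid] = "pav"

    sweet = list(config.sweet_lines)

    def add_snp(line: str, gene: GeneModel | None, chrom: str, pos: int,
                ref_b: str, alt_b: str, effect: str, region: str,
                zygosity: str = "hom") -> None:
        truth.snps.append(
            TruthSnp(line, chrom, pos, ref_b, alt_b, zygosity, region, effect,
                     gene.gene_id if gene else None)
        )
        alloc.reserve_line(line, chrom, pos - _SNP_PAD, pos + _SNP_PAD + 1)

    # shared non-synonymous SNPs in the sweet pair; two independent sites
    # per gene so that one site lost to a read-level filter in one line
    # does not lose the gene
    for gid in sweet_snp:
        g = genes_by_id[gid]
        planted_sites: list[tuple[int, str, str]] = []
        for _ in range(40):
            if len(planted_sites) == 2:
                break
            got = crafter.snp(g, "non_synonymous")
            if got is None:
                continue
            pos, ref_b, alt_b = got
            if any(abs(pos - p) <= 2 * _SNP_PAD for p, _, _ in planted_sites):
                continue
            planted_sites.append((pos, ref_b, alt_b))
        if not planted_sites:
            raise ValueError(f"could not craft sweet SNP in {gid}")
        for pos, ref_b, alt_b in planted_sites:
            for line in sweet:
                add_snp(line, g, g.chrom, pos, ref_b, alt_b, "non_synonymous", "CDS")

    # shared coding indels in the sweet pair (frameshift and in-frame),
    # likewise two sites per gene
    for j, gid in enumerate(sweet_indel):
        g = genes_by_id[gid]
        planted_ind: list[TruthIndel] = []
        for length in (2 if j % 2 == 0 else 3, 6):
            for _ in range(40):
                ind = _craft_cds_indel(rng, g, genome, length)
                lo, hi = ind.pos - _INDEL_PAD, ind.pos + ind.length + _INDEL_PAD
                # the gene sits inside its own structural reservation, so
                # only per-line collisions matter here
                if not any(
                    alloc.line_tree(line, g.chrom).overlap(lo, hi) for line in sweet
                ):
                    planted_ind.append(ind)
                    for line in sweet:
                        alloc.reserve_line(line, g.chrom, lo, hi)
                    break
        if not planted_ind:
            raise ValueError(f"could not craft sweet indel in {gid}")
        for ind in planted_ind:
            for line in sweet:
                truth.indels.append(dataclasses.replace(ind, line=line))

    # shared PAVs deleting the gene in the sweet pair
    for gid in sweet_pav:
        g = genes_by_id[gid]
        start = max(0, g.start - 200)
        end = min(lengths[g.chrom], g.end + 200)
        if end - start < 1000:
            end = min(lengths[g.chrom], start + 1000)
        for line in sweet:
            truth.pavs.append(TruthPav(line, g.chrom, start, end))

    # ---- per-line crafted coding SNPs -------------------------------------
    # Sweet genes are off limits for everyone else (grain lines must never
    # gain a non-synonymous SNP there, and nothing may delete them), and the
    # sweet pair must not coincidentally share a private non-synonymous site.
    large_classes = ("stop_gain", "start_loss", "splice_disrupt", "stop_loss")
    crafted_genes: dict[str, set[str]] = {line: set() for line in config.lines}
    sweet_nonsyn_sites: set[tuple[str, int, str]] = set()
    candidates = [g for g in genes if g.gene_id not in truth.sweet_genes]
    for line in config.lines:
        wanted: list[str] = list(large_classes) if config.guarantee_effect_classes else []
        wanted += ["non_synonymous"] * config.coding_nonsyn_per_line
        wanted += ["synonymous"] * config.coding_syn_per_line
        order = list(rng.permutation(len(candidates)))
        ci = 0
        for kind in wanted:
            placed = False
            attempts = 0
            while not placed and attempts < 4 * len(candidates):
                g = candidates[order[ci % len(candidates)]]
                ci += 1
                attempts += 1
                if kind == "splice_disrupt" and not g.introns:
                    continue
                got = crafter.snp(g, kind)
                if got is None:
                    continue
                pos, ref_b, alt_b = got
                if not alloc.free_for_line(line, g.chrom, pos - _SNP_PAD, pos + _SNP_PAD + 1):
                    continue
                if kind == "non_synonymous" and line in sweet:
                    site = (g.gene_id, pos, alt_b)
                    if site in sweet_nonsyn_sites:
                        continue
                    sweet_nonsyn_sites.add(site)
                region = "intron" if kind == "splice_disrupt" else "CDS"
                add_snp(line, g, g.chrom, pos, ref_b, alt_b, kind, region)
                crafted_genes[line].add(g.gene_id)
                placed = True
            if not placed:
                raise ValueError(f"could not place a {kind} SNP for {line}")

    # ---- structural variants (global, non-overlapping slots) --------------
    # a gene deleted by a PAV in some line must not carry that same line's
    # crafted SNPs (they would be unrecoverable); structural slots stay
    # disjoint across lines so the sweet-contrast channels see no
    # coincidental cross-line sharing
    used_structural: set[str] = set()

    def pick_sacrificial(line: str, min_cds: int = 0) -> GeneModel:
        pool = [
            g for g in bona
            if g.gene_id not in truth.sweet_genes
            and g.gene_id not in crafted_genes[line]
            and g.gene_id not in used_structural
            and g.cds_length >= min_cds
        ]
        if not pool:
            raise ValueError(f"no sacrificial genes left for {line}")
        g = pool[rng.integers(0, len(pool))]
        used_structural.add(g.gene_id)
        return g

    def take_intergenic_slot(length: int) -> tuple[str, int] | None:
        for _ in range(400):
            chrom = list(lengths)[rng.integers(0, len(lengths))]
            L = lengths[chrom]
            start = int(rng.integers(400, L - length - 400))
            lo, hi = start - _STRUCT_MARGIN, start + length + _STRUCT_MARGIN
            if alloc.struct_tree(chrom).overlap(lo, hi):
                continue
            if any(g.start < hi and g.end > lo for g in genes if g.chrom == chrom):
                continue
            alloc.reserve_struct(chrom, lo, hi)
            return chrom, start
        return None

    for line in config.lines:
        # intergenic PAV absences
        for _ in range(config.intergenic_pavs_per_line):
            length = 1000 + int(rng.exponential(1394))
            length = min(length, 4000)
            slot = take_intergenic_slot(length)
            if slot is None:
                raise ValueError("no intergenic space left for PAVs")
            chrom, start = slot
            truth.pavs.append(TruthPav(line, chrom, start, start + length))
        # genic PAV (deletes a sacrificial gene's CDS in this line only)
        for _ in range(config.genic_pavs_per_line):
            g = pick_sacrificial(line)
            start = max(0, g.start - 150)
            end = min(lengths[g.chrom], max(g.end + 150, start + 1000))
            alloc.reserve_struct(g.chrom, start - _STRUCT_MARGIN, end + _STRUCT_MARGIN)
            truth.pavs.append(TruthPav(line, g.chrom, start, end))
        # CNV segments
        for ratio in config.cnv_ratios:
            length = 2400 + int(rng.exponential(1200))
            length = min(length, 6000)
            slot = take_intergenic_slot(length)
            if slot is None:
                raise ValueError("no intergenic space left for CNVs")
            chrom, start = slot
            truth.cnvs.append(TruthCnv(line, chrom, start, start + length, ratio))

    # ---- per-line indels ---------------------------------------------------
    for line in config.lines:
        if config.indels_per_line == 0:
            continue
        placed_lengths: list[int] = []
        # coding indels in sacrificial bona fide genes
        for j in range(config.coding_indels_per_line):
            g = pick_sacrificial(line, min_cds=120)
            length = (j % 10) + 1
            ind = _craft_cds_indel(rng, g, genome, length)
            if not alloc.free_for_line(line, g.chrom, ind.pos - _INDEL_PAD,
                                       ind.pos + ind.length + _INDEL_PAD):
                continue
            truth.indels.append(dataclasses.replace(ind, line=line))
            alloc.reserve_line(line, g.chrom, ind.pos - _INDEL_PAD, ind.pos + ind.length + _INDEL_PAD)
            placed_lengths.append(length)
        # non-coding indels: guarantee every length 1..10, then a decaying tail
        lengths_wanted = [l for l in range(1, 11) if l not in placed_lengths]
        n_extra = config.indels_per_line - config.coding_indels_per_line - len(lengths_wanted)
        w = np.exp(-0.35 * np.arange(1, 11))
        w /= w.sum()
        lengths_wanted += [int(l) for l in rng.choice(np.arange(1, 11), size=max(n_extra, 0), p=w)]
        for length in lengths_wanted:
            for _ in range(200):
                chrom = list(lengths)[rng.integers(0, len(lengths))]
                L = lengths[chrom]
                pos = int(rng.integers(400, L - 400))
                lo, hi = pos - _INDEL_PAD, pos + length + _INDEL_PAD
                if not alloc.free_for_line(line, chrom, lo, hi):
                    continue
                typ = "del" if rng.random() < 0.5 else "ins"
                if typ == "del":
                    seqv = genome[chrom][pos : pos + length]
                else:
                    seqv = "".join(_BASES[c] for c in rng.integers(0, 4, length))
                region, gid = _locate_noncoding(genes, chrom, pos)
                truth.indels.append(
                    TruthIndel(line, chrom, pos, typ, length, seqv, region, gid)
                )
                alloc.reserve_line(line, chrom, lo, hi)
                break

    # ---- background SNPs ---------------------------------------------------
    for line in config.lines:
        n_placed = sum(1 for s in truth.snps if s.line == line)
        n_needed = config.snps_per_line - n_placed
        tries = 0
        while n_needed > 0 and tries < 50 * config.snps_per_line:
            tries += 1
            chrom = list(lengths)[rng.integers(0, len(lengths))]
            L = lengths[chrom]
            pos = int(rng.integers(300, L - 300))
            if not alloc.free_for_line(line, chrom, pos - _SNP_PAD, pos + _SNP_PAD + 1):
                continue
            region, gid = _locate_noncoding(genes, chrom, pos)
            if region == "CDS" or region == "splice":
                continue  # coding effects come from the crafted set only
            ref_b = genome[chrom][pos]
            alts = [b for b in _BASES if b != ref_b]
            alt_b = alts[rng.integers(0, 3)]
            zyg = "het" if rng.random() < config.residual_het else "hom"
            gene = genes_by_id.get(gid) if gid else None
            add_snp(line, gene, chrom, pos, ref_b, alt_b, "none", region, zyg)
            n_needed -= 1
        if n_needed > 0:
            raise ValueError(f"could not place all SNPs for {line}")

    truth.validate(lengths)
    return truth


def _craft_cds_indel(
    rng: np.random.Generator, gene: GeneModel, genome: dict[str, str], length: int
) -> TruthIndel:
    """A coding indel well inside the gene's largest CDS interval."""
    s, e = max(gene.cds, key=lambda iv: iv[1] - iv[0])
    if e - s < length + 30:
        raise ValueError(f"CDS interval too small for indel in {gene.gene_id}")
    pos = int(rng.integers(s + 15, e - 15 - length))
    typ = "del" if rng.random() < 0.5 else "ins"
    if typ == "del":
        seqv = genome[gene.chrom][pos : pos + length]
    else:
        seqv = "".join(_BASES[c] for c in rng.integers(0, 4, length))
    return TruthIndel("", gene.chrom, pos, typ, length, seqv, "CDS", gene.gene_id)


def _locate_noncoding(
    genes: list[GeneModel], chrom: str, pos: int
) -> tuple[str, str | None]:
    for g in genes:
        if g.chrom == chrom and g.start <= pos < g.end:
            if pos in g.splice_site_positions():
                return "splice", g.gene_id
            return g.region_of(pos), g.gene_id
    return "intergenic", None


# ---------------------------------------------------------------------------
# Read/alignment simulation
# ---------------------------------------------------------------------------


@dataclass
class _Segment:
    m_start: int
    m_end: int
    ref_start: int | None  # None for inserted sequence


class _LineChromModel:
    """Mutated chromosome of one line plus the map back to the reference."""

    def __init__(
        self,
        chrom: str,
        ref_seq: str,
        snps_hom: list[TruthSnp],
        snps_het: list[TruthSnp],
        small_indels: list[TruthIndel],
        large_deletions: list[tuple[int, int]],
    ) -> None:
        self.chrom = chrom
        base = np.frombuffer(ref_seq.encode(), dtype=np.uint8).copy()
        for s in snps_hom:
            base[s.pos] = ord(s.alt_base)
        events: list[tuple[int, int, str, str]] = []  # (start, end, kind, payload)
        for ind in small_indels:
            if ind.type == "del":
                events.append((ind.pos, ind.pos + ind.length, "del", ""))
            else:
                events.append((ind.pos, ind.pos, "ins", ind.sequence))
        for s, e in large_deletions:
            events.append((s, e, "bigdel", ""))
        events.sort()

        parts: list[bytes] = []
        segments: list[_Segment] = []
        m_len = 0
        cursor = 0
        ref_to_m: list[tuple[int, int, int]] = []  # (ref_start, ref_end, m_start)

        def emit_match(upto: int) -> None:
            nonlocal m_len, cursor
            if upto > cursor:
                parts.append(base[cursor:upto].tobytes())
                segments.append(_Segment(m_len, m_len + upto - cursor, cursor))
                ref_to_m.append((cursor, upto, m_len))
                m_len += upto - cursor
                cursor = upto

        for start, end, kind, payload in events:
            emit_match(start)
            if kind in ("del", "bigdel"):
                cursor = end
            else:  # insertion
                parts.append(payload.encode())
                segments.append(_Segment(m_len, m_len + len(payload), None))
                m_len += len(payload)
        emit_match(len(base))

        self.seq = np.frombuffer(b"".join(parts), dtype=np.uint8).copy()
        self.segments = segments
        self._seg_starts = [s.m_start for s in segments]
        self._ref_ivs = ref_to_m
        self._ref_starts = [iv[0] for iv in ref_to_m]
        # heterozygous SNPs in mutated coordinates
        self.het_pos: list[int] = []
        self.het_alt: list[int] = []
        for s in snps_het:
            m = self.ref_to_m(s.pos)
            if m is not None:
                self.het_pos.append(m)
                self.het_alt.append(ord(s.alt_base))
        order = np.argsort(self.het_pos) if self.het_pos else []
        self.het_pos = [self.het_pos[i] for i in order] if len(order) else []
        self.het_alt = [self.het_alt[i] for i in order] if len(order) else []

    def ref_to_m(self, pos: int) -> int | None:
        i = bisect_right(self._ref_starts, pos) - 1
        if i < 0:
            return None
        s, e, m = self._ref_ivs[i]
        if s <= pos < e:
            return m + (pos - s)
        return None

    def map_read(
        self, m_s: int, m_e: int, min_anchor: int = 3, max_gap: int = 10
    ) -> tuple[int, list[tuple[str, int]]] | None:
        """Map a mutated-genome interval to a reference alignment.

        Returns (ref_pos, cigar) or None when the read is unmappable (it
        starts/ends inside an insertion, spans a deletion longer than
        ``max_gap`` — a PAV breakpoint — or anchors with < ``min_anchor``
        matched bases).
        """
        i = bisect_right(self._seg_starts, m_s) - 1
        ops: list[tuple[str, int]] = []
        ref_pos: int | None = None
        prev_ref_end: int | None = None
        while i < len(self.segments):
            seg = self.segments[i]
            if seg.m_start >= m_e:
                break
            lo = max(m_s, seg.m_start)
            hi = min(m_e, seg.m_end)
            if hi <= lo:
                i += 1
                continue
            if seg.ref_start is None:
                ops.append(("I", hi - lo))
            else:
                seg_ref = seg.ref_start + (lo - seg.m_start)
                if prev_ref_end is not None:
                    gap = seg_ref - prev_ref_end
                    if gap > 0:
                        if gap > max_gap:
                            return None
                        ops.append(("D", gap))
                if ref_pos is None:
                    ref_pos = seg_ref
                ops.append(("M", hi - lo))
                prev_ref_end = seg_ref + (hi - lo)
            i += 1
        if ref_pos is None or not ops:
            return None
        if ops[0][0] != "M" or ops[-1][0] != "M":
            return None
        if ops[0][1] < min_anchor or ops[-1][1] < min_anchor:
            return None
        # merge adjacent M ops (can arise from zero-length gaps)
        merged: list[tuple[str, int]] = []
        for op, n in ops:
            if merged and merged[-1][0] == op:
                merged[-1] = (op, merged[-1][1] + n)
            else:
                merged.append((op, n))
        n_gaps = sum(1 for op, _ in merged if op in "ID")
        if n_gaps > 1:
            return None  # one optional gap per read
        return ref_pos, merged


def simulate_alignments(
    config: SimConfig,
    genome: dict[str, str],
    truth: TruthSet,
) -> dict[str, list[AlignmentRecord]]:
    """Generate coordinate-sorted alignment records per line.

    Fragments are sampled from each line's mutated genome; reads map back
    to the reference with gapped alignments over planted indels, stretched
    pair spans over PAV deletions, and depth scaled by copy ratio over CNV
    segments.  Duplicate pairs are injected at the configured rate.
    """
    config.validate()
    lengths = _chrom_lengths(config)
    rl = config.read_length
    shift = (config.insert_mean - rl) // 2  # centres CNV depth modulation
    out: dict[str, list[AlignmentRecord]] = {}
    for li, line in enumerate(config.lines):
        rng = np.random.default_rng(config.seed + 1000 + li)
        records: list[AlignmentRecord] = []
        for chrom, L in lengths.items():
            snps_hom = [s for s in truth.snps if s.line == line and s.chrom == chrom and s.zygosity == "hom"]
            snps_het = [s for s in truth.snps if s.line == line and s.chrom == chrom and s.zygosity == "het"]
            indels = [i for i in truth.indels if i.line == line and i.chrom == chrom]
            bigdels = [(p.start, p.end) for p in truth.pavs if p.line == line and p.chrom == chrom]
            bigdels += [
                (c.start, c.end)
                for c in truth.cnvs
                if c.line == line and c.chrom == chrom and c.copy_ratio == 0.0
            ]
            model = _LineChromModel(chrom, genome[chrom], snps_hom, snps_het, indels, sorted(bigdels))
            cnv_rates = [
                (c.start, c.end, c.copy_ratio)
                for c in truth.cnvs
                if c.line == line and c.chrom == chrom and c.copy_ratio > 0.0
            ]
            records.extend(
                _sample_fragments(config, rng, line, model, cnv_rates, shift)
            )
        records.sort(key=lambda r: (r.chrom, r.pos, r.read_id, not r.is_read1))
        out[line] = records
    return out


def _rate_pieces(
    m_len: int,
    cnv_rates: list[tuple[int, int, float]],
    model: _LineChromModel,
    shift: int,
) -> list[tuple[int, int, float]]:
    """Piecewise-constant fragment-start rate multiplier over the mutated
    genome for partial losses (0 < ratio < 1); the suppression window is
    shifted left by half the inner fragment span so the depth trough is
    centred on the planted segment.  Gains are not rate-modulated — they
    are simulated as tandem-duplication fragments (see
    :func:`_sample_fragments`), which gives the sharp depth edges real
    duplications have."""
    pieces = [(0, m_len, 1.0)]
    for start, end, ratio in cnv_rates:
        if ratio >= 1.0:
            continue
        ms = model.ref_to_m(start)
        me = model.ref_to_m(end - 1)
        if ms is None or me is None:
            continue
        ws, we = max(0, ms - shift), min(m_len, me + 1 - shift)
        new: list[tuple[int, int, float]] = []
        for ps, pe, pr in pieces:
            if pe <= ws or ps >= we:
                new.append((ps, pe, pr))
                continue
            if ps < ws:
                new.append((ps, ws, pr))
            new.append((max(ps, ws), min(pe, we), pr * ratio))
            if pe > we:
                new.append((we, pe, pr))
        pieces = sorted(new)
    return pieces


def _sample_fragments(
    config: SimConfig,
    rng: np.random.Generator,
    line: str,
    model: _LineChromModel,
    cnv_rates: list[tuple[int, int, float]],
    shift: int,
) -> list[AlignmentRecord]:
    rl = config.read_length
    m_len = len(model.seq)
    rate0 = config.depth_per_line / (2 * rl)
    err = config.base_error_rate
    het_pos = np.asarray(model.het_pos, dtype=np.int64)
    het_alt = np.asarray(model.het_alt, dtype=np.uint8)
    seq_arr = model.seq
    records: list[AlignmentRecord] = []
    other = {
        ord("A"): b"CGT",
        ord("C"): b"AGT",
        ord("G"): b"ACT",
        ord("T"): b"ACG",
    }

    def draw_isizes(n: int) -> np.ndarray:
        lo = max(2 * rl + 2, config.insert_mean - int(3.9 * config.insert_sd))
        hi = config.insert_mean + int(3.9 * config.insert_sd)
        return np.clip(
            np.rint(rng.normal(config.insert_mean, config.insert_sd, n)), lo, hi
        ).astype(np.int64)

    def emit_pair(name: str, m1, m2, hap: int, dup: bool, mult_val: int) -> None:
        a1 = model.map_read(*m1)
        a2 = model.map_read(*m2)
        if a1 is None or a2 is None:
            return
        (ref1, cig1), (ref2, cig2) = a1, a2
        end1 = ref1 + sum(x for op, x in cig1 if op in "MD")
        end2 = ref2 + sum(x for op, x in cig2 if op in "MD")
        span = max(end1, end2) - min(ref1, ref2)
        if span <= 0:
            return
        pair: list[AlignmentRecord] = []
        for (ms, me), (refp, cig), strand, is_r1 in (
            (m1, (ref1, cig1), "+", True),
            (m2, (ref2, cig2), "-", False),
        ):
            bases = seq_arr[ms:me].copy()
            if hap == 1 and len(het_pos):
                lo = bisect_left(model.het_pos, ms)
                hi = bisect_left(model.het_pos, me)
                for k in range(lo, hi):
                    bases[het_pos[k] - ms] = het_alt[k]
            if err > 0:
                emask = rng.random(rl) < err
                for j in np.nonzero(emask)[0]:
                    bases[j] = other[int(bases[j])][rng.integers(0, 3)]
            quals = np.clip(np.rint(rng.normal(36, 3, rl)), 20, 40).astype(int)
            pair.append(
                AlignmentRecord(
                    read_id=name,
                    chrom=model.chrom,
                    pos=refp,
                    strand=strand,
                    cigar=cig,
                    seq=bases.tobytes().decode(),
                    quals=list(quals),
                    mate_chrom=model.chrom,
                    mate_pos=0,  # filled below
                    observed_span=span,
                    is_read1=is_r1,
                    multiplicity=mult_val,
                )
            )
        pair[0].mate_pos = pair[1].pos
        pair[1].mate_pos = pair[0].pos
        records.extend(pair)
        if dup:
            for rec in pair:
                records.append(
                    dataclasses.replace(
                        rec,
                        read_id=name + ".d",
                        quals=list(rec.quals),
                        cigar=list(rec.cigar),
                    )
                )

    # ---- baseline fragments (rate-modulated for partial losses) ----------
    starts: list[np.ndarray] = []
    for ps, pe, ratio in _rate_pieces(m_len, cnv_rates, model, shift):
        if ratio <= 0 or pe <= ps:
            continue
        n = rng.poisson(rate0 * ratio * (pe - ps))
        if n:
            starts.append(rng.integers(ps, pe, size=n, dtype=np.int64))
    if starts:
        frag_starts = np.sort(np.concatenate(starts))
        n = len(frag_starts)
        isizes = draw_isizes(n)
        haps = rng.integers(0, 2, n)
        dup_mask = rng.random(n) < config.duplicate_rate
        mult = np.where(
            rng.random(n) < config.multimap_fraction, rng.integers(2, 4, n), 1
        )
        for i in range(n):
            s = int(frag_starts[i])
            isize = int(isizes[i])
            if s + isize > m_len:
                continue
            emit_pair(
                f"{line}.{model.chrom}.{i}",
                (s, s + rl),
                (s + isize - rl, s + isize),
                int(haps[i]),
                bool(dup_mask[i]),
                int(mult[i]),
            )

    # ---- tandem-duplication fragments for gains ---------------------------
    # the extra copies of a gained segment yield fragments whose reads both
    # lie inside the segment; fragments spanning a copy junction wrap around
    # (discordant span/orientation), so segment depth has sharp edges
    for start, end, ratio in cnv_rates:
        if ratio <= 1.0:
            continue
        ms, me = model.ref_to_m(start), model.ref_to_m(end - 1)
        if ms is None or me is None:
            continue
        seg_len = me + 1 - ms
        n = rng.poisson(rate0 * (ratio - 1.0) * seg_len)
        if not n:
            continue
        gstarts = rng.integers(ms, me + 1, size=n, dtype=np.int64)
        gisizes = draw_isizes(n)
        ghaps = rng.integers(0, 2, n)
        gdup = rng.random(n) < config.duplicate_rate
        gmult = np.where(
            rng.random(n) < config.multimap_fraction, rng.integers(2, 4, n), 1
        )
        for i in range(n):
            s = int(gstarts[i])
            isize = int(gisizes[i])
            r1 = s
            r2 = ms + (s + isize - rl - ms) % seg_len
            if r1 + rl > me + 1 or r2 + rl > me + 1:
                continue  # read would cross a copy junction; unmappable
            emit_pair(
                f"{line}.{model.chrom}.t{i}",
                (r1, r1 + rl),
                (r2, r2 + rl),
                int(ghaps[i]),
                bool(gdup[i]),
                int(gmult[i]),
            )
    return records


# ---------------------------------------------------------------------------
# Truth table I/O
# ---------------------------------------------------------------------------


def write_truth(truth: TruthSet, outdir: str | Path) -> None:
    import pandas as pd

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame([dataclasses.asdict(s) for s in truth.snps]).to_csv(
        outdir / "truth_snps.tsv", sep="\t", index=False
    )
    pd.DataFrame([dataclasses.asdict(i) for i in truth.indels]).to_csv(
        outdir / "truth_indels.tsv", sep="\t", index=False
    )
    pd.DataFrame([dataclasses.asdict(p) for p in truth.pavs]).to_csv(
        outdir / "truth_pavs.tsv", sep="\t", index=False
    )
    pd.DataFrame([dataclasses.asdict(c) for c in truth.cnvs]).to_csv(
        outdir / "truth_cnvs.tsv", sep="\t", index=False
    )
    pd.DataFrame(
        [{"gene_id": g, "channel": c} for g, c in sorted(truth.sweet_genes.items())]
    ).to_csv(outdir / "truth_sweet_genes.tsv", sep="\t", index=False)


def read_truth(outdir: str | Path) -> TruthSet:
    import pandas as pd

    outdir = Path(outdir)
    truth = TruthSet()

    def rows(name: str):
        df = pd.read_csv(outdir / name, sep="\t")
        df = df.where(pd.notna(df), None)
        return df.to_dict("records")

    for r in rows("truth_snps.tsv"):
        truth.snps.append(TruthSnp(**r))
    for r in rows("truth_indels.tsv"):
        truth.indels.append(TruthIndel(**r))
    for r in rows("truth_pavs.tsv"):
        truth.pavs.append(TruthPav(**r))
    for r in rows("truth_cnvs.tsv"):
        truth.cnvs.append(TruthCnv(**r))
    for r in rows("truth_sweet_genes.tsv"):
        truth.sweet_genes[r["gene_id"]] = r["channel"]
    return truth
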