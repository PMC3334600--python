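"""Per-line SNP genotyping and quality filtering.

The genotyper is a deliberately simple maximum-posterior diploid model with
a uniform prior over {ref/ref, ref/alt, alt/alt} and a symmetric per-base
error rate; the scientific content is in the filter cascade applied on top
of it:

* per-line depth between 3 and 50,
* mean mapping multiplicity ("average mappable sites") below 1.5,
* mean base quality of the novel allele above 20,
* no two emitted SNPs closer than 5 bp on a chromosome, and
* a site is heterozygous only when each allele is supported by at least
  three reads.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .alignio import PileupArrays, pileup_arrays
from .models import AlignmentRecord, PileupColumn, SnpCall


@dataclass
class SnpFilterConfig:
    depth_min: int = 3
    depth_max: int = 50
    novel_quality_min: float = 20.0
    mappable_max: float = 1.5
    adjacency_bp: int = 5
    het_min_support: int = 3
    error_rate: float = 0.01


@dataclass
class CandidateSnp:
    """Genotyped non-reference site before filtering."""

    chrom: str
    pos: int
    ref_base: str
    alt_base: str
    line: str
    genotype: str  # "hom_alt" | "het"
    genotype_quality: float
    depth: int
    ref_support: int
    alt_support: int
    novel_allele_mean_quality: float
    mean_mapping_multiplicity: float


def genotype_posteriors(
    n_ref: int, n_alt: int, n_other: int, error_rate: float
) -> dict[str, float]:
    """Posterior over {ref/ref, ref/alt, alt/alt} with a uniform prior.

    Per-read emission model: the true allele is read correctly with
    probability 1−e and miscalled as each of the three other bases with
    probability e/3; for a heterozygote each chromosome is sampled with
    probability 1/2.
    """
    e = error_rate
    p_match = math.log(1 - e) if e < 1 else -math.inf
    p_mis = math.log(e / 3) if e > 0 else -math.inf
    p_het_allele = math.log((1 - e) / 2 + e / 6)  # observed base matches one allele
    p_het_other = p_mis
    logl = {
        "ref_ref": n_ref * p_match + (n_alt + n_other) * p_mis,
        "ref_alt": (n_ref + n_alt) * p_het_allele + n_other * p_het_other,
        "alt_alt": n_alt * p_match + (n_ref + n_other) * p_mis,
    }
    m = max(logl.values())
    w = {g: math.exp(v - m) for g, v in logl.items()}
    z = sum(w.values())
    return {g: v / z for g, v in w.items()}


def genotype_site(
    column: PileupColumn, line: str, error_rate: float = 0.01
) -> CandidateSnp | None:
    """Maximum-posterior diploid genotype at one pileup column.

    Only the most frequent non-reference base is considered as the
    alternate allele.  Returns ``None`` for reference-homozygous sites and
    for zero-depth columns (no call).
    """
    depth = column.depth
    if depth == 0:
        return None
    alt, n_alt = column.top_alt()
    if not alt or n_alt == 0:
        return None
    ref_ev = column.bases.get(column.ref_base)
    n_ref = ref_ev.count if ref_ev else 0
    n_other = depth - n_ref - n_alt
    post = genotype_posteriors(n_ref, n_alt, n_other, error_rate)
    best = max(post, key=post.get)
    if best == "ref_ref":
        return None
    quality = -10.0 * math.log10(max(1.0 - post[best], 1e-300))
    alt_ev = column.bases[alt]
    return CandidateSnp(
        chrom=column.chrom,
        pos=column.pos,
        ref_base=column.ref_base,
        alt_base=alt,
        line=line,
        genotype="het" if best == "ref_alt" else "hom_alt",
        genotype_quality=quality,
        depth=depth,
        ref_support=n_ref,
        alt_support=n_alt,
        novel_allele_mean_quality=alt_ev.mean_quality,
        mean_mapping_multiplicity=column.mean_multiplicity,
    )


def apply_site_filters(
    candidates: Iterable[CandidateSnp], config: SnpFilterConfig | None = None
) -> list[CandidateSnp]:
    """Depth window, mappability and novel-allele quality filters."""
    cfg = config or SnpFilterConfig()
    out = []
    for c in candidates:
        if not cfg.depth_min <= c.depth <= cfg.depth_max:
            continue
        if c.mean_mapping_multiplicity >= cfg.mappable_max:
            continue
        if c.novel_allele_mean_quality <= cfg.novel_quality_min:
            continue
        out.append(c)
    return out


def enforce_adjacency(
    candidates: Sequence[CandidateSnp], adjacency_bp: int = 5
) -> list[CandidateSnp]:
    """Drop every SNP with a same-chromosome neighbour closer than
    ``adjacency_bp`` (both members of a too-close pair are removed,
    chain-wise)."""
    by_chrom: dict[str, list[CandidateSnp]] = {}
    for c in candidates:
        by_chrom.setdefault(c.chrom, []).append(c)
    keep: list[CandidateSnp] = []
    for chrom, group in by_chrom.items():
        group.sort(key=lambda c: c.pos)
        bad = [False] * len(group)
        for i in range(len(group) - 1):
            if group[i + 1].pos - group[i].pos < adjacency_bp:
                bad[i] = bad[i + 1] = True
        keep.extend(c for c, b in zip(group, bad) if not b)
    keep.sort(key=lambda c: (c.chrom, c.pos))
    return keep


def classify_zygosity(
    candidate: CandidateSnp, het_min_support: int = 3
) -> str | None:
    """Final zygosity: heterozygous only with ≥3 reads per allele *and* a
    heterozygous maximum-posterior genotype; otherwise homozygous for the
    majority allele (a reference-majority demotion yields no call)."""
    if (
        candidate.genotype == "het"
        and candidate.ref_support >= het_min_support
        and candidate.alt_support >= het_min_support
    ):
        return "het"
    if candidate.genotype == "het":
        # insufficient allele support: fall back to the majority allele
        if candidate.ref_support >= candidate.alt_support:
            return None
        return "hom_alt"
    return "hom_alt"


def call_snps_from_arrays(
    arrays: PileupArrays,
    reference_chrom: str,
    ref_seq: str,
    line: str,
    config: SnpFilterConfig | None = None,
) -> list[SnpCall]:
    """Full per-chromosome SNP calling from a dense pileup.

    Candidate sites (≥2 reads supporting one non-reference base) are
    genotyped, filtered, adjacency-pruned and zygosity-classified.
    """
    cfg = config or SnpFilterConfig()
    L = arrays.length
    ref_codes = np.frombuffer(ref_seq.encode(), dtype=np.uint8)
    code_of = np.full(256, -1, dtype=np.int64)
    for i, b in enumerate("ACGT"):
        code_of[ord(b)] = i
    ref_idx = code_of[ref_codes[:L]]
    counts = arrays.counts
    masked = counts.copy()
    valid = ref_idx >= 0
    cols = np.arange(L)[valid]
    masked[ref_idx[valid], cols] = -1
    alt_count = masked.max(axis=0)
    candidate_pos = np.nonzero((alt_count >= 2) & valid)[0]

    candidates: list[CandidateSnp] = []
    for pos in candidate_pos:
        col = arrays.column(int(pos), ref_seq[pos])
        cand = genotype_site(col, line, cfg.error_rate)
        if cand is not None:
            candidates.append(cand)
    filtered = apply_site_filters(candidates, cfg)
    pruned = enforce_adjacency(filtered, cfg.adjacency_bp)
    calls: list[SnpCall] = []
    for c in pruned:
        zyg = classify_zygosity(c, cfg.het_min_support)
        if zyg is None:
            continue
        calls.append(
            SnpCall(
                chrom=c.chrom,
                pos=c.pos,
                ref_base=c.ref_base,
                alt_base=c.alt_base,
                line=line,
                zygosity=zyg,
                genotype_quality=c.genotype_quality,
                depth=c.depth,
                novel_allele_mean_quality=c.novel_allele_mean_quality,
                mean_mapping_multiplicity=c.mean_mapping_multiplicity,
                ref_support=c.ref_support,
                alt_support=c.alt_support,
            )
        )
    return calls


def call_snps(
    records: Sequence[AlignmentRecord],
    reference: dict[str, str],
    line: str,
    config: SnpFilterConfig | None = None,
) -> list[SnpCall]:
    """Call SNPs for one line across all chromosomes of the reference."""
    calls: list[SnpCall] = []
    chroms = sorted({r.chrom for r in records})
    for chrom in chroms:
        arrays = pileup_arrays(records, chrom, len(reference[chrom]))
        calls.extend(
            call_snps_from_arrays(arrays, chrom, reference[chrom], line, config)
        )
    return calls
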