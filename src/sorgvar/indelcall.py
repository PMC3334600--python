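"""Short-indel (1–10 bp) calling from gapped paired-end alignments.

A candidate indel is a gap signature aggregated over non-redundant gapped
read pairs; it is emitted when

* at least three non-redundant pairs support the identical gap,
* the number of gapless reads crossing the locus is at most twice the
  gapped support, and
* gapped support is seen on both read strands.
"""

from __future__ import annotations

import logging
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from typing import Sequence

from .models import AlignmentRecord, IndelCall

log = logging.getLogger(__name__)


@dataclass
class GapSignature:
    chrom: str
    pos: int  # 0-based first deleted base / insertion point
    type: str  # "ins" | "del"
    length: int
    sequence: str
    supporting_pairs: set[str] = field(default_factory=set)
    strands_seen: set[str] = field(default_factory=set)
    crossing_ungapped: int = 0

    @property
    def supporting_gapped(self) -> int:
        return len(self.supporting_pairs)

    @property
    def key(self) -> tuple:
        return (self.chrom, self.pos, self.type, self.length, self.sequence)


@dataclass
class IndelCallConfig:
    min_gapped: int = 3
    crossing_ratio: float = 2.0
    max_gap: int = 10


def collect_gap_signatures(
    records: Sequence[AlignmentRecord], max_gap: int = 10
) -> list[GapSignature]:
    """Aggregate identical gaps over non-redundant gapped pairs.

    Duplicate-flagged reads are ignored; gaps longer than ``max_gap`` are
    skipped with a warning.  Two gapped reads of one pair count once.
    """
    sigs: dict[tuple, GapSignature] = {}
    for rec in records:
        if rec.duplicate:
            continue
        gap = rec.gap
        if gap is None:
            continue
        typ, pos, length, seq = gap
        if typ == "del":
            # deleted bases come from the reference, which the record does
            # not carry; the caller fills sequence via reference lookup
            seq = ""
        if length > max_gap:
            log.warning(
                "ignoring %d-bp gap at %s:%d (limit %d)", length, rec.chrom, pos, max_gap
            )
            continue
        key = (rec.chrom, pos, typ, length, seq)
        sig = sigs.get(key)
        if sig is None:
            sig = GapSignature(rec.chrom, pos, typ, length, seq)
            sigs[key] = sig
        sig.supporting_pairs.add(rec.read_id)
        sig.strands_seen.add(rec.strand)
    return sorted(sigs.values(), key=lambda s: (s.chrom, s.pos))


def count_crossing_ungapped(
    signatures: Sequence[GapSignature], records: Sequence[AlignmentRecord]
) -> None:
    """Fill ``crossing_ungapped``: gapless non-duplicate reads whose aligned
    span covers both bases flanking the gap anchor ([pos−1, pos+1))."""
    by_chrom: dict[str, tuple[list[int], list[int]]] = {}
    for chrom in {s.chrom for s in signatures}:
        spans = sorted(
            (r.pos, r.ref_end)
            for r in records
            if r.chrom == chrom and not r.duplicate and r.gap is None
        )
        starts = [s for s, _ in spans]
        ends = [e for _, e in spans]
        by_chrom[chrom] = (starts, ends)
    for sig in signatures:
        starts, ends = by_chrom[sig.chrom]
        lo, hi = sig.pos - 1, sig.pos + 1
        # reads with start <= lo and end >= hi; a gapless read spans at most
        # its read length, so only a short start window can qualify
        i = bisect_right(starts, lo)
        i0 = bisect_left(starts, lo - 500)
        sig.crossing_ungapped = sum(1 for e in ends[i0:i] if e >= hi)


def call_indels(
    signatures: Sequence[GapSignature],
    config: IndelCallConfig | None = None,
    line: str = "",
    reference: dict[str, str] | None = None,
) -> list[IndelCall]:
    """Apply the support heuristics and resolve same-locus ties.

    When two different signatures share a locus, the better-supported one
    wins; an exact tie leaves the locus uncalled (ambiguous).
    """
    cfg = config or IndelCallConfig()
    passing: list[GapSignature] = []
    for sig in signatures:
        if sig.supporting_gapped < cfg.min_gapped:
            continue
        if sig.crossing_ungapped > cfg.crossing_ratio * sig.supporting_gapped:
            continue
        if sig.strands_seen != {"+", "-"}:
            continue
        passing.append(sig)
    # same-locus tie handling
    by_locus: dict[tuple[str, int], list[GapSignature]] = {}
    for sig in passing:
        by_locus.setdefault((sig.chrom, sig.pos), []).append(sig)
    calls: list[IndelCall] = []
    for (chrom, pos), group in sorted(by_locus.items()):
        if len(group) > 1:
            group.sort(key=lambda s: -s.supporting_gapped)
            if group[0].supporting_gapped == group[1].supporting_gapped:
                continue
        sig = group[0]
        seq = sig.sequence
        if sig.type == "del" and reference is not None:
            seq = reference[chrom][pos : pos + sig.length]
        elif sig.type == "del" and not seq:
            seq = "N" * sig.length
        calls.append(
            IndelCall(
                chrom=chrom,
                pos=pos,
                type=sig.type,
                length=sig.length,
                sequence=seq,
                line=line,
                gapped_support=sig.supporting_gapped,
                crossing_ungapped=sig.crossing_ungapped,
            )
        )
    return calls


def call_indels_from_alignments(
    records: Sequence[AlignmentRecord],
    reference: dict[str, str],
    line: str,
    config: IndelCallConfig | None = None,
) -> list[IndelCall]:
    cfg = config or IndelCallConfig()
    sigs = collect_gap_signatures(records, cfg.max_gap)
    count_crossing_ungapped(sigs, records)
    return call_indels(sigs, cfg, line=line, reference=reference)
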