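"""Structural variation: presence/absence (PAV) and copy-number (CNV) calling.

PAVs come from discordant paired-end signatures: a proper pair should map
in forward/reverse orientation with a span close to the library insert
size, so pairs whose span deviates by more than four standard deviations
(or whose orientation is wrong) flag structural change.  Stretched-span
pairs whose implied deleted intervals mutually overlap are clustered;
clusters with ≥3 pairs are candidates and ≥6 pairs make a high-quality
absence call.

CNVs come from read-depth segmentation: each base is classed by its depth
ratio against the per-line genome-wide mean (loss < 0.5, gain > 2.0), runs
shorter than a 200-base smoothing window are merged into their neighbours,
and each remaining aberrant fragment receives a two-sided Poisson tail
p-value.  Fragments longer than 2 kb with p ≤ 0.35 and a ratio outside
[0.5, 2.0] are kept.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .models import AlignmentRecord, CnvCall, PavCall


# ---------------------------------------------------------------------------
# Pair anomaly classification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class InsertModel:
    mean: float
    sd: float

    @property
    def span_limit(self) -> float:
        return 4.0 * self.sd


@dataclass(frozen=True)
class PairAnomaly:
    chrom: str
    left_pos: int  # inner edge: end of the left read
    right_pos: int  # inner edge: start of the right read
    anomaly_kind: str  # stretched_span | shortened_span | bad_orientation
    observed_span: int
    expected_span_mean: float
    expected_span_sd: float


@dataclass(frozen=True)
class ReadPair:
    """Both ends of one non-duplicate fragment, leftmost first."""

    chrom: str
    left_start: int
    left_end: int
    left_strand: str
    right_start: int
    right_end: int
    right_strand: str

    @property
    def observed_span(self) -> int:
        return self.right_end - self.left_start


def pair_up(records: Sequence[AlignmentRecord]) -> list[ReadPair]:
    """Collect proper same-chromosome pairs, excluding duplicates."""
    by_id: dict[str, list[AlignmentRecord]] = {}
    for rec in records:
        if rec.duplicate:
            continue
        by_id.setdefault(rec.read_id, []).append(rec)
    pairs: list[ReadPair] = []
    for rid, recs in by_id.items():
        if len(recs) != 2 or recs[0].chrom != recs[1].chrom:
            continue
        a, b = sorted(recs, key=lambda r: r.pos)
        pairs.append(
            ReadPair(
                chrom=a.chrom,
                left_start=a.pos,
                left_end=a.ref_end,
                left_strand=a.strand,
                right_start=b.pos,
                right_end=b.ref_end,
                right_strand=b.strand,
            )
        )
    pairs.sort(key=lambda p: (p.chrom, p.left_start))
    return pairs


def estimate_insert_model(pairs: Sequence[ReadPair]) -> InsertModel:
    """Median/MAD-based insert-size model from FR pairs (robust to the
    anomalous tail)."""
    spans = [
        p.observed_span
        for p in pairs
        if p.left_strand == "+" and p.right_strand == "-"
    ]
    if not spans:
        raise ValueError("no forward/reverse pairs to estimate insert size")
    med = statistics.median(spans)
    mad = statistics.median([abs(s - med) for s in spans])
    sd = 1.4826 * mad if mad > 0 else max(statistics.pstdev(spans), 1.0)
    return InsertModel(mean=float(med), sd=float(sd))


def classify_pair_anomaly(
    pair: ReadPair, insert_model: InsertModel
) -> PairAnomaly | None:
    """Classify one pair; ``None`` means a normal (concordant) pair."""
    if not (pair.left_strand == "+" and pair.right_strand == "-"):
        kind = "bad_orientation"
    else:
        dev = pair.observed_span - insert_model.mean
        if abs(dev) <= insert_model.span_limit:
            return None
        kind = "stretched_span" if dev > 0 else "shortened_span"
    return PairAnomaly(
        chrom=pair.chrom,
        left_pos=pair.left_end,
        right_pos=pair.right_start,
        anomaly_kind=kind,
        observed_span=pair.observed_span,
        expected_span_mean=insert_model.mean,
        expected_span_sd=insert_model.sd,
    )


# ---------------------------------------------------------------------------
# PAV clustering
# ---------------------------------------------------------------------------


@dataclass
class PavCluster:
    chrom: str
    anomalies: list[PairAnomaly]

    @property
    def n_pairs(self) -> int:
        return len(self.anomalies)

    def call(self, line: str, insert_mean: float) -> PavCall:
        start = int(statistics.median([a.left_pos for a in self.anomalies]))
        end = int(statistics.median([a.right_pos for a in self.anomalies]))
        if end <= start:
            end = start + 1
        return PavCall(
            chrom=self.chrom,
            start=start,
            end=end,
            type="absence",
            supporting_pairs=self.n_pairs,
            line=line,
        )

    @property
    def implied_length(self) -> float:
        spans = [a.observed_span for a in self.anomalies]
        return statistics.median(spans) - self.anomalies[0].expected_span_mean


def cluster_pavs(
    anomalies: Iterable[PairAnomaly],
    line: str,
    candidate_min: int = 3,
    final_min: int = 6,
) -> tuple[list[PavCall], list[PavCluster]]:
    """Cluster stretched-span pairs into absence calls.

    The implied deleted interval of a stretched pair is the gap between its
    inner read edges; pairs whose intervals mutually overlap form one
    cluster.  Returns (final calls with ≥ ``final_min`` pairs, candidate
    clusters with ≥ ``candidate_min``).  Shortened-span and bad-orientation
    anomalies signal inserted/rearranged sequence, which needs assembly to
    resolve, and are not clustered here.
    """
    stretched = sorted(
        (a for a in anomalies if a.anomaly_kind == "stretched_span"),
        key=lambda a: (a.chrom, a.left_pos, a.right_pos),
    )
    clusters: list[PavCluster] = []
    current: list[PairAnomaly] = []
    cur_end = -1  # running intersection right edge (mutual overlap)
    cur_chrom = None
    for a in stretched:
        if current and a.chrom == cur_chrom and a.left_pos < cur_end:
            current.append(a)
            cur_end = min(cur_end, a.right_pos)
        else:
            if current:
                clusters.append(PavCluster(cur_chrom, current))
            current = [a]
            cur_chrom = a.chrom
            cur_end = a.right_pos
    if current:
        clusters.append(PavCluster(cur_chrom, current))

    candidates = [c for c in clusters if c.n_pairs >= candidate_min]
    insert_mean = stretched[0].expected_span_mean if stretched else 0.0
    finals = [
        c.call(line, insert_mean) for c in candidates if c.n_pairs >= final_min
    ]
    return finals, candidates


def call_pavs(
    records: Sequence[AlignmentRecord],
    line: str,
    insert_model: InsertModel | None = None,
    candidate_min: int = 3,
    final_min: int = 6,
) -> list[PavCall]:
    pairs = pair_up(records)
    model = insert_model or estimate_insert_model(pairs)
    anomalies = [
        a for p in pairs if (a := classify_pair_anomaly(p, model)) is not None
    ]
    finals, _ = cluster_pavs(anomalies, line, candidate_min, final_min)
    return finals


# ---------------------------------------------------------------------------
# CNV calling
# ---------------------------------------------------------------------------


@dataclass
class CnvConfig:
    min_length: int = 2000  # strict: fragments must be longer than this
    p_max: float = 0.35
    loss_ratio: float = 0.5
    gain_ratio: float = 2.0
    smooth_window: int = 200


@dataclass
class DepthFragment:
    chrom: str
    start: int
    end: int
    depth_class: str  # "loss" | "normal" | "gain"
    mean_depth: float = 0.0
    p_value: float = 1.0

    @property
    def length(self) -> int:
        return self.end - self.start


def genome_mean_depth(depth: np.ndarray) -> float:
    """Mean depth over covered bases (zero-coverage bases excluded)."""
    covered = depth[depth > 0]
    if covered.size == 0:
        raise ValueError("no covered bases")
    return float(covered.mean())


def segment_depth(
    depth: np.ndarray,
    genome_mean: float,
    chrom: str,
    config: CnvConfig | None = None,
) -> list[DepthFragment]:
    """Partition a per-base depth track into constant-class fragments.

    Bases are classed by depth ratio (loss < ``loss_ratio``, gain >
    ``gain_ratio``); runs shorter than the smoothing window are merged into
    their (longer) neighbour until none remain, then aberrant fragments are
    returned with their mean depth.
    """
    cfg = config or CnvConfig()
    if genome_mean <= 0:
        raise ValueError("expected depth must be positive")
    ratio = depth / genome_mean
    classes = np.ones(len(depth), dtype=np.int8)  # 0 loss, 1 normal, 2 gain
    classes[ratio < cfg.loss_ratio] = 0
    classes[ratio > cfg.gain_ratio] = 2

    # run-length encode
    change = np.nonzero(np.diff(classes))[0] + 1
    starts = np.concatenate(([0], change)).tolist()
    ends = np.concatenate((change, [len(classes)])).tolist()
    labels = [int(classes[s]) for s in starts]
    runs = list(zip(starts, ends, labels))

    runs = _merge_short_runs(runs, cfg.smooth_window)

    fragments = []
    names = {0: "loss", 1: "normal", 2: "gain"}
    for s, e, lab in runs:
        if lab == 1:
            continue
        fragments.append(
            DepthFragment(
                chrom=chrom,
                start=int(s),
                end=int(e),
                depth_class=names[lab],
                mean_depth=float(depth[s:e].mean()),
            )
        )
    return fragments


def _merge_short_runs(
    runs: list[tuple[int, int, int]], window: int
) -> list[tuple[int, int, int]]:
    """Repeatedly relabel the shortest sub-window run to its longer
    neighbour's class (coalescing equal-class neighbours) until every run
    reaches the window size.

    Shortest-first order matters: single-base Poisson dips vanish into
    their local surroundings before any longer run is touched, so a long
    aberrant segment cannot creep over adjacent noise chunk by chunk.
    Implemented as a doubly linked list plus a lazy-deletion heap.
    """
    import heapq

    if len(runs) <= 1:
        return runs
    n = len(runs)
    start = [r[0] for r in runs]
    end = [r[1] for r in runs]
    label = [r[2] for r in runs]
    prev = [i - 1 for i in range(n)]
    nxt = [i + 1 if i + 1 < n else -1 for i in range(n)]
    alive = [True] * n
    version = [0] * n
    heap = [(end[i] - start[i], i, 0) for i in range(n)]
    heapq.heapify(heap)

    def coalesce(i: int) -> int:
        """Merge node i with equal-label neighbours; returns surviving id."""
        j = prev[i]
        if j >= 0 and alive[j] and label[j] == label[i]:
            end[j] = end[i]
            alive[i] = False
            nxt[j] = nxt[i]
            if nxt[i] >= 0:
                prev[nxt[i]] = j
            i = j
        k = nxt[i]
        if k >= 0 and alive[k] and label[k] == label[i]:
            end[i] = end[k]
            alive[k] = False
            nxt[i] = nxt[k]
            if nxt[k] >= 0:
                prev[nxt[k]] = i
        version[i] += 1
        heapq.heappush(heap, (end[i] - start[i], i, version[i]))
        return i

    while heap:
        length, i, ver = heapq.heappop(heap)
        if not alive[i] or ver != version[i] or end[i] - start[i] != length:
            continue
        if length >= window:
            break
        left = prev[i] if prev[i] >= 0 and alive[prev[i]] else -1
        right = nxt[i] if nxt[i] >= 0 and alive[nxt[i]] else -1
        if left < 0 and right < 0:
            break
        if right < 0 or (
            left >= 0 and end[left] - start[left] >= end[right] - start[right]
        ):
            label[i] = label[left]
        else:
            label[i] = label[right]
        coalesce(i)

    out = []
    i = 0
    while not alive[i]:
        i += 1
    while prev[i] >= 0:
        i = prev[i]
    while i >= 0:
        out.append((start[i], end[i], label[i]))
        i = nxt[i]
    return out


def cnv_pvalue(fragment_mean_depth: float, expected_depth: float) -> float:
    """Two-sided Poisson tail probability of a fragment's depth.

    With observed mean depth d and expectation E: if d < E the p-value is
    2·P(X ≤ d), else 2·P(X ≥ d), X ~ Poisson(E), evaluated at round(d) and
    clamped to [0, 1].
    """
    if expected_depth <= 0:
        raise ValueError("expected depth must be positive")
    d = int(round(fragment_mean_depth))
    if fragment_mean_depth < expected_depth:
        p = 2.0 * float(stats.poisson.cdf(d, expected_depth))
    else:
        p = 2.0 * float(stats.poisson.sf(d - 1, expected_depth))
    return min(max(p, 0.0), 1.0)


def call_cnvs(
    fragments: Sequence[DepthFragment],
    genome_mean: float,
    line: str,
    config: CnvConfig | None = None,
) -> list[CnvCall]:
    """Keep fragments longer than 2 kb with p ≤ 0.35 and an aberrant depth
    ratio; calls are sorted by ascending p-value (most credible first)."""
    cfg = config or CnvConfig()
    calls: list[CnvCall] = []
    for frag in fragments:
        if frag.length <= cfg.min_length:
            continue
        p = cnv_pvalue(frag.mean_depth, genome_mean)
        ratio = frag.mean_depth / genome_mean
        if p > cfg.p_max:
            continue
        if cfg.loss_ratio <= ratio <= cfg.gain_ratio:
            continue
        calls.append(
            CnvCall(
                chrom=frag.chrom,
                start=frag.start,
                end=frag.end,
                mean_depth_ratio=ratio,
                p_value=p,
                cnv_class="loss" if ratio < cfg.loss_ratio else "gain",
                line=line,
            )
        )
    calls.sort(key=lambda c: c.p_value)
    return calls


def call_cnvs_from_depth(
    depth_by_chrom: dict[str, np.ndarray],
    line: str,
    config: CnvConfig | None = None,
) -> list[CnvCall]:
    """CNV calling across chromosomes with a line-wide expected depth."""
    cfg = config or CnvConfig()
    all_depth = np.concatenate(list(depth_by_chrom.values()))
    mean = genome_mean_depth(all_depth)
    calls: list[CnvCall] = []
    for chrom, depth in depth_by_chrom.items():
        frags = segment_depth(depth, mean, chrom, cfg)
        calls.extend(call_cnvs(frags, mean, line, cfg))
    calls.sort(key=lambda c: c.p_value)
    return calls
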