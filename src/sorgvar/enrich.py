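"""Summary tables and enrichment statistics.

Implements the reporting arithmetic around the call sets: per-line and
total non-synonymous/synonymous ratio tables stratified by gene category,
per-family chi-square tests of the non-syn/syn split, Fisher-exact
enrichment/depletion of large-effect SNPs across gene families, one-sided
hypergeometric pathway enrichment (equivalently one-sided Fisher's exact
test — the two coincide, so one implementation serves both), and the 1-Mb
sliding-window clustering of trait-associated genes.

P-values are reported raw; the thresholds used downstream (0.01 for
families, 0.1 for pathways, 0.05/0.001 chi-square stars) follow the
analysis design.  A Benjamini–Hochberg option exists but is off by
default.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .models import GENE_CATEGORIES, VariantEffect

NON_SYN_EFFECTS = {"non_synonymous", "stop_gain", "start_loss", "stop_loss"}
SYN_EFFECTS = {"synonymous"}


# ---------------------------------------------------------------------------
# Ratio tables (coding-SNP accounting)
# ---------------------------------------------------------------------------


def ns_ratio(non_syn: int, syn: int) -> float:
    """Non-syn/syn ratio rounded half-up to 2 decimals; 0.00 when syn = 0."""
    if syn == 0:
        return 0.0
    q = Decimal(non_syn) / Decimal(syn)
    return float(q.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def ratio_table(
    effects: Sequence[VariantEffect],
    lines: Sequence[str],
    categories: Sequence[str] = GENE_CATEGORIES,
) -> pd.DataFrame:
    """Per-line coding-SNP counts and ratios by gene category, plus a Total
    row in which each site (chrom, pos, alt) is counted once across lines.

    Protein-changing substitutions (plain non-synonymous plus the stop/start
    classes) count as non-syn; splice variants sit in introns and are not
    part of the coding table.
    """

    def bucket(eff: VariantEffect) -> str | None:
        if eff.effect in NON_SYN_EFFECTS:
            return "non_syn"
        if eff.effect in SYN_EFFECTS:
            return "syn"
        return None

    counts: dict[tuple[str, str, str], int] = {}
    seen_sites: set[tuple] = set()
    total_counts: dict[tuple[str, str], int] = {}
    for eff in effects:
        b = bucket(eff)
        if b is None or eff.gene_category is None:
            continue
        v = eff.variant
        counts[(v.line, eff.gene_category, b)] = (
            counts.get((v.line, eff.gene_category, b), 0) + 1
        )
        site = (v.chrom, v.pos, v.alt_base)
        if site not in seen_sites:
            seen_sites.add(site)
            total_counts[(eff.gene_category, b)] = (
                total_counts.get((eff.gene_category, b), 0) + 1
            )

    rows = []
    for line in list(lines) + ["Total"]:
        row: dict[str, object] = {"sample": line}
        all_ns = all_s = 0
        for cat in categories:
            if line == "Total":
                ns = total_counts.get((cat, "non_syn"), 0)
                s = total_counts.get((cat, "syn"), 0)
            else:
                ns = counts.get((line, cat, "non_syn"), 0)
                s = counts.get((line, cat, "syn"), 0)
            row[f"{cat}_non_syn"] = ns
            row[f"{cat}_syn"] = s
            row[f"{cat}_ratio"] = ns_ratio(ns, s)
            all_ns += ns
            all_s += s
        row["total_non_syn"] = all_ns
        row["total_syn"] = all_s
        row["total_ratio"] = ns_ratio(all_ns, all_s)
        rows.append(row)
    return pd.DataFrame(rows).set_index("sample")


# ---------------------------------------------------------------------------
# Family chi-square of non-syn/syn distributions
# ---------------------------------------------------------------------------


def chisq_2x2(table: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Pearson chi-square without continuity correction on a 2×2 table."""
    obs = np.asarray(table, dtype=float)
    if obs.sum() == 0:
        return 0.0, 1.0
    stat, p, _, _ = stats.chi2_contingency(obs, correction=False)
    return float(stat), float(p)


def family_chisq(
    family_non_syn: int,
    family_syn: int,
    rest_non_syn: int,
    rest_syn: int,
) -> tuple[float, float]:
    """Chi-square of one family's non-syn/syn split against the rest of the
    genome."""
    return chisq_2x2([[family_non_syn, family_syn], [rest_non_syn, rest_syn]])


def family_chisq_report(
    effects: Sequence[VariantEffect],
    gene_families: Mapping[str, Sequence[str]],
    min_snps: int = 30,
) -> pd.DataFrame:
    """Per-family chi-square over families with ≥ ``min_snps`` coding SNPs.

    ``gene_families`` maps gene_id → families.  Stars mark p < 0.05 (*) and
    p < 0.001 (**).
    """
    fam_counts: dict[str, list[int]] = {}
    tot_ns = tot_s = 0
    for eff in effects:
        if eff.effect in NON_SYN_EFFECTS:
            col = 0
        elif eff.effect in SYN_EFFECTS:
            col = 1
        else:
            continue
        tot_ns += col == 0
        tot_s += col == 1
        for fam in gene_families.get(eff.gene_id or "", ()):
            fam_counts.setdefault(fam, [0, 0])[col] += 1
    rows = []
    for fam, (ns, s) in sorted(fam_counts.items()):
        if ns + s < min_snps:
            continue
        stat, p = family_chisq(ns, s, tot_ns - ns, tot_s - s)
        stars = "**" if p < 0.001 else "*" if p < 0.05 else ""
        rows.append(
            {
                "family": fam,
                "non_syn": ns,
                "syn": s,
                "ratio": ns_ratio(ns, s),
                "chisq": stat,
                "p_value": p,
                "stars": stars,
            }
        )
    return pd.DataFrame(
        rows, columns=["family", "non_syn", "syn", "ratio", "chisq", "p_value", "stars"]
    )


# ---------------------------------------------------------------------------
# Enrichment tests
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EnrichmentResult:
    unit_id: str
    in_set: int  # members of the unit inside the selected set
    set_size: int  # size of the selected set
    background: int  # unit size in the background
    background_size: int
    statistic: float
    p_value: float
    direction: str  # "enriched" | "depleted"

    def __post_init__(self) -> None:
        if not (
            self.in_set <= self.set_size <= self.background_size
            and self.in_set <= self.background <= self.background_size
        ):
            raise ValueError("inconsistent enrichment counts")


def large_effect_family_test(
    genes_with_large_effect: set[str],
    family_map: Mapping[str, Sequence[str]],
    background_genes: Sequence[str],
    p_threshold: float = 0.01,
    fdr: bool = False,
) -> list[EnrichmentResult]:
    """Two-sided Fisher's exact test per family for enrichment/depletion of
    large-effect genes; families below the p threshold are reported with
    their direction (odds ratio vs 1)."""
    background = set(background_genes)
    selected = genes_with_large_effect & background
    fam_members: dict[str, set[str]] = {}
    for gene, fams in family_map.items():
        if gene in background:
            for fam in fams:
                fam_members.setdefault(fam, set()).add(gene)
    raw: list[EnrichmentResult] = []
    for fam, members in sorted(fam_members.items()):
        if not members:
            continue
        a = len(members & selected)
        b = len(members) - a
        c = len(selected) - a
        d = len(background) - len(members) - c
        odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        fam_rate = a / len(members)
        bg_rate = len(selected) / len(background)
        direction = "enriched" if fam_rate > bg_rate else "depleted"
        raw.append(
            EnrichmentResult(
                unit_id=fam,
                in_set=a,
                set_size=len(members),
                background=len(members),
                background_size=len(background),
                statistic=float(odds) if np.isfinite(odds) else float("inf"),
                p_value=float(p),
                direction=direction,
            )
        )
    pvals = [r.p_value for r in raw]
    if fdr and pvals:
        adj = benjamini_hochberg(pvals)
        raw = [
            dataclass_replace(r, p_value=q) for r, q in zip(raw, adj)
        ]
    return [r for r in raw if r.p_value < p_threshold]


def pathway_test(
    selected_genes: set[str],
    pathway_map: Mapping[str, Sequence[str]],
    background_genes: Sequence[str],
    p_threshold: float = 0.1,
    fdr: bool = False,
) -> list[EnrichmentResult]:
    """One-sided hypergeometric enrichment per pathway.

    With N background genes, K pathway members, n selected genes and k
    selected members, p = P(X ≥ k) for X ~ Hypergeom(N, K, n) — identical
    to one-sided Fisher's exact on the 2×2 table.  Pathways with p below
    the threshold are reported.
    """
    background = set(background_genes)
    selected = selected_genes & background
    if not selected <= background:
        raise ValueError("selected genes must lie in the background")
    path_members: dict[str, set[str]] = {}
    for gene, paths in pathway_map.items():
        if gene in background:
            for pw in paths:
                path_members.setdefault(pw, set()).add(gene)
    N, n = len(background), len(selected)
    raw = []
    for pw, members in sorted(path_members.items()):
        K = len(members)
        k = len(members & selected)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        raw.append(
            EnrichmentResult(
                unit_id=pw,
                in_set=k,
                set_size=n,
                background=K,
                background_size=N,
                statistic=float(k),
                p_value=p,
                direction="enriched",
            )
        )
    pvals = [r.p_value for r in raw]
    if fdr and pvals:
        adj = benjamini_hochberg(pvals)
        raw = [dataclass_replace(r, p_value=q) for r, q in zip(raw, adj)]
    return [r for r in raw if r.p_value < p_threshold]


def benjamini_hochberg(pvals: Sequence[float]) -> list[float]:
    """BH-adjusted p-values (step-up)."""
    m = len(pvals)
    order = np.argsort(pvals)
    adj = np.empty(m)
    prev = 1.0
    for rank_from_top, i in enumerate(order[::-1]):
        rank = m - rank_from_top
        prev = min(prev, pvals[i] * m / rank)
        adj[i] = prev
    return adj.tolist()


def dataclass_replace(r: EnrichmentResult, **kw) -> EnrichmentResult:
    import dataclasses

    return dataclasses.replace(r, **kw)


# ---------------------------------------------------------------------------
# Sliding-window clustering of trait-associated genes
# ---------------------------------------------------------------------------


def sliding_windows(
    gene_midpoints: Mapping[str, Sequence[int]],
    chrom_lengths: Mapping[str, int],
    window: int = 1_000_000,
    step: int = 100_000,
    min_genes_gt: int = 3,
) -> list[tuple[str, int, int, int]]:
    """Windows containing more than ``min_genes_gt`` gene midpoints, merged
    into maximal regions.

    Returns (chrom, start, end, max window count) per merged region.
    """
    regions: list[tuple[str, int, int, int]] = []
    for chrom, L in chrom_lengths.items():
        mids = np.sort(np.asarray(gene_midpoints.get(chrom, []), dtype=np.int64))
        if mids.size == 0:
            continue
        starts = list(range(0, max(L - window, 0) + 1, step))
        hits: list[tuple[int, int, int]] = []
        for s in starts:
            e = min(s + window, L)
            n = int(np.searchsorted(mids, e) - np.searchsorted(mids, s))
            if n > min_genes_gt:
                hits.append((s, e, n))
        # merge overlapping reported windows
        for s, e, n in hits:
            if regions and regions[-1][0] == chrom and s <= regions[-1][2]:
                c, rs, re, rn = regions[-1]
                regions[-1] = (c, rs, max(re, e), max(rn, n))
            else:
                regions.append((chrom, s, e, n))
    return regions


# ---------------------------------------------------------------------------
# Report arithmetic (variant-count bookkeeping)
# ---------------------------------------------------------------------------


def count_report(groups: Mapping[str, int]) -> dict[str, int]:
    """Aggregate named count groups and append their total."""
    out = dict(groups)
    out["total"] = sum(groups.values())
    return out


def validation_accuracy(verified: int, assayed: int) -> float:
    """Validation accuracy in percent (e.g. verified targeted variants over
    assayed ones)."""
    if assayed <= 0:
        raise ValueError("assayed must be positive")
    return 100.0 * verified / assayed
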