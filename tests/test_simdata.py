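"""Simulator properties: determinism, composition, gene-model invariants,
planted-truth guarantees and alignment geometry."""

import dataclasses

import numpy as np
import pytest
from Bio.Seq import Seq

from sorgvar.models import GENE_CATEGORIES
from sorgvar.simdata import (
    SimConfig,
    plant_variants,
    sample_intron_length,
    simulate_alignments,
    simulate_gene_models,
    simulate_genome,
)
from tests.conftest import small_config


class TestGenome:
    def test_same_seed_is_byte_identical(self):
        cfg = SimConfig(genome_length=50_000, n_chromosomes=2, n_genes=8, seed=7)
        assert simulate_genome(cfg) == simulate_genome(cfg)

    def test_different_seed_differs(self):
        a = simulate_genome(SimConfig(genome_length=50_000, n_genes=8, seed=1))
        b = simulate_genome(SimConfig(genome_length=50_000, n_genes=8, seed=2))
        assert a != b

    def test_gc_content_concentrates_at_target(self):
        cfg = SimConfig(genome_length=1_000_000, gc_fraction=0.5, seed=3)
        genome = simulate_genome(cfg)
        seq = "".join(genome.values())
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert 0.48 <= gc <= 0.52

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError):
            simulate_genome(SimConfig(genome_length=0))

    def test_bad_category_mix_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(gene_category_mix=(0.5, 0.5, 0.5, 0.5)).validate()


@pytest.fixture(scope="module")
def built():
    cfg = SimConfig(
        genome_length=1_200_000, n_chromosomes=2, n_genes=200, seed=11,
        gene_category_mix=(0.8, 0.1, 0.05, 0.05),
    )
    genome0 = simulate_genome(cfg)
    genes, genome = simulate_gene_models(cfg, genome0)
    return cfg, genes, genome


class TestGeneModels:
    def test_bona_fide_cds_translates_to_single_terminal_stop(self, built):
        _, genes, genome = built
        for g in genes:
            if g.category != "bona_fide":
                continue
            cds = g.cds_sequence(genome)
            assert len(cds) % 3 == 0
            assert cds.startswith("ATG")
            protein = str(Seq(cds).translate())
            assert protein.count("*") == 1 and protein.endswith("*")

    def test_introns_have_canonical_boundaries(self, built):
        _, genes, genome = built
        for g in genes:
            for s, e in g.introns:
                seg = genome[g.chrom][s:e]
                if g.strand == "-":
                    seg = str(Seq(seg).reverse_complement())
                assert seg[:2] == "GT" and seg[-2:] == "AG"

    def test_models_do_not_overlap(self, built):
        _, genes, _ = built
        by_chrom: dict[str, list] = {}
        for g in genes:
            by_chrom.setdefault(g.chrom, []).append((g.start, g.end))
        for spans in by_chrom.values():
            spans.sort()
            for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                assert s2 >= e1

    def test_category_counts_near_multinomial_expectation(self, built):
        cfg, genes, _ = built
        n = len(genes)
        for cat, p in zip(GENE_CATEGORIES, cfg.gene_category_mix):
            observed = sum(1 for g in genes if g.category == cat)
            sigma = (n * p * (1 - p)) ** 0.5
            assert abs(observed - n * p) <= 3 * sigma + 1

    def test_intron_length_sampler_mean(self):
        rng = np.random.default_rng(5)
        draws = [sample_intron_length(rng, 444.0) for _ in range(500)]
        assert abs(np.mean(draws) - 444.0) / 444.0 < 0.10
        assert min(draws) >= 60


@pytest.fixture(scope="module")
def planted():
    cfg = small_config(seed=3)
    genome0 = simulate_genome(cfg)
    genes, genome = simulate_gene_models(cfg, genome0)
    truth = plant_variants(cfg, genome, genes)
    return cfg, genes, genome, truth


class TestPlanting:
    def test_every_large_effect_class_planted_per_line(self, planted):
        cfg, _, _, truth = planted
        for line in cfg.lines:
            effects = {s.effect for s in truth.snps if s.line == line}
            assert {"stop_gain", "start_loss", "splice_disrupt", "stop_loss",
                    "synonymous", "non_synonymous"} <= effects

    def test_indels_cover_all_lengths(self, planted):
        cfg, _, _, truth = planted
        for line in cfg.lines:
            lengths = {i.length for i in truth.indels if i.line == line}
            assert lengths == set(range(1, 11))

    def test_planted_coding_snp_effects_verified_by_codon_oracle(self, planted):
        """Independent re-translation of every planted coding SNP."""
        _, genes, genome, truth = planted
        by_id = {g.gene_id: g for g in genes}
        comp = str.maketrans("ACGT", "TGCA")
        for s in truth.snps:
            if s.region != "CDS" or s.effect == "none":
                continue
            g = by_id[s.gene_id]
            cds = g.cds_sequence(genome)
            off = g.cds_offset(s.pos)
            alt = s.alt_base if g.strand == "+" else s.alt_base.translate(comp)
            mutated = cds[:off] + alt + cds[off + 1 :]
            old_p = str(Seq(cds).translate())
            new_p = str(Seq(mutated).translate())
            ci = off // 3
            if s.effect == "synonymous":
                assert old_p == new_p
            elif s.effect == "non_synonymous":
                assert old_p != new_p and "*" not in new_p[:-1]
            elif s.effect == "stop_gain":
                assert "*" in new_p[:-1]
            elif s.effect == "start_loss":
                assert ci == 0 and new_p[0] != "M"
            elif s.effect == "stop_loss":
                assert ci == len(old_p) - 1 and new_p[-1] != "*"

    def test_sweet_contrast_variants_only_in_sweet_lines(self, planted):
        cfg, genes, _, truth = planted
        by_id = {g.gene_id: g for g in genes}
        sweet = set(cfg.sweet_lines)
        for gid, channel in truth.sweet_genes.items():
            g = by_id[gid]
            if channel == "snp":
                hits = [s for s in truth.snps if s.gene_id == gid]
                assert {s.line for s in hits} == sweet
                # every site is planted with the identical allele in each
                # sweet line (one or two independent shared sites per gene)
                by_site: dict[tuple, set] = {}
                for s in hits:
                    by_site.setdefault((s.pos, s.alt_base), set()).add(s.line)
                assert 1 <= len(by_site) <= 2
                for lines in by_site.values():
                    assert lines == sweet
            elif channel == "indel":
                hits = [i for i in truth.indels if i.gene_id == gid]
                assert {i.line for i in hits} == sweet
            else:
                hits = [
                    p for p in truth.pavs
                    if p.chrom == g.chrom and p.start < g.end and p.end > g.start
                ]
                assert {p.line for p in hits} == sweet

    def test_same_locus_same_class_rejected(self, planted):
        _, _, _, truth = planted
        dup = dataclasses.replace(truth.indels[0])
        truth2 = dataclasses.replace(truth)
        truth2.indels = truth.indels + [dup]
        with pytest.raises(ValueError, match="overlap"):
            truth2._check_no_same_class_overlap()


@pytest.fixture(scope="module")
def sim():
    cfg = small_config(seed=5)
    genome0 = simulate_genome(cfg)
    genes, genome = simulate_gene_models(cfg, genome0)
    truth = plant_variants(cfg, genome, genes)
    aligns = simulate_alignments(cfg, genome, truth)
    return cfg, genome, truth, aligns


class TestAlignments:
    def test_mean_depth_close_to_target(self, sim):
        cfg, genome, truth, aligns = sim
        L = sum(len(s) for s in genome.values())
        for line, records in aligns.items():
            aligned = sum(
                sum(n for op, n in r.cigar if op == "M") for r in records if not r.duplicate
            )
            # CNV gains/losses shift total coverage; correct for the planted ratios
            expected = cfg.depth_per_line * L
            for c in truth.cnvs:
                if c.line == line:
                    expected += (c.copy_ratio - 1) * (c.end - c.start) * cfg.depth_per_line
            for p in truth.pavs:
                if p.line == line:
                    expected -= (p.end - p.start) * cfg.depth_per_line
            assert abs(aligned - expected) / expected < 0.05

    def test_no_read_starts_in_zero_copy_segment(self):
        cfg = small_config(seed=9)
        cfg = dataclasses.replace(cfg, cnv_ratios=(0.0,))
        genome0 = simulate_genome(cfg)
        genes, genome = simulate_gene_models(cfg, genome0)
        truth = plant_variants(cfg, genome, genes)
        aligns = simulate_alignments(cfg, genome, truth)
        for c in truth.cnvs:
            if c.copy_ratio != 0.0:
                continue
            inside = [
                r for r in aligns[c.line]
                if r.chrom == c.chrom and c.start <= r.pos and r.ref_end <= c.end
            ]
            assert inside == []

    def test_pairs_straddling_pav_have_stretched_span(self, sim):
        cfg, _, truth, aligns = sim
        pav = max((p for p in truth.pavs), key=lambda p: p.end - p.start)
        dlen = pav.end - pav.start
        spans = [
            r.observed_span
            for r in aligns[pav.line]
            if r.chrom == pav.chrom and r.is_read1
            and r.ref_end <= pav.start and r.mate_pos >= pav.end
        ]
        assert len(spans) >= 6
        med = np.median(spans)
        assert abs(med - (cfg.insert_mean + dlen)) < 4 * 4 * cfg.insert_sd

    def test_unaffected_pairs_are_gapless_with_normal_span(self, sim):
        cfg, _, truth, aligns = sim
        line = cfg.lines[0]
        variant_zones = []
        for i in truth.indels:
            if i.line == line:
                variant_zones.append((i.chrom, i.pos - 600, i.pos + i.length + 600))
        for p in truth.pavs:
            if p.line == line:
                variant_zones.append((p.chrom, p.start - 600, p.end + 600))
        for c in truth.cnvs:
            if c.line == line:
                variant_zones.append((c.chrom, c.start - 600, c.end + 600))

        def clear(r):
            return all(
                not (r.chrom == chrom and r.pos < hi and r.ref_end > lo)
                for chrom, lo, hi in variant_zones
            )

        checked = 0
        for r in aligns[line]:
            if not r.is_read1 or not clear(r):
                continue
            assert all(op == "M" for op, _ in r.cigar)
            assert abs(r.observed_span - cfg.insert_mean) <= 4 * cfg.insert_sd
            checked += 1
        assert checked > 1000

    def test_alignment_determinism(self):
        cfg = small_config(seed=21)
        genome0 = simulate_genome(cfg)
        genes, genome = simulate_gene_models(cfg, genome0)
        truth = plant_variants(cfg, genome, genes)
        a = simulate_alignments(cfg, genome, truth)
        b = simulate_alignments(cfg, genome, truth)
        for line in cfg.lines:
            assert [(r.read_id, r.pos, r.seq, r.cigar) for r in a[line]] == [
                (r.read_id, r.pos, r.seq, r.cigar) for r in b[line]
            ]
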