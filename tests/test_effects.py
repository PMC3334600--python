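"""Effect annotation: region assignment, codon-level SNP classes verified by
a brute-force translate-and-diff oracle, indel frame logic, and gene-level
PAV/CNV annotation."""

import pytest
from Bio.Seq import Seq

from sorgvar.effects import (
    GeneIndex,
    annotate_sv_genes,
    classify_indel_effect,
    classify_snp_effect,
    locate_variant,
)
from sorgvar.models import CnvCall, GeneModel, IndelCall, PavCall, SnpCall

_COMP = str.maketrans("ACGT", "TGCA")


def snp(pos, ref, alt, line="l1", chrom="chr1"):
    return SnpCall(
        chrom=chrom, pos=pos, ref_base=ref, alt_base=alt, line=line,
        zygosity="hom_alt", genotype_quality=40, depth=12,
        novel_allele_mean_quality=35, mean_mapping_multiplicity=1.0,
    )


@pytest.fixture(scope="module")
def toy():
    """Plus-strand gene with one intron.

    Layout (0-based): intergenic 0..10, UTR5 10..15, CDS 15..29,
    intron 29..39 (GT…AG), CDS 39..55, UTR3 55..60.
    CDS = ATG GCT TGG TAT CCT AAA GGA TCA CTT TAA (10 codons, terminal stop).
    """
    cds1 = "ATGGCTTGGTATCC"  # 14 bases, genomic 15..29
    cds2 = "TAAAGGATCACTTTAA"  # 16 bases, genomic 39..55
    intron = "GT" + "A" * 6 + "AG"  # genomic 29..39
    seq = "T" * 10 + "CCCCC" + cds1 + intron + cds2 + "GGGGG" + "T" * 40
    gene = GeneModel(
        gene_id="g1", chrom="chr1", start=10, end=60, strand="+",
        exons=((10, 29), (39, 60)), cds=((15, 29), (39, 55)),
    )
    ref = {"chr1": seq}
    assert gene.cds_sequence(ref) == cds1 + cds2
    assert len(gene.cds_sequence(ref)) % 3 == 0
    return gene, ref


class TestLocate:
    def test_cds_position(self, toy):
        gene, ref = toy
        index = GeneIndex([gene])
        assert locate_variant("chr1", 20, index) == ("g1", "CDS")

    def test_intron_donor_base(self, toy):
        gene, ref = toy
        index = GeneIndex([gene])
        assert locate_variant("chr1", 29, index) == ("g1", "intron")
        assert gene.splice_site_positions() == {29, 30, 37, 38}

    def test_intergenic(self, toy):
        gene, _ = toy
        index = GeneIndex([gene])
        assert locate_variant("chr1", 5, index) == (None, "intergenic")


class TestSnpEffects:
    def classify(self, toy, pos, alt):
        gene, ref = toy
        index = GeneIndex([gene])
        return classify_snp_effect(snp(pos, ref["chr1"][pos], alt), index, ref)

    def test_synonymous_wobble(self, toy):
        # codon 2 GCT -> GCC (Ala -> Ala): CDS offset 5 = genomic 20
        eff = self.classify(toy, 20, "C")
        assert (eff.region, eff.effect) == ("CDS", "synonymous")
        assert eff.codon_change == "GCT>GCC"

    def test_stop_gain_mid_cds(self, toy):
        # codon 3 TGG -> TGA: CDS offset 8 = genomic 23
        eff = self.classify(toy, 23, "A")
        assert eff.effect == "stop_gain"
        assert eff.codon_change == "TGG>TGA"

    def test_non_synonymous(self, toy):
        # codon 3 TGG -> TGC (Trp -> Cys)
        eff = self.classify(toy, 23, "C")
        assert eff.effect == "non_synonymous"

    def test_start_loss(self, toy):
        eff = self.classify(toy, 15, "C")  # ATG -> CTG
        assert eff.effect == "start_loss"

    def test_stop_loss(self, toy):
        # annotated stop TAA at CDS offsets 27-29 = genomic 52-54
        eff = self.classify(toy, 53, "C")  # TAA -> TCA (Ser)
        assert eff.effect == "stop_loss"

    def test_stop_to_stop_is_synonymous(self, toy):
        eff = self.classify(toy, 54, "G")  # TAA -> TAG, still a stop
        assert eff.effect == "synonymous"

    def test_splice_disruption_at_donor(self, toy):
        eff = self.classify(toy, 29, "A")  # G of GT donor
        assert (eff.region, eff.effect) == ("intron", "splice_disrupt")

    def test_plain_intron_snp_has_no_effect(self, toy):
        eff = self.classify(toy, 33, "C")
        assert (eff.region, eff.effect) == ("intron", "none")

    def test_utr_snp(self, toy):
        eff = self.classify(toy, 12, "A")
        assert (eff.region, eff.effect) == ("UTR5", "none")


class TestSnpEffectOracle:
    def test_every_called_coding_snp_matches_translation_diff(self, small_result):
        """Brute-force oracle: mutate the CDS, translate both proteins and
        diff — agreement must be exact for every coding SNP call."""
        genes = {g.gene_id: g for g in small_result.genes}
        genome = small_result.genome
        checked = 0
        for eff in small_result.snp_effects:
            if eff.region != "CDS" or eff.effect == "none":
                continue
            g = genes[eff.gene_id]
            v = eff.variant
            cds = g.cds_sequence(genome)
            off = g.cds_offset(v.pos)
            alt = v.alt_base if g.strand == "+" else v.alt_base.translate(_COMP)
            mutated = cds[:off] + alt + cds[off + 1 :]
            old_p = str(Seq(cds).translate())
            new_p = str(Seq(mutated).translate())
            ci = off // 3
            if ci == 0:
                expected = "start_loss"
            elif ci == len(old_p) - 1:
                expected = "stop_loss" if new_p[-1] != "*" else "synonymous"
            elif new_p[ci] == "*":
                expected = "stop_gain"
            elif new_p == old_p:
                expected = "synonymous"
            else:
                expected = "non_synonymous"
            assert eff.effect == expected, (eff.gene_id, v.pos, eff.effect, expected)
            checked += 1
        assert checked >= 20

    def test_every_snp_gets_exactly_one_region_and_effect(self, small_result):
        assert len(small_result.snp_effects) == len(small_result.all_snp_calls)
        for eff in small_result.snp_effects:
            assert eff.region in ("CDS", "intron", "UTR5", "UTR3", "intergenic")

    def test_all_planted_large_effect_classes_recovered(self, small_result):
        truth_large = {
            (s.line, s.chrom, s.pos): s.effect
            for s in small_result.truth.snps
            if s.effect in ("stop_gain", "start_loss", "splice_disrupt", "stop_loss")
        }
        called = {
            (e.variant.line, e.variant.chrom, e.variant.pos): e.effect
            for e in small_result.snp_effects
        }
        recovered = {k: v for k, v in truth_large.items() if k in called}
        assert set(recovered.values()) == {
            "stop_gain", "start_loss", "splice_disrupt", "stop_loss"
        }
        for k, v in recovered.items():
            assert called[k] == v


def indel(pos, typ="del", length=3, chrom="chr1"):
    return IndelCall(
        chrom=chrom, pos=pos, type=typ, length=length, sequence="A" * length,
        line="l1", gapped_support=4, crossing_ungapped=0,
    )


class TestIndelEffects:
    def test_inframe_deletion(self, toy):
        gene, _ = toy
        eff = classify_indel_effect(indel(18, "del", 3), GeneIndex([gene]))
        assert (eff.region, eff.effect) == ("CDS", "inframe_indel")

    def test_frameshift_insertion(self, toy):
        gene, _ = toy
        eff = classify_indel_effect(indel(18, "ins", 2), GeneIndex([gene]))
        assert eff.effect == "frameshift"

    def test_intron_middle_indel_has_no_effect(self, toy):
        gene, _ = toy
        eff = classify_indel_effect(indel(32, "del", 4), GeneIndex([gene]))
        assert (eff.region, eff.effect) == ("intron", "none")

    def test_splice_zone_indel(self, toy):
        gene, _ = toy
        eff = classify_indel_effect(indel(29, "del", 2), GeneIndex([gene]))
        assert eff.effect == "splice_disrupt"

    def test_coding_non_triplet_indels_annotated_frameshift(self, small_result):
        """Cross-module invariant: every called CDS indel with length not a
        multiple of 3 is a frameshift."""
        for eff in small_result.indel_effects:
            if eff.region == "CDS":
                if eff.variant.length % 3 != 0:
                    assert eff.effect == "frameshift"
                else:
                    assert eff.effect == "inframe_indel"


class TestSvGeneAnnotation:
    def make_gene(self, gid="g1", start=1000, end=4000):
        return GeneModel(
            gene_id=gid, chrom="chr1", start=start, end=end, strand="+",
            exons=((start, end),), cds=((start + 200, end - 200),),
        )

    def test_pav_over_cds_marks_gene(self):
        g = self.make_gene()
        pav = PavCall(chrom="chr1", start=1100, end=2500, type="absence",
                      supporting_pairs=8, line="l1")
        df = annotate_sv_genes([pav], [], [g])
        assert df.loc[df.gene_id == "g1", "pav_affected"].item()

    def test_pav_over_utr_only_does_not_mark_gene(self):
        g = self.make_gene()
        pav = PavCall(chrom="chr1", start=900, end=1150, type="absence",
                      supporting_pairs=8, line="l1")
        df = annotate_sv_genes([pav], [], [g])
        assert df.empty

    def test_cnv_over_promoter_only_does_not_mark_gene(self):
        g = self.make_gene(start=5000, end=9000)
        cnv = CnvCall(chrom="chr1", start=500, end=4900, mean_depth_ratio=3.0,
                      p_value=0.01, cnv_class="gain", line="l1")
        df = annotate_sv_genes([], [cnv], [g])
        assert df.empty

    def test_gene_lost_in_two_lines_gained_in_one_records_both(self):
        g = self.make_gene()
        cnvs = [
            CnvCall(chrom="chr1", start=500, end=4500, mean_depth_ratio=0.1,
                    p_value=0.01, cnv_class="loss", line=l)
            for l in ("sweet1", "sweet2")
        ] + [
            CnvCall(chrom="chr1", start=500, end=4500, mean_depth_ratio=3.0,
                    p_value=0.01, cnv_class="gain", line="grain1")
        ]
        df = annotate_sv_genes([], cnvs, [g])
        row = df.iloc[0]
        assert row.cnv_loss_lines == "sweet1,sweet2"
        assert row.cnv_gain_lines == "grain1"
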