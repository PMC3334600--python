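"""I/O round-trips, coordinate conventions, duplicate marking and pileups."""

import numpy as np
import pytest

from sorgvar import alignio
from sorgvar.models import AlignmentRecord, CnvCall, GeneModel, IndelCall, PavCall, SnpCall


def make_record(
    pos,
    cigar=(("M", 10),),
    seq=None,
    strand="+",
    read_id="r1",
    chrom="chr1",
    quals=None,
    duplicate=False,
    multiplicity=1,
    mate_pos=None,
    is_read1=True,
):
    length = sum(n for op, n in cigar if op in "MI")
    seq = seq or "A" * length
    return AlignmentRecord(
        read_id=read_id,
        chrom=chrom,
        pos=pos,
        strand=strand,
        cigar=list(cigar),
        seq=seq,
        quals=list(quals) if quals is not None else [35] * length,
        mate_chrom=chrom,
        mate_pos=mate_pos if mate_pos is not None else pos + 400,
        observed_span=440,
        is_read1=is_read1,
        duplicate=duplicate,
        multiplicity=multiplicity,
    )


class TestFasta:
    def test_round_trip(self, tmp_path):
        seqs = {"chr1": "ACGTACGTAA", "chr2": "GGGCCC"}
        p = tmp_path / "ref.fa"
        alignio.write_reference(seqs, p)
        assert alignio.load_reference(p) == seqs

    def test_lowercase_normalised(self, tmp_path):
        p = tmp_path / "ref.fa"
        p.write_text(">chr1\nacgTAcgt\n")
        assert alignio.load_reference(p) == {"chr1": "ACGTACGT"}

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "empty.fa"
        p.write_text("")
        with pytest.raises(ValueError):
            alignio.load_reference(p)


class TestGff:
    def gene(self, **kw):
        base = dict(
            gene_id="g1",
            chrom="chr1",
            start=100,
            end=400,
            strand="+",
            exons=((100, 220), (300, 400)),
            cds=((130, 220), (300, 360)),
            category="low_confidence",
            pfam=("PF0001", "PF0002"),
            pathways=("sbi00110",),
        )
        base.update(kw)
        return GeneModel(**base)

    def test_round_trip_preserves_structure_and_attributes(self, tmp_path):
        g = self.gene()
        p = tmp_path / "genes.gff3"
        alignio.write_gene_models([g], p)
        (loaded,) = alignio.load_gene_models(p)
        assert loaded == g

    def test_missing_category_defaults_to_bona_fide(self, tmp_path, caplog):
        p = tmp_path / "genes.gff3"
        p.write_text(
            "##gff-version 3\n"
            "chr1\tx\tgene\t101\t400\t.\t+\t.\tID=g1\n"
            "chr1\tx\tmRNA\t101\t400\t.\t+\t.\tID=g1.1;Parent=g1\n"
            "chr1\tx\texon\t101\t400\t.\t+\t.\tParent=g1.1\n"
            "chr1\tx\tCDS\t131\t220\t.\t+\t0\tParent=g1.1\n"
        )
        with caplog.at_level("WARNING"):
            (loaded,) = alignio.load_gene_models(p)
        assert loaded.category == "bona_fide"
        assert any("category" in m for m in caplog.messages)

    def test_overlapping_cds_rejected(self, tmp_path):
        p = tmp_path / "genes.gff3"
        p.write_text(
            "##gff-version 3\n"
            "chr1\tx\tgene\t101\t400\t.\t+\t.\tID=g1;category=bona_fide\n"
            "chr1\tx\tmRNA\t101\t400\t.\t+\t.\tID=g1.1;Parent=g1\n"
            "chr1\tx\texon\t101\t400\t.\t+\t.\tParent=g1.1\n"
            "chr1\tx\tCDS\t131\t220\t.\t+\t0\tParent=g1.1\n"
            "chr1\tx\tCDS\t200\t260\t.\t+\t0\tParent=g1.1\n"
        )
        with pytest.raises(ValueError, match="overlapping CDS"):
            alignio.load_gene_models(p)

    def test_cds_outside_exon_rejected(self, tmp_path):
        p = tmp_path / "genes.gff3"
        p.write_text(
            "##gff-version 3\n"
            "chr1\tx\tgene\t101\t400\t.\t+\t.\tID=g1;category=bona_fide\n"
            "chr1\tx\tmRNA\t101\t400\t.\t+\t.\tID=g1.1;Parent=g1\n"
            "chr1\tx\texon\t101\t200\t.\t+\t.\tParent=g1.1\n"
            "chr1\tx\tCDS\t131\t260\t.\t+\t0\tParent=g1.1\n"
        )
        with pytest.raises(ValueError, match="CDS outside exon"):
            alignio.load_gene_models(p)


class TestSam:
    def test_round_trip(self, tmp_path):
        recs = [
            make_record(10, read_id="a", mate_pos=400, multiplicity=2),
            make_record(
                50,
                cigar=(("M", 4), ("D", 3), ("M", 6)),
                read_id="b",
                strand="-",
                is_read1=False,
            ),
        ]
        p = tmp_path / "x.sam"
        alignio.write_sam(recs, {"chr1": 1000}, p)
        loaded = alignio.load_sam(p)
        assert [(r.read_id, r.pos, r.strand, r.cigar, r.seq, r.multiplicity, r.is_read1)
                for r in loaded] == [
            (r.read_id, r.pos, r.strand, r.cigar, r.seq, r.multiplicity, r.is_read1)
            for r in recs
        ]

    def test_duplicate_marking_keeps_first_pair(self):
        a1 = make_record(10, read_id="a", mate_pos=400)
        a2 = make_record(400, read_id="a", strand="-", mate_pos=10, is_read1=False)
        b1 = make_record(10, read_id="b", mate_pos=400)
        b2 = make_record(400, read_id="b", strand="-", mate_pos=10, is_read1=False)
        c1 = make_record(20, read_id="c", mate_pos=420)
        recs = [a1, a2, b1, b2, c1]
        n = alignio.mark_duplicates(recs)
        assert n == 2
        assert not a1.duplicate and not a2.duplicate
        assert b1.duplicate and b2.duplicate
        assert not c1.duplicate


class TestPileup:
    def test_gapless_depth_counts_every_read(self):
        recs = [make_record(5, read_id=f"r{i}") for i in range(12)]
        ref = {"chr1": "C" * 40}
        cols = list(alignio.build_pileup(recs, ref, region=("chr1", 10, 11)))
        assert len(cols) == 1
        assert cols[0].depth == 12
        assert cols[0].bases["A"].count == 12

    def test_deletion_contributes_no_bases_over_gap(self):
        rec = make_record(0, cigar=(("M", 4), ("D", 2), ("M", 4)))
        ref = {"chr1": "G" * 20}
        cols = list(alignio.build_pileup([rec], ref))
        covered = {c.pos for c in cols}
        assert covered == {0, 1, 2, 3, 6, 7, 8, 9}

    def test_duplicate_reads_do_not_contribute(self):
        recs = [make_record(0, read_id="a"), make_record(0, read_id="b", duplicate=True)]
        ref = {"chr1": "T" * 20}
        cols = list(alignio.build_pileup(recs, ref, region=("chr1", 0, 1)))
        assert cols[0].depth == 1

    def test_depth_conservation_invariant(self):
        rng = np.random.default_rng(0)
        recs = [
            make_record(int(p), read_id=f"r{i}", seq="".join(rng.choice(list("ACGT"), 10)))
            for i, p in enumerate(sorted(rng.integers(0, 50, 40)))
        ]
        ref = {"chr1": "A" * 80}
        for col in alignio.build_pileup(recs, ref):
            assert col.depth == sum(b.count for b in col.bases.values())
            for ev in col.bases.values():
                assert ev.forward + ev.reverse == ev.count

    def test_unsorted_input_rejected(self):
        recs = [make_record(50), make_record(10, read_id="r2")]
        with pytest.raises(ValueError, match="sorted"):
            list(alignio.build_pileup(recs, {"chr1": "A" * 100}))


class TestVariantFiles:
    REF = {"chr1": "ACGTACGTAC" * 30}

    def test_snp_vcf_round_trip(self, tmp_path):
        calls = [
            SnpCall(
                chrom="chr1", pos=99, ref_base=self.REF["chr1"][99], alt_base="T",
                line="l1", zygosity="hom_alt", genotype_quality=40, depth=12,
                novel_allele_mean_quality=35.5, mean_mapping_multiplicity=1.02,
            ),
            SnpCall(
                chrom="chr1", pos=150, ref_base=self.REF["chr1"][150], alt_base="G",
                line="l1", zygosity="het", genotype_quality=30, depth=10,
                novel_allele_mean_quality=33.0, mean_mapping_multiplicity=1.0,
                ref_support=5, alt_support=5,
            ),
        ]
        p = tmp_path / "x.vcf"
        alignio.write_snp_vcf(calls, self.REF, p, "l1")
        loaded = alignio.read_snp_vcf(p)
        assert [(c.chrom, c.pos, c.ref_base, c.alt_base, c.zygosity, c.depth) for c in loaded] == [
            (c.chrom, c.pos, c.ref_base, c.alt_base, c.zygosity, c.depth) for c in calls
        ]

    def test_indel_vcf_anchor_convention(self, tmp_path):
        # deletion of 3 bases at 0-based pos 100 → 1-based POS 100, REF 4 bases
        call = IndelCall(
            chrom="chr1", pos=100, type="del", length=3,
            sequence=self.REF["chr1"][100:103], line="l1", gapped_support=5,
            crossing_ungapped=2,
        )
        p = tmp_path / "x.vcf"
        alignio.write_indel_vcf([call], self.REF, p, "l1")
        line = [l for l in p.read_text().splitlines() if not l.startswith("#")][0]
        fields = line.split("\t")
        assert fields[1] == "100"
        assert len(fields[3]) == 4 and len(fields[4]) == 1
        (loaded,) = alignio.read_indel_vcf(p)
        assert (loaded.chrom, loaded.pos, loaded.type, loaded.length, loaded.sequence) == (
            "chr1", 100, "del", 3, call.sequence
        )

    def test_indel_vcf_round_trip_insertion(self, tmp_path):
        call = IndelCall(
            chrom="chr1", pos=50, type="ins", length=4, sequence="TTAG",
            line="l1", gapped_support=4, crossing_ungapped=0,
        )
        p = tmp_path / "x.vcf"
        alignio.write_indel_vcf([call], self.REF, p, "l1")
        (loaded,) = alignio.read_indel_vcf(p)
        assert (loaded.pos, loaded.type, loaded.length, loaded.sequence) == (50, "ins", 4, "TTAG")

    def test_sv_bed_round_trip(self, tmp_path):
        pav = PavCall(chrom="chr1", start=100, end=2500, type="absence",
                      supporting_pairs=9, line="l1")
        cnv = CnvCall(chrom="chr1", start=5000, end=9000, mean_depth_ratio=2.7,
                      p_value=0.01, cnv_class="gain", line="l1")
        p = tmp_path / "x.bed"
        alignio.write_sv_bed([pav], [cnv], p)
        pavs, cnvs = alignio.read_sv_bed(p)
        assert pavs == [pav]
        assert cnvs == [cnv]

    def test_cnv_bed_score_is_p_value(self, tmp_path):
        cnv = CnvCall(chrom="chr1", start=5000, end=9000, mean_depth_ratio=0.1,
                      p_value=0.25, cnv_class="loss", line="l1")
        p = tmp_path / "x.bed"
        alignio.write_sv_bed([], [cnv], p)
        fields = p.read_text().strip().split("\t")
        assert fields[3] == "loss"
        assert float(fields[4]) == 0.25


class TestRegion:
    def test_one_based_inclusive_to_half_open(self):
        assert alignio.parse_region("chr1:101-200") == ("chr1", 100, 200)

    @pytest.mark.parametrize("bad", ["chr1", "chr1:5-2", "chr1:0-10"])
    def test_bad_region_rejected(self, bad):
        with pytest.raises(ValueError):
            alignio.parse_region(bad)
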