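import pytest

from sigscan import (
    FilterPolicy,
    GenomeSequence,
    MutationRecord,
    apply_filters,
    read_fasta,
    read_records_tsv,
    read_vcf_somatic,
    write_fasta,
    write_records_tsv,
    write_vcf,
)
from sigscan.genome import FastaParseError

from conftest import mk_sbs


class TestReadFasta:
    def test_case_normalization(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text(">c1\nacgt\n")
        assert read_fasta(str(p)).contigs == {"c1": "ACGT"}

    def test_multiline_and_header_token(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text(">c1 description here\nAC\nGT\n")
        assert read_fasta(str(p)).contigs == {"c1": "ACGT"}

    def test_duplicate_contig_rejected(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text(">c1\nAC\n>c1\nGG\n")
        with pytest.raises(FastaParseError, match="duplicate"):
            read_fasta(str(p))

    def test_not_fasta_rejected(self, tmp_path):
        p = tmp_path / "a.txt"
        p.write_text("ACGT\n>c1\nAC\n")
        with pytest.raises(FastaParseError, match="line 1"):
            read_fasta(str(p))

    def test_rna_rejected(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text(">c1\nACGU\n")
        with pytest.raises(FastaParseError, match="U"):
            read_fasta(str(p))

    def test_write_read_roundtrip(self, tmp_path, tiny_genome):
        p = tmp_path / "g.fa"
        write_fasta(tiny_genome, str(p), width=7)
        assert read_fasta(str(p)).contigs == tiny_genome.contigs


class TestMutationRecord:
    def test_sbs_indel_flags(self):
        assert mk_sbs(ref="C", alt="T").is_sbs
        rec = mk_sbs(ref="CA", alt="C")
        assert rec.is_indel and not rec.is_sbs
        mnv = mk_sbs(ref="CA", alt="TG")
        assert not mnv.is_sbs and not mnv.is_indel  # kept as a distinct class

    def test_invalid_alleles_rejected(self):
        with pytest.raises(ValueError):
            mk_sbs(ref="C", alt="C")
        with pytest.raises(ValueError):
            mk_sbs(ref="X", alt="T")

    def test_inconsistent_vaf_rejected(self):
        with pytest.raises(ValueError, match="vaf"):
            MutationRecord("S1", "c1", 5, "C", "T", 10, 50, 0.5)


VCF_TEXT = """\
##fileformat=VCFv4.2
##contig=<ID=c1,length=1000>
##FILTER=<ID=clustered_events,Description="clustered">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tT1
c1\t100\t.\tC\tT\t.\tPASS\t.\tGT:AD\t0/1:20,5
c1\t200\t.\tC\tT,G\t.\tPASS\t.\tGT:AD\t0/1:10,4,6
c1\t300\t.\tCA\tC\t.\tPASS\t.\tGT:AD\t0/1:10,5
c1\t400\t.\tC\tT\t.\tclustered_events\t.\tGT:AD\t0/1:10,5
c1\t500\t.\tG\tA\t.\t.\t.\tGT:AD\t0/1:12,4
"""


class TestReadVcf:
    @pytest.fixture
    def vcf_path(self, tmp_path):
        p = tmp_path / "t.vcf"
        p.write_text(VCF_TEXT)
        return str(p)

    def test_field_mapping(self, vcf_path):
        records = read_vcf_somatic(vcf_path, "T1")
        first = records[0]
        assert (first.contig, first.position) == ("c1", 100)
        assert (first.ref_allele, first.alt_allele) == ("C", "T")
        assert (first.alt_depth, first.total_depth) == (5, 25)
        assert first.vaf == pytest.approx(0.2)

    def test_multiallelic_split(self, vcf_path):
        records = read_vcf_somatic(vcf_path, "T1")
        at_200 = [r for r in records if r.position == 200]
        assert [(r.alt_allele, r.alt_depth, r.total_depth) for r in at_200] == [
            ("T", 4, 20),
            ("G", 6, 20),
        ]

    def test_filter_fail_excluded_dot_kept(self, vcf_path):
        positions = {r.position for r in read_vcf_somatic(vcf_path, "T1")}
        assert 400 not in positions  # non-PASS filter
        assert 500 in positions  # FILTER "." counts as pass

    def test_indel_representation(self, vcf_path):
        indel = [r for r in read_vcf_somatic(vcf_path, "T1") if r.position == 300][0]
        assert (indel.ref_allele, indel.alt_allele) == ("CA", "C")
        assert indel.is_indel


class TestApplyFilters:
    def test_boundary_values_kept(self):
        rec = mk_sbs(alt_depth=3, total_depth=10)  # vaf 0.30
        assert apply_filters([rec]) == [rec]

    def test_vaf_boundary_strict(self):
        rec = MutationRecord("S1", "c1", 10, "C", "T", 3, 60, 0.05)
        assert apply_filters([rec]) == []

    def test_mitochondrial_excluded(self):
        rec = mk_sbs(contig="chrM", alt_depth=5, total_depth=50)
        assert apply_filters([rec]) == []

    def test_each_rule_and_order_preserved(self):
        keep1 = mk_sbs(pos=1, alt_depth=10, total_depth=40)
        low_alt = mk_sbs(pos=2, alt_depth=2, total_depth=40)
        low_depth = mk_sbs(pos=3, alt_depth=4, total_depth=8)
        keep2 = mk_sbs(pos=4, alt_depth=6, total_depth=30)
        assert apply_filters([keep1, low_alt, low_depth, keep2]) == [keep1, keep2]

    def test_idempotent(self):
        records = [
            mk_sbs(pos=i, alt_depth=a, total_depth=d)
            for i, (a, d) in enumerate([(3, 10), (2, 10), (20, 25), (5, 9)], start=1)
        ]
        once = apply_filters(records)
        assert apply_filters(once) == once
        assert len(once) <= len(records)

    def test_missing_depth_is_error(self):
        rec = MutationRecord("S1", "c1", 5, "C", "T")
        with pytest.raises(ValueError, match="lacks depth"):
            apply_filters([rec])
        # a policy that needs nothing passes the record through
        lax = FilterPolicy(min_alt_reads=0, min_total_reads=0, min_vaf=0.0)
        with pytest.raises(ValueError, match="VAF"):
            apply_filters([rec], lax)


class TestRoundTrips:
    def test_vcf_round_trip(self, tmp_path, sim_genome):
        records = [
            mk_sbs(contig="c1", pos=50, ref=sim_genome.base("c1", 50), alt="A"
                   if sim_genome.base("c1", 50) != "A" else "T"),
            mk_sbs(contig="c2", pos=99, ref=sim_genome.base("c2", 99), alt="A"
                   if sim_genome.base("c2", 99) != "A" else "T"),
        ]
        path = tmp_path / "out.vcf"
        write_vcf(records, str(path), genome=sim_genome)
        back = read_vcf_somatic(str(path), "S1")
        key = lambda r: (r.contig, r.position, r.ref_allele, r.alt_allele, r.sample_id)
        assert sorted(map(key, back)) == sorted(map(key, records))
        assert all(
            (r.alt_depth, r.total_depth) == (20, 50) for r in back
        )

    def test_tsv_round_trip(self, tmp_path):
        records = [mk_sbs(pos=5), mk_sbs(pos=9, ref="CA", alt="C")]
        path = tmp_path / "r.tsv"
        write_records_tsv(records, str(path))
        assert read_records_tsv(str(path)) == records
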