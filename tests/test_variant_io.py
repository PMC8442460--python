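"""VCF/TSV/BED reading and writing, and the round-trip guarantees."""

import warnings

import pytest

from phasekit import simulate as sim
from phasekit import variant_io as vio
from phasekit.variant_io import (
    HaplotagRecord,
    MethylationCall,
    Region,
    TableParseError,
    VariantRecord,
    parse_supporting_reads,
)

VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=SVTYPE,Number=1,Type=String,Description="x">
##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="x">
##INFO=<ID=RNAMES,Number=.,Type=String,Description="x">
##FORMAT=<ID=GT,Number=1,Type=String,Description="x">
##FORMAT=<ID=PS,Number=1,Type=Integer,Description="x">
##contig=<ID=1>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1
"""


def write_vcf_text(tmp_path, *rows):
    path = tmp_path / "in.vcf"
    path.write_text(VCF_HEADER + "".join(r + "\n" for r in rows))
    return path


class TestReadVcf:
    def test_header_only_gives_empty_sequence(self, tmp_path):
        assert vio.read_vcf(write_vcf_text(tmp_path)) == []

    def test_sv_row_hand_parsed(self, tmp_path):
        path = write_vcf_text(
            tmp_path, "1\t100\t.\tA\tT\t30\tPASS\tSVTYPE=DEL;SVLEN=-120;RNAMES=r1,r2\tGT\t0/1"
        )
        (rec,) = vio.read_vcf(path)
        assert (rec.chrom, rec.pos, rec.ref, rec.alt) == ("1", 100, "A", "T")
        assert rec.qual == 30
        assert rec.sv_type == "DEL" and rec.sv_len == -120
        assert rec.supporting_reads == ("r1", "r2")
        assert not rec.phased and rec.ps is None and rec.gt == (0, 1)

    def test_phased_gt_reads_ps(self, tmp_path):
        path = write_vcf_text(tmp_path, "1\t100\t.\tA\tT\t30\tPASS\t.\tGT:PS\t1|0:7")
        (rec,) = vio.read_vcf(path)
        assert rec.phased and rec.ps == 7 and rec.gt == (1, 0)

    def test_unphased_gt_leaves_ps_missing(self, tmp_path):
        path = write_vcf_text(tmp_path, "1\t100\t.\tA\tT\t30\tPASS\t.\tGT\t0/1")
        (rec,) = vio.read_vcf(path)
        assert not rec.phased and rec.ps is None

    def test_multiallelic_row_split_per_alt(self, tmp_path):
        path = write_vcf_text(tmp_path, "1\t100\t.\tA\tT,G\t30\tPASS\t.\tGT\t1/2")
        recs = vio.read_vcf(path)
        assert [r.alt for r in recs] == ["T", "G"]
        assert recs[0].gt == (1, 0) and recs[1].gt == (0, 1)

    def test_missing_gt_skipped_with_warning(self, tmp_path):
        path = write_vcf_text(tmp_path, "1\t100\t.\tA\tT\t30\tPASS\t.\tGT\t./.")
        with pytest.warns(UserWarning, match="missing GT"):
            assert vio.read_vcf(path) == []

    def test_rnames_deduplicated_in_order(self, tmp_path):
        path = write_vcf_text(
            tmp_path, "1\t100\t.\tA\tT\t30\tPASS\tSVTYPE=INS;RNAMES=r1,r2,r1\tGT\t0/1"
        )
        (rec,) = vio.read_vcf(path)
        assert parse_supporting_reads(rec) == ("r1", "r2")

    def test_no_rnames_is_empty_not_error(self, tmp_path):
        path = write_vcf_text(tmp_path, "1\t100\t.\tA\tT\t30\tPASS\tSVTYPE=INS\tGT\t0/1")
        (rec,) = vio.read_vcf(path)
        assert parse_supporting_reads(rec) == ()


class TestWriteVcf:
    def test_empty_sequence_gives_header_only(self, tmp_path):
        out = tmp_path / "out.vcf"
        vio.write_phased_vcf([], out)
        body = [l for l in out.read_text().splitlines() if not l.startswith("#")]
        assert body == []
        assert vio.read_vcf(out) == []

    def test_phased_del_row_layout(self, tmp_path):
        rec = VariantRecord(
            chrom="1", pos=100, ref="A", alt="<DEL>", qual=30.0,
            filter=frozenset({"PASS"}), gt=(1, 0), phased=True, ps=500,
            sv_type="DEL", sv_len=-120, conflict=0,
        )
        out = tmp_path / "out.vcf"
        vio.write_phased_vcf([rec], out)
        (line,) = [l for l in out.read_text().splitlines() if not l.startswith("#")]
        assert "1|0:500" in line and "CONFLICT=0" in line and line.split("\t")[8] == "GT:PS"

    def test_unphased_record_has_slash_and_no_ps(self, tmp_path):
        rec = VariantRecord(chrom="1", pos=5, ref="A", alt="T", gt=(0, 1))
        out = tmp_path / "out.vcf"
        vio.write_phased_vcf([rec], out)
        (line,) = [l for l in out.read_text().splitlines() if not l.startswith("#")]
        assert "0/1" in line and "PS" not in line.split("\t")[8]

    def test_unsorted_input_rejected(self, tmp_path):
        recs = [
            VariantRecord(chrom="1", pos=200, ref="A", alt="T"),
            VariantRecord(chrom="1", pos=100, ref="A", alt="T"),
        ]
        with pytest.raises(ValueError, match="not sorted"):
            vio.write_phased_vcf(recs, tmp_path / "out.vcf")

    def test_interleaved_contigs_rejected(self, tmp_path):
        recs = [
            VariantRecord(chrom="1", pos=100, ref="A", alt="T"),
            VariantRecord(chrom="2", pos=50, ref="A", alt="T"),
            VariantRecord(chrom="1", pos=200, ref="A", alt="T"),
        ]
        with pytest.raises(ValueError, match="appears twice"):
            vio.write_phased_vcf(recs, tmp_path / "out.vcf")


class TestRoundTrip:
    def test_fixture_vcf_round_trip_preserves_all_fields(self, tmp_path, truth, reads):
        tags, read_df = reads
        svs, _ = sim.simulate_svs(truth, read_df, n_sv=30, n_conflict_reads=1, seed=3)
        records = sorted(truth + svs, key=lambda r: r.pos)
        first = tmp_path / "a.vcf"
        vio.write_phased_vcf(records, first)
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            back = vio.read_vcf(first)
        assert back == records

    def test_second_write_is_byte_identical(self, tmp_path, truth):
        first, second = tmp_path / "a.vcf", tmp_path / "b.vcf"
        vio.write_phased_vcf(truth, first)
        vio.write_phased_vcf(vio.read_vcf(first), second)
        assert first.read_bytes() == second.read_bytes()


class TestHaplotagTable:
    def test_empty_table(self, tmp_path):
        path = tmp_path / "t.tsv"
        path.write_text("#read_name\tchrom\tstart\tend\thp\tps\n")
        assert vio.read_haplotag_table(path) == []

    def test_single_row(self, tmp_path):
        path = tmp_path / "t.tsv"
        path.write_text("r1\tchr1\t0\t1000\t1\t77\n")
        (rec,) = vio.read_haplotag_table(path)
        assert rec == HaplotagRecord("r1", "chr1", 0, 1000, 1, 77)

    def test_hp_out_of_domain_rejected(self, tmp_path):
        path = tmp_path / "t.tsv"
        path.write_text("r1\tchr1\t0\t1000\t3\t77\n")
        with pytest.raises(TableParseError, match="hp must be 1 or 2"):
            vio.read_haplotag_table(path)

    def test_wrong_column_count_names_line(self, tmp_path):
        path = tmp_path / "t.tsv"
        path.write_text("r1\tchr1\t0\t1000\t1\t77\nr2\tchr1\t0\n")
        with pytest.raises(TableParseError, match=":2"):
            vio.read_haplotag_table(path)

    def test_duplicate_read_on_same_chrom_rejected(self, tmp_path):
        path = tmp_path / "t.tsv"
        path.write_text("r1\tchr1\t0\t1000\t1\t77\nr1\tchr1\t2000\t3000\t2\t77\n")
        with pytest.raises(TableParseError, match="duplicate"):
            vio.read_haplotag_table(path)

    def test_write_read_round_trip(self, tmp_path, tags):
        path = tmp_path / "t.tsv"
        vio.write_haplotag_table(tags, path)
        assert vio.read_haplotag_table(path) == tags


class TestMethylationTable:
    HEADER = "chromosome\tstart\tend\tread_name\tlog_lik_ratio\tnum_motifs\n"

    def test_header_only_gives_empty(self, tmp_path):
        path = tmp_path / "m.tsv"
        path.write_text(self.HEADER)
        assert vio.read_methylation_tsv(path) == []

    def test_row_parsed_with_dot_phase(self, tmp_path):
        path = tmp_path / "m.tsv"
        path.write_text(self.HEADER + "chrT\t10\t11\tr1\t2.5\t1\n")
        (call,) = vio.read_methylation_tsv(path)
        assert call.llr == 2.5 and call.hp == "." and call.ps == "."

    def test_missing_column_named_in_error(self, tmp_path):
        path = tmp_path / "m.tsv"
        path.write_text("chromosome\tstart\tend\tlog_lik_ratio\tnum_motifs\nchrT\t1\t2\t2.5\t1\n")
        with pytest.raises(TableParseError, match="read_name"):
            vio.read_methylation_tsv(path)

    def test_phased_table_round_trip(self, tmp_path):
        calls = [
            MethylationCall("r1", "chrT", 10, 11, 2.5, 1, hp=2, ps=9),
            MethylationCall("r2", "chrT", 10, 11, -3.0, 1),
        ]
        path = tmp_path / "m.tsv"
        vio.write_methylation_tsv(calls, path)
        assert vio.read_methylation_tsv(path) == calls


class TestBed:
    def test_bed3_plus_name(self, tmp_path):
        path = tmp_path / "r.bed"
        path.write_text("chr1\t0\t100\tGENE1\nchr2\t50\t60\n")
        regions = vio.read_bed(path)
        assert regions == [Region("chr1", 0, 100, "GENE1"), Region("chr2", 50, 60, ".")]

    def test_too_few_columns_rejected(self, tmp_path):
        path = tmp_path / "r.bed"
        path.write_text("chr1\t0\n")
        with pytest.raises(TableParseError):
            vio.read_bed(path)


class TestDomainInvariants:
    def test_phased_record_requires_ps(self):
        with pytest.raises(ValueError, match="PS"):
            VariantRecord(chrom="1", pos=1, ref="A", alt="T", phased=True)

    def test_position_must_be_one_based(self):
        with pytest.raises(ValueError, match="pos"):
            VariantRecord(chrom="1", pos=0, ref="A", alt="T")

    def test_haplotag_span_must_be_nonempty(self):
        with pytest.raises(ValueError):
            HaplotagRecord("r", "1", 10, 10, 1, 1)

    def test_methylation_phase_fields_move_together(self):
        with pytest.raises(ValueError):
            MethylationCall("r", "1", 0, 1, 2.0, hp=1, ps=".")
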