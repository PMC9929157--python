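import pytest

from clonocna import airr_io
from clonocna.errors import FormatError
from clonocna.models import Clonotype


def write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadRearrangements:
    def test_junction_stripped_to_cdr3(self, tmp_path):
        p = write(
            tmp_path, "a.tsv",
            "sequence_id\tv_call\tjunction_aa\tproductive\tv_identity\n"
            "r1\tTRBV12-3*01\tCASSLKF\tT\t97.2\n"
            "r2\tTRBV19*01\tCAWSVGQF\ttrue\t99.0\n"
            "r3\tTRBV28*01\tCASRPDW\tF\t96.0\n",
        )
        rs = airr_io.read_rearrangements(p)
        assert rs.n_input_rows == 3 and not rs.rejected
        assert [r.cdr3_aa for r in rs.records] == ["ASSLK", "AWSVGQ", "ASRPD"]
        assert rs.records[0].productive and rs.records[0].v_identity == 97.2
        assert not rs.records[2].productive

    def test_missing_v_call_column_is_format_error(self, tmp_path):
        p = write(tmp_path, "b.tsv", "sequence_id\tjunction_aa\tproductive\tv_identity\nr1\tCAF\tT\t99\n")
        with pytest.raises(FormatError, match="v_call"):
            airr_io.read_rearrangements(p)

    def test_bad_rows_rejected_not_dropped(self, tmp_path):
        p = write(
            tmp_path, "c.tsv",
            "sequence_id\tv_call\tcdr3_aa\tproductive\tv_identity\n"
            "r1\tTRBV19*01\tASSLK\tT\t99\n"
            "r2\tTRBV19*01\tASSLK\tmaybe\t99\n"       # unparseable productive
            "r3\tTRBV19*01\tASSLK\tT\t190\n"          # identity out of range
            "r4\tTRBV19*01\tASS*K\tT\t99\n",          # stop in productive CDR3
        )
        rs = airr_io.read_rearrangements(p)
        assert len(rs.records) == 1 and len(rs.rejected) == 3
        assert rs.n_input_rows == 4
        assert "maybe" in rs.rejected[0].reason

    def test_fractional_identity_autoscaled(self, tmp_path):
        p = write(
            tmp_path, "d.tsv",
            "sequence_id\tv_call\tcdr3_aa\tproductive\tv_identity\n"
            "r1\tTRBV19*01\tASSLK\tT\t0.972\n",
        )
        rs = airr_io.read_rearrangements(p)
        assert rs.records[0].v_identity == pytest.approx(97.2)

    def test_dialect_maps_other_headers(self, tmp_path):
        p = write(
            tmp_path, "e.tsv",
            "id\tVgene\tCDR3\tfunctional\tidentity\n"
            "r1\tTRBV19*01\tASSLK\tT\t99\n",
        )
        rs = airr_io.read_rearrangements(
            p,
            dialect={"sequence_id": "id", "v_call": "Vgene", "cdr3_aa": "CDR3",
                     "productive": "functional", "v_identity": "identity"},
        )
        assert rs.records[0].v_call == "TRBV19*01"

    def test_empty_cdr3_retained(self, tmp_path):
        p = write(
            tmp_path, "f.tsv",
            "sequence_id\tv_call\tcdr3_aa\tproductive\tv_identity\n"
            "r1\tTRBV19*01\t\tT\t99\n",
        )
        rs = airr_io.read_rearrangements(p)
        assert len(rs.records) == 1 and rs.records[0].cdr3_aa == ""


class TestReferenceDB:
    def test_duplicates_collapsed_and_alleles_stripped(self, tmp_path):
        p = write(
            tmp_path, "db.tsv",
            "v_gene\tcdr3_aa\n"
            "TRBV19*01\tCASSF\nTRBV19\tCASSF\nTRBV19\tCASSF\n"
            "TRBV12-3\tCAWF\nTRBV28\tCASRF\n",
        )
        db = airr_io.read_reference_db(p)
        assert len(db) == 3
        assert ("TRBV19", "CASSF") in db

    def test_header_only_gives_empty_db(self, tmp_path):
        p = write(tmp_path, "db2.tsv", "v_gene\tcdr3_aa\n")
        assert len(airr_io.read_reference_db(p)) == 0


class TestClonotypeRoundTrip:
    def test_write_read_is_identity(self, tmp_path):
        clonotypes = [
            Clonotype("s1", "TRBV19", "CASSF", 3, 0.6, 1),
            Clonotype("s1", "TRBV12-3", "CAWF", 2, 1 / 3, 2),
        ]
        p = tmp_path / "c.tsv"
        airr_io.write_clonotype_table(p, clonotypes)
        assert airr_io.read_clonotype_table(p) == clonotypes


class TestFastaAndHla:
    def test_terminator_stripped_and_uppercased(self, tmp_path):
        p = write(tmp_path, "p.fa", ">p53\nmeepq*\n")
        assert airr_io.read_protein_fasta(p) == {"p53": "MEEPQ"}

    def test_bad_residue_reported_with_position(self, tmp_path):
        p = write(tmp_path, "p.fa", ">x\nMEXPQ\n")
        with pytest.raises(FormatError, match="position 3"):
            airr_io.read_protein_fasta(p)

    def test_hla_lines_verbatim(self, tmp_path):
        p = write(tmp_path, "h.txt", "HLA-B*27:05\nHLA-A*02:01\n\n# comment\n")
        assert airr_io.read_hla_list(p) == ["HLA-B*27:05", "HLA-A*02:01"]


def test_normalize_v_gene():
    assert airr_io.normalize_v_gene("TRBV12-3*01") == "TRBV12-3"
    assert airr_io.normalize_v_gene("TRBV12-3*01, TRBV12-4*01") == "TRBV12-3"
    assert airr_io.normalize_v_gene(" TRBV19 ") == "TRBV19"
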