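import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clonocna import clonotyping
from clonocna.errors import InputError
from conftest import make_read


class TestFilters:
    @pytest.mark.parametrize(
        "v_identity,kept", [(94.9, False), (95.0, True), (97.0, True)]
    )
    def test_germline_identity_boundary(self, v_identity, kept):
        """<95% identity discarded; the boundary value itself is kept."""
        rows = [make_read(v_identity=v_identity)]
        k, d = clonotyping.filter_rearrangements(rows)
        assert (len(k) == 1) is kept
        if not kept:
            assert d[0][1] == clonotyping.REASON_LOW_V_IDENTITY

    def test_non_productive_discarded_first(self):
        rows = [make_read(productive=False, v_identity=99.0)]
        _, d = clonotyping.filter_rearrangements(rows)
        assert d[0][1] == clonotyping.REASON_NON_PRODUCTIVE

    def test_empty_cdr3_discarded(self):
        rows = [make_read(cdr3="")]
        _, d = clonotyping.filter_rearrangements(rows)
        assert d[0][1] == clonotyping.REASON_EMPTY_CDR3

    def test_empty_input(self):
        assert clonotyping.filter_rearrangements([]) == ([], [])


class TestCallClonotypes:
    def test_same_cdr3_different_v_gene_distinct(self):
        rows = [make_read(v_call="TRBV12-3*01", cdr3="CASSLKF", seq_id=f"a{i}") for i in range(3)]
        rows += [make_read(v_call="TRBV29-1*01", cdr3="CASSLKF", seq_id=f"b{i}") for i in range(2)]
        rep = clonotyping.call_clonotypes(rows)
        assert len(rep) == 2
        by_gene = {c.v_gene: c.frequency for c in rep.clonotypes}
        assert by_gene == {"TRBV12-3": pytest.approx(0.6), "TRBV29-1": pytest.approx(0.4)}

    def test_alleles_collapse_to_one_clonotype(self):
        rows = [
            make_read(v_call="TRBV12-3*01", cdr3="CASSF", seq_id="a"),
            make_read(v_call="TRBV12-3*02", cdr3="CASSF", seq_id="b"),
        ]
        rep = clonotyping.call_clonotypes(rows)
        assert len(rep) == 1 and rep.clonotypes[0].frequency == 1.0

    def test_single_clonotype_degenerate(self):
        rows = [make_read(seq_id=f"r{i}") for i in range(6)]
        rep = clonotyping.call_clonotypes(rows)
        assert len(rep) == 1 and rep.clonotypes[0].frequency == 1.0
        assert rep.clonotypes[0].read_count == 6

    def test_mixed_samples_rejected(self):
        rows = [make_read(sample_id="a"), make_read(sample_id="b")]
        with pytest.raises(InputError, match="mixed sample_ids"):
            clonotyping.call_clonotypes(rows)

    def test_duplicate_count_weighting(self):
        rows = [
            make_read(cdr3="CASSA", count=7, seq_id="a"),
            make_read(cdr3="CASSB", count=3, seq_id="b"),
        ]
        rep = clonotyping.call_clonotypes(rows)
        assert rep.n_reads_kept == 10
        assert rep.clonotypes[0].frequency == pytest.approx(0.7)

    @settings(max_examples=50, deadline=None)
    @given(
        st.lists(
            st.tuples(st.sampled_from(["TRBV1*01", "TRBV2*01", "TRBV3*01"]),
                      st.sampled_from(["CASA", "CASB", "CASC", "CASD"]),
                      st.integers(1, 5)),
            min_size=1, max_size=100,
        )
    )
    def test_matches_bruteforce_grouping(self, triples):
        """call_clonotypes equals a dictionary-grouping oracle."""
        rows = [
            make_read(v_call=v, cdr3=c, count=n, seq_id=f"r{i}")
            for i, (v, c, n) in enumerate(triples)
        ]
        rep = clonotyping.call_clonotypes(rows)

        oracle: dict = {}
        for v, c, n in triples:
            oracle[(v.split("*")[0], c)] = oracle.get((v.split("*")[0], c), 0) + n
        total = sum(oracle.values())
        assert len(rep) == len(oracle) <= len(rows)
        for clone in rep.clonotypes:
            assert clone.read_count == oracle[clone.key]
            assert clone.frequency == pytest.approx(oracle[clone.key] / total)
        assert sum(rep.frequencies()) == pytest.approx(1.0, abs=1e-9)
        # frequencies invariant under row order
        rep2 = clonotyping.call_clonotypes(list(reversed(rows)))
        assert {c.key: c.frequency for c in rep2.clonotypes} == {
            c.key: c.frequency for c in rep.clonotypes
        }


class TestMajorClonotypes:
    def test_top10_of_twelve(self, twelve_count_repertoire):
        major = clonotyping.major_clonotypes(twelve_count_repertoire, 10)
        assert len(major) == 10
        assert sum(c.read_count for c in major) == 96

    def test_fewer_than_n_returns_all(self, twelve_count_repertoire):
        assert len(clonotyping.major_clonotypes(twelve_count_repertoire, 20)) == 12

    def test_tie_break_is_deterministic(self):
        rows = [
            make_read(v_call="TRBV2*01", cdr3="CASB", seq_id="a"),
            make_read(v_call="TRBV1*01", cdr3="CASA", seq_id="b"),
        ]
        rep = clonotyping.call_clonotypes(rows)
        # tied counts: CDR3 lexicographic ascending decides rank 1
        assert rep.clonotypes[0].cdr3_aa == "CASA"
        top1 = clonotyping.major_clonotypes(rep, 1)
        assert top1[0].cdr3_aa == "CASA"
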