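import numpy as np
import pytest

from clonocna import neoepitopes as neo
from clonocna.errors import ContractError, CoordinateError, InputError
from clonocna.models import MutantProtein
from conftest import make_repertoire

AA = "ACDEFGHIKLMNPQRSTVWY"


def bruteforce_kmers(mp: MutantProtein, kmin=9, kmax=15, flank=15) -> set:
    """Independent oracle: all substrings, then filter by the window /
    altered-position rules."""
    protein = mp.mut_protein
    L = len(protein)
    out = set()
    if mp.frameshift:
        fs = mp.frameshift_start
        for k in range(kmin, kmax + 1):
            for start in range(1, L - k + 2):
                if start >= fs:
                    out.add(protein[start - 1 : start + k - 1])
        return out
    for k in range(kmin, kmax + 1):
        for start in range(1, L - k + 2):
            end = start + k - 1
            for pos in mp.altered_positions:
                lo, hi = max(1, pos - flank), min(L, pos + flank)
                if start >= lo and end <= hi and start <= pos <= end:
                    out.add(protein[start - 1 : end])
                    break
    return out


class TestHgvsParsing:
    CDS = "ATGCCAGGATGTTGA"

    def test_substitution(self):
        v = neo.parse_hgvs_c("g", self.CDS, "c.4C>T")
        assert v.kind == "substitution" and v.positions == (4,)

    def test_reference_mismatch(self):
        with pytest.raises(CoordinateError, match="reference base"):
            neo.parse_hgvs_c("g", self.CDS, "c.4A>T")

    def test_out_of_range(self):
        with pytest.raises(CoordinateError, match="outside CDS"):
            neo.parse_hgvs_c("g", self.CDS, "c.99A>T")

    def test_deletion_and_insertion(self):
        d = neo.parse_hgvs_c("g", self.CDS, "c.4_5del")
        assert d.kind == "deletion" and d.positions == (4, 5)
        i = neo.parse_hgvs_c("g", self.CDS, "c.6_7insAC")
        assert i.kind == "insertion" and i.alt == "AC"


class TestApplyVariant:
    CDS = "ATGCCAGGATGTTGA"  # M P G C *

    def test_missense(self):
        mp = neo.apply_variant(neo.parse_hgvs_c("g", self.CDS, "c.4C>T"))
        assert mp.ref_protein == "MPGC"
        assert mp.mut_protein == "MSGC"
        assert mp.altered_positions == {2} and not mp.frameshift

    def test_two_base_deletion_frameshift(self):
        # ATG AGG ATG TTG A -> MRML, shifted from residue 2 onward
        mp = neo.apply_variant(neo.parse_hgvs_c("g", self.CDS, "c.4_5del"))
        assert mp.frameshift and mp.frameshift_start == 2
        assert mp.mut_protein == "MRML"
        assert mp.altered_positions == {2, 3, 4}

    def test_in_frame_deletion(self):
        mp = neo.apply_variant(neo.parse_hgvs_c("g", self.CDS, "c.4_6del"))
        assert not mp.frameshift and mp.mut_protein == "MGC"

    def test_synonymous_warns_with_empty_altered_set(self):
        # c.6A>G: CCA -> CCG, still Pro
        with pytest.warns(UserWarning, match="synonymous"):
            mp = neo.apply_variant(neo.parse_hgvs_c("g", self.CDS, "c.6A>G"))
        assert mp.altered_positions == set()

    def test_substitution_semantics_at_codon_34(self):
        """c.100C>T on a 50-codon CDS with Pro at codon 34 -> Ser34."""
        codons = ["ATG"] + ["GCT"] * 32 + ["CCA"] + ["GCT"] * 15 + ["TAA"]
        cds = "".join(codons)
        assert cds[99:102] == "CCA"  # codon 34 starts at c.100
        mp = neo.apply_variant(neo.parse_hgvs_c("TP53", cds, "c.100C>T"))
        assert mp.ref_protein[33] == "P" and mp.mut_protein[33] == "S"
        assert mp.altered_positions == {34}


class TestEnumerateKmers:
    def test_interior_missense_with_full_flanks(self):
        protein = "".join(AA[i % 20] for i in range(41))
        mp = MutantProtein("g", protein, protein, altered_positions={21})
        assert len(neo.enumerate_kmers(mp)) == 84  # sum of k for k in 9..15

    def test_n_terminal_missense(self):
        protein = "".join(AA[i % 19] for i in range(30))
        mp = MutantProtein("g", protein, protein, altered_positions={1})
        assert len(neo.enumerate_kmers(mp)) == 7  # one k-mer per k

    def test_frameshift_suffix_of_20(self):
        protein = "".join(AA[(i * 7) % 20] for i in range(40))
        mp = MutantProtein("g", protein, protein, altered_positions=set(range(21, 41)),
                           frameshift=True, frameshift_start=21)
        assert len(neo.enumerate_kmers(mp)) == 63  # sum of (20-k+1)

    def test_short_protein_warns_empty(self):
        mp = MutantProtein("g", "MAW", "MAW", altered_positions={2})
        with pytest.warns(UserWarning):
            assert neo.enumerate_kmers(mp) == []

    def test_peptides_contain_altered_position_and_are_substrings(self, rng):
        for _ in range(300):
            L = int(rng.integers(9, 61))
            protein = "".join(AA[i] for i in rng.integers(0, 20, L))
            pos = int(rng.integers(1, L + 1))
            mp = MutantProtein("g", protein, protein, altered_positions={pos})
            for c in neo.enumerate_kmers(mp):
                assert c.peptide in protein
                assert any(a <= pos <= b for a, b in c.source_spans)

    def test_equals_bruteforce_oracle(self, rng):
        for trial in range(200):
            L = int(rng.integers(9, 61))
            protein = "".join(AA[i] for i in rng.integers(0, 20, L))
            if trial % 2:
                fs = int(rng.integers(1, L + 1))
                mp = MutantProtein("g", protein, protein,
                                   altered_positions=set(range(fs, L + 1)),
                                   frameshift=True, frameshift_start=fs)
            else:
                n_pos = int(rng.integers(1, 4))
                positions = set(int(p) for p in rng.integers(1, L + 1, n_pos))
                mp = MutantProtein("g", protein, protein, altered_positions=positions)
            got = {c.peptide for c in neo.enumerate_kmers(mp)}
            assert got == bruteforce_kmers(mp)

    def test_filtered_set_monotone_in_cutoff(self, rng):
        protein = "".join(AA[i % 20] for i in range(41))
        mp = MutantProtein("g", protein, protein, altered_positions={21})
        scored = neo.score_immunogenicity(
            neo.enumerate_kmers(mp), neo.HashImmunogenicityScorer(seed=1)
        )
        strict = {c.peptide for c in scored if c.filtered_in}
        lowered = {
            c.peptide
            for c in neo.score_immunogenicity(
                neo.enumerate_kmers(mp), neo.HashImmunogenicityScorer(seed=1), cut=0.8
            )
            if c.filtered_in
        }
        assert strict <= lowered


class TestScoringAndBinding:
    def make_candidates(self, peptides):
        return [neo.EpitopeCandidate(peptide=p, source_spans=[(1, len(p))]) for p in peptides]

    def test_strict_immunogenicity_boundary(self):
        class FixedScorer:
            name = "fixed"
            table = {"AAAAAAAAA": 0.95, "CCCCCCCCC": 0.90, "DDDDDDDDD": 0.89}

            def __call__(self, peptide):
                return self.table[peptide]

        scored = neo.score_immunogenicity(
            self.make_candidates(list(FixedScorer.table)), FixedScorer()
        )
        kept = {c.peptide for c in scored if c.filtered_in}
        assert kept == {"AAAAAAAAA"}

    def test_planted_scorer_selects_exactly_planted(self):
        peptides = [a * 9 for a in "ACDEFGHIK"]
        planted = set(peptides[:5])
        scored = neo.score_immunogenicity(
            self.make_candidates(peptides), neo.PlantedImmunogenicityScorer(planted)
        )
        assert {c.peptide for c in scored if c.filtered_in} == planted

    def test_out_of_range_scorer_is_contract_error(self):
        class BadScorer:
            name = "bad"

            def __call__(self, peptide):
                return 1.5

        with pytest.raises(ContractError, match="bad"):
            neo.score_immunogenicity(self.make_candidates(["AAAAAAAAA"]), BadScorer())

    def test_binding_product_cardinality(self):
        rep = make_repertoire([0.5, 0.3, 0.2])
        cands = self.make_candidates(["A" * 9, "C" * 9])
        for c in cands:
            c.filtered_in = True
        pairs = neo.predict_binding(
            rep.clonotypes, cands, ["HLA-A*02:01", "HLA-B*27:05"],
            neo.HashBindingPredictor(seed=0),
        )
        assert len(pairs) == 12

    def test_empty_allele_list_is_input_error(self):
        rep = make_repertoire([1.0])
        with pytest.raises(InputError):
            neo.predict_binding(rep.clonotypes, [], [], neo.HashBindingPredictor(0))

    def test_planted_predictor_single_pair(self):
        rep = make_repertoire([0.5, 0.5])
        cands = self.make_candidates(["W" * 9])
        cands[0].filtered_in = True
        target = (rep.clonotypes[0].key, "W" * 9, "HLA-A*02:01")
        pairs = neo.predict_binding(
            rep.clonotypes, cands, ["HLA-A*02:01", "HLA-B*27:05"],
            neo.PlantedBindingPredictor([target]),
        )
        selected = [p for p in pairs if p.selected]
        assert len(selected) == 1
        assert neo.specific_clonotypes(pairs) == {rep.clonotypes[0].key}

    def test_binding_boundary_excluded(self):
        rep = make_repertoire([1.0])
        cands = self.make_candidates(["W" * 9])
        cands[0].filtered_in = True
        target = (rep.clonotypes[0].key, "W" * 9, "X")
        pairs = neo.predict_binding(
            rep.clonotypes, cands, ["X"],
            neo.PlantedBindingPredictor([target], hi=0.8),
        )
        assert not any(p.selected for p in pairs)


class TestSpecificFraction:
    def test_printed_pair(self):
        """789 specific of 8567 clonotypes reports as 9.21%."""
        assert round(100 * 789 / 8567, 2) == 9.21
        rep = make_repertoire([1 / 4] * 4)
        pairs = [
            neo.BindingPair(rep.clonotypes[0].key, "W" * 9, "X", 0.9, True),
            neo.BindingPair(rep.clonotypes[0].key, "C" * 9, "X", 0.9, True),
        ]
        assert neo.neoepitope_specific_fraction(4, pairs) == 25.0

    def test_no_selected_pairs(self):
        assert neo.neoepitope_specific_fraction(100, []) == 0.0
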