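"""Neoepitope prediction workflow: variant -> mutant protein -> k-mers ->
immunogenicity filter -> TR/peptide/MHC binding -> specific-clonotype
fraction.

Coding variants (HGVS ``c.`` substitutions, deletions, insertions) are
applied to a reference CDS and translated to the first stop codon.  For a
missense change, the 15-residue regions flanking each mutated position are
dissected into 9-15-mer peptides containing the mutation; for a frameshift
the entire altered amino-acid sequence downstream of the shift is
enumerated.  Candidates with immunogenicity score strictly above 0.9 are
filtered in; every (clonotype, filtered-in peptide, MHC allele) triple is
scored by a binding predictor, and pairs with binding strictly above 0.8
mark the clonotype as neoepitope-specific.

Immunogenicity scorers and binding predictors are pluggable: external
trained models can be wrapped behind the two small protocols below.  Two
deterministic implementations are bundled — a seeded hash-based
pseudo-scorer and a planted-table scorer for controlled experiments.
"""

from __future__ import annotations

import hashlib
import re
import warnings
from typing import Iterable, Mapping, Protocol, Sequence

from Bio.Seq import Seq

from .errors import ContractError, CoordinateError, InputError
from .models import (
    BindingPair,
    Clonotype,
    ClonotypeKey,
    CodingVariant,
    EpitopeCandidate,
    MutantProtein,
)

IMMUNOGENICITY_CUT = 0.9  # strict: p_imm > 0.9 is filtered in
BINDING_CUT = 0.8  # strict: b > 0.8 is selected
KMIN, KMAX, FLANK = 9, 15, 15

_HGVS_SUB = re.compile(r"^c\.(\d+)([ACGT])>([ACGT])$")
_HGVS_DEL = re.compile(r"^c\.(\d+)(?:_(\d+))?del([ACGT]*)$")
_HGVS_INS = re.compile(r"^c\.(\d+)_(\d+)ins([ACGT]+)$")


def parse_hgvs_c(gene: str, cds_ref: str, descriptor: str) -> CodingVariant:
    """Parse a simple HGVS 'c.' descriptor against a reference CDS.

    Supported: substitutions ``c.100C>T``, deletions ``c.4_5del`` /
    ``c.4del``, insertions ``c.10_11insACG``.
    """
    cds_ref = cds_ref.upper()
    desc = descriptor.strip()
    m = _HGVS_SUB.match(desc)
    if m:
        pos, ref, alt = int(m.group(1)), m.group(2), m.group(3)
        _check_range(cds_ref, pos, pos, desc)
        if cds_ref[pos - 1] != ref:
            raise CoordinateError(
                f"{desc}: reference base at c.{pos} is {cds_ref[pos-1]}, not {ref}"
            )
        return CodingVariant(
            gene=gene, cds_ref=cds_ref, hgvs_c=desc, kind="substitution",
            positions=(pos,), ref=ref, alt=alt,
        )
    m = _HGVS_DEL.match(desc)
    if m:
        start = int(m.group(1))
        end = int(m.group(2)) if m.group(2) else start
        _check_range(cds_ref, start, end, desc)
        deleted = cds_ref[start - 1 : end]
        if m.group(3) and m.group(3) != deleted:
            raise CoordinateError(
                f"{desc}: deleted bases are {deleted}, not {m.group(3)}"
            )
        return CodingVariant(
            gene=gene, cds_ref=cds_ref, hgvs_c=desc, kind="deletion",
            positions=tuple(range(start, end + 1)), ref=deleted,
        )
    m = _HGVS_INS.match(desc)
    if m:
        start, end, ins = int(m.group(1)), int(m.group(2)), m.group(3)
        if end != start + 1:
            raise CoordinateError(f"{desc}: insertion flanks must be adjacent")
        _check_range(cds_ref, start, start, desc)
        return CodingVariant(
            gene=gene, cds_ref=cds_ref, hgvs_c=desc, kind="insertion",
            positions=(start, end), alt=ins,
        )
    raise CoordinateError(f"unsupported HGVS descriptor: {descriptor!r}")


def _check_range(cds: str, start: int, end: int, desc: str) -> None:
    if not (1 <= start <= end <= len(cds)):
        raise CoordinateError(
            f"{desc}: positions {start}..{end} outside CDS of length {len(cds)}"
        )


def _mutant_cds(variant: CodingVariant) -> str:
    cds = variant.cds_ref
    if variant.kind == "substitution":
        pos = variant.positions[0]
        return cds[: pos - 1] + variant.alt + cds[pos:]
    if variant.kind == "deletion":
        start, end = variant.positions[0], variant.positions[-1]
        return cds[: start - 1] + cds[end:]
    if variant.kind == "insertion":
        start = variant.positions[0]
        return cds[:start] + variant.alt + cds[start:]
    raise InputError(f"unknown variant kind {variant.kind!r}")


def _translate(cds: str) -> str:
    # translate up to the first stop; a trailing partial codon is ignored
    trimmed = cds[: len(cds) - len(cds) % 3]
    return str(Seq(trimmed).translate(to_stop=True))


def apply_variant(variant: CodingVariant) -> MutantProtein:
    """Build the mutant CDS, translate to the first stop codon and locate
    the altered protein positions.

    An indel whose length is not a multiple of 3 is a frameshift: every
    position from the first divergent residue to the end of the mutant
    protein is altered.  A synonymous variant yields an empty altered set
    with a warning.
    """
    cds = variant.cds_ref
    if len(cds) % 3 != 0 or not cds.startswith("ATG"):
        raise CoordinateError(
            f"{variant.gene}: reference CDS must start with ATG and have "
            f"length divisible by 3"
        )
    ref_protein = _translate(cds)
    mut_protein = _translate(_mutant_cds(variant))

    indel_len = 0
    if variant.kind == "deletion":
        indel_len = len(variant.positions)
    elif variant.kind == "insertion":
        indel_len = len(variant.alt)
    frameshift = indel_len % 3 != 0

    # first residue where the proteins diverge (1-based)
    first_diff = None
    for i in range(min(len(ref_protein), len(mut_protein))):
        if ref_protein[i] != mut_protein[i]:
            first_diff = i + 1
            break
    if first_diff is None and len(ref_protein) != len(mut_protein):
        first_diff = min(len(ref_protein), len(mut_protein)) + 1

    if frameshift:
        # fall back to the codon of the first affected base when the shifted
        # frame happens to reproduce the reference residues up to the end
        start = first_diff or ((variant.positions[0] - 1) // 3 + 1)
        start = min(start, len(mut_protein) + 1)
        altered = set(range(start, len(mut_protein) + 1))
        return MutantProtein(
            gene=variant.gene, ref_protein=ref_protein, mut_protein=mut_protein,
            altered_positions=altered, frameshift=True,
            frameshift_start=start if altered else None,
        )

    altered = {
        i + 1
        for i in range(min(len(ref_protein), len(mut_protein)))
        if ref_protein[i] != mut_protein[i]
    }
    # in-frame length change: the novel/shifted tail counts as altered
    if len(mut_protein) > len(ref_protein):
        altered |= set(range(len(ref_protein) + 1, len(mut_protein) + 1))
    if not altered:
        warnings.warn(
            f"{variant.hgvs_c}: synonymous variant, protein unchanged",
            stacklevel=2,
        )
    return MutantProtein(
        gene=variant.gene, ref_protein=ref_protein, mut_protein=mut_protein,
        altered_positions=altered, frameshift=False, frameshift_start=None,
    )


def enumerate_kmers(
    mp: MutantProtein,
    kmin: int = KMIN,
    kmax: int = KMAX,
    flank: int = FLANK,
    include_junction: bool = False,
) -> list[EpitopeCandidate]:
    """Enumerate candidate neoepitope k-mers from a mutant protein.

    Non-frameshift: for each altered position, the window of ``flank``
    residues on both sides (clipped at the termini) is dissected into every
    k-mer, k in [kmin, kmax], that lies wholly inside the window and
    contains the altered position.  Frameshift: every k-mer of the altered
    suffix starting at the frameshift position; ``include_junction``
    additionally emits k-mers spanning the last wild-type residues and the
    shift point.  Identical peptides from overlapping windows are emitted
    once, keeping all source spans.
    """
    protein = mp.mut_protein
    L = len(protein)
    if L < kmin:
        warnings.warn(
            f"{mp.gene}: mutant protein shorter than {kmin} aa; no candidates",
            stacklevel=2,
        )
        return []

    spans: dict[str, list[tuple[int, int]]] = {}

    def emit(start: int, end: int) -> None:  # 1-based inclusive
        pep = protein[start - 1 : end]
        spans.setdefault(pep, []).append((start, end))

    if mp.frameshift and mp.frameshift_start is not None:
        fs = mp.frameshift_start
        for k in range(kmin, kmax + 1):
            lo = fs if not include_junction else max(1, fs - (k - 1))
            for start in range(lo, L - k + 2):
                if not include_junction and start < fs:
                    continue
                end = start + k - 1
                if include_junction and end < fs:
                    continue
                emit(start, end)
    else:
        for pos in sorted(mp.altered_positions):
            w_lo, w_hi = max(1, pos - flank), min(L, pos + flank)
            for k in range(kmin, kmax + 1):
                for start in range(w_lo, w_hi - k + 2):
                    end = start + k - 1
                    if start <= pos <= end:
                        emit(start, end)

    return [
        EpitopeCandidate(peptide=pep, source_spans=sp)
        for pep, sp in sorted(spans.items())
    ]


class ImmunogenicityScorer(Protocol):
    """Maps a peptide to an immunogenicity probability in [0, 1]."""

    name: str

    def __call__(self, peptide: str) -> float: ...


class BindingPredictor(Protocol):
    """Maps (cdr3_aa, v_gene, peptide, mhc_allele) to a binding score in
    [0, 1]."""

    name: str

    def __call__(
        self, cdr3_aa: str, v_gene: str, peptide: str, mhc_allele: str
    ) -> float: ...


def _hash_unit(seed: int, *parts: str) -> float:
    digest = hashlib.sha256(
        (f"{seed}|" + "|".join(parts)).encode()
    ).digest()
    return int.from_bytes(digest[:8], "big") / 2**64


class HashImmunogenicityScorer:
    """Deterministic pseudo-scorer: a seeded hash of the peptide mapped to
    [0, 1].  Reproducible stand-in where no trained model is configured."""

    def __init__(self, seed: int = 0):
        self.seed = seed
        self.name = f"hash-imm:seed={seed}"

    def __call__(self, peptide: str) -> float:
        return _hash_unit(self.seed, "imm", peptide)


class PlantedImmunogenicityScorer:
    """Scores a designated peptide set high and everything else low."""

    def __init__(self, immunogenic: Iterable[str], hi: float = 0.95, lo: float = 0.1):
        self.immunogenic = set(immunogenic)
        self.hi, self.lo = hi, lo
        self.name = f"planted-imm:n={len(self.immunogenic)}"

    def __call__(self, peptide: str) -> float:
        return self.hi if peptide in self.immunogenic else self.lo


class HashBindingPredictor:
    """Deterministic pseudo-predictor over (CDR3, V gene, peptide, allele)."""

    def __init__(self, seed: int = 0):
        self.seed = seed
        self.name = f"hash-bind:seed={seed}"

    def __call__(self, cdr3_aa: str, v_gene: str, peptide: str, mhc_allele: str) -> float:
        return _hash_unit(self.seed, "bind", cdr3_aa, v_gene, peptide, mhc_allele)


class PlantedBindingPredictor:
    """Scores designated ((v_gene, cdr3), peptide, allele) triples high."""

    def __init__(
        self,
        binders: Iterable[tuple[ClonotypeKey, str, str]],
        hi: float = 0.85,
        lo: float = 0.1,
    ):
        self.binders = set(binders)
        self.hi, self.lo = hi, lo
        self.name = f"planted-bind:n={len(self.binders)}"

    def __call__(self, cdr3_aa: str, v_gene: str, peptide: str, mhc_allele: str) -> float:
        return (
            self.hi
            if ((v_gene, cdr3_aa), peptide, mhc_allele) in self.binders
            else self.lo
        )


def score_immunogenicity(
    candidates: Sequence[EpitopeCandidate],
    scorer: ImmunogenicityScorer,
    cut: float = IMMUNOGENICITY_CUT,
) -> list[EpitopeCandidate]:
    """Score candidates and set ``filtered_in`` iff p_imm strictly exceeds
    the cut (0.9 by default, for stringency)."""
    out = []
    for c in candidates:
        p = float(scorer(c.peptide))
        if not (0.0 <= p <= 1.0):
            raise ContractError(
                f"scorer {getattr(scorer, 'name', scorer)!r} returned {p} "
                f"for {c.peptide!r}; expected [0, 1]"
            )
        out.append(
            EpitopeCandidate(
                peptide=c.peptide, source_spans=c.source_spans,
                p_imm=p, filtered_in=p > cut,
            )
        )
    return out


def predict_binding(
    clonotypes: Sequence[Clonotype],
    candidates: Sequence[EpitopeCandidate],
    mhc_alleles: Sequence[str],
    predictor: BindingPredictor,
    cut: float = BINDING_CUT,
    filtered_only: bool = True,
) -> list[BindingPair]:
    """Score the full clonotype x peptide x MHC-allele product.

    Only filtered-in candidates are used by default.  A pair is selected
    iff its binding score strictly exceeds the cut (0.8 by default).
    """
    if not mhc_alleles:
        raise InputError("MHC allele list is empty; binding is conditioned on MHC")
    peptides = [
        c.peptide for c in candidates if (c.filtered_in or not filtered_only)
    ]
    pairs: list[BindingPair] = []
    for clone in clonotypes:
        for pep in peptides:
            for allele in mhc_alleles:
                b = float(predictor(clone.cdr3_aa, clone.v_gene, pep, allele))
                if not (0.0 <= b <= 1.0):
                    raise ContractError(
                        f"predictor {getattr(predictor, 'name', predictor)!r} "
                        f"returned {b}; expected [0, 1]"
                    )
                pairs.append(
                    BindingPair(
                        clonotype_key=clone.key, peptide=pep,
                        mhc_allele=allele, b=b, selected=b > cut,
                    )
                )
    return pairs


def specific_clonotypes(pairs: Sequence[BindingPair]) -> set[ClonotypeKey]:
    """Clonotypes appearing in >= 1 selected binding pair."""
    return {p.clonotype_key for p in pairs if p.selected}


def neoepitope_specific_fraction(
    n_total_clonotypes: int, pairs: Sequence[BindingPair]
) -> float:
    """Percentage of the sample's clonotypes that are neoepitope-specific,
    rounded to 2 decimals (e.g. 789 of 8567 -> 9.21)."""
    if n_total_clonotypes <= 0:
        raise InputError("sample has no clonotypes")
    return round(100.0 * len(specific_clonotypes(pairs)) / n_total_clonotypes, 2)


def make_scorer(spec: str | Mapping) -> ImmunogenicityScorer:
    """Build a scorer from a spec string such as ``"stub:seed=7"``."""
    if isinstance(spec, str):
        kind, _, args = spec.partition(":")
        kwargs = dict(kv.split("=") for kv in args.split(",") if kv)
        if kind in ("stub", "hash"):
            return HashImmunogenicityScorer(seed=int(kwargs.get("seed", 0)))
        raise InputError(f"unknown scorer spec {spec!r}")
    raise InputError(f"unsupported scorer spec {spec!r}")


def make_predictor(spec: str | Mapping) -> BindingPredictor:
    """Build a binding predictor from a spec string such as ``"stub:seed=7"``."""
    if isinstance(spec, str):
        kind, _, args = spec.partition(":")
        kwargs = dict(kv.split("=") for kv in args.split(",") if kv)
        if kind in ("stub", "hash"):
            return HashBindingPredictor(seed=int(kwargs.get("seed", 0)))
        raise InputError(f"unknown predictor spec {spec!r}")
    raise InputError(f"unsupported predictor spec {spec!r}")
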