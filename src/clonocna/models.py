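"""Core domain types for TRB repertoire analysis.

A *clonotype* is the unique pair (TRBV gene, CDR3 amino-acid sequence)
within a sample; it is the unit of every downstream statistic.  The
dataclasses here are deliberately plain containers — all computation lives
in the per-stage modules.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

#: Clonotype identity within a sample: (v_gene without allele, CDR3 aa).
ClonotypeKey = tuple[str, str]

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class Rearrangement:
    """One annotated sequencing read of a TRBV-TRBD-TRBJ rearrangement."""

    sample_id: str
    sequence_id: str
    v_call: str
    j_call: str
    cdr3_aa: str
    productive: bool
    v_identity: float  # percent germline identity of the V segment, [0, 100]
    d_call: str = ""
    duplicate_count: int = 1


@dataclass(frozen=True)
class Clonotype:
    """A (TRBV gene, CDR3 aa) pair within one sample.

    ``frequency`` is the clonotype's read count over the sample's total
    filtered-in productive reads; ``rank`` 1 is the most abundant.
    """

    sample_id: str
    v_gene: str
    cdr3_aa: str
    read_count: int
    frequency: float
    rank: int

    @property
    def key(self) -> ClonotypeKey:
        return (self.v_gene, self.cdr3_aa)


@dataclass
class SampleRepertoire:
    """All clonotypes of one sample plus filtering bookkeeping."""

    sample_id: str
    clonotypes: list[Clonotype]
    group_label: Optional[str] = None
    n_reads_kept: int = 0
    n_reads_discarded: int = 0

    def frequencies(self) -> list[float]:
        return [c.frequency for c in self.clonotypes]

    def __len__(self) -> int:
        return len(self.clonotypes)


@dataclass
class ReferenceClonotypeDB:
    """A named set of reference clonotypes (V gene without allele, CDR3 aa)."""

    name: str
    entries: set[ClonotypeKey] = field(default_factory=set)

    def __contains__(self, key: ClonotypeKey) -> bool:
        return key in self.entries

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class ExpansionResult:
    """Outcome of the data-driven expanded-clonotype classification.

    ``per_sample_threshold`` maps sample id to the minimum frequency among
    that sample's clonotypes with z > z_cut (None when no clonotype
    qualifies); ``cohort_threshold`` is the median of the defined per-sample
    thresholds; ``expanded`` flags clonotypes with frequency >= threshold.
    """

    per_clonotype_z: dict[str, dict[ClonotypeKey, float]]
    per_sample_threshold: dict[str, Optional[float]]
    cohort_threshold: float
    expanded: dict[str, dict[ClonotypeKey, bool]]
    z_cut: float = 2.0

    def expanded_keys(self, sample_id: str) -> set[ClonotypeKey]:
        return {k for k, v in self.expanded[sample_id].items() if v}


@dataclass
class GroupSummary:
    """Per-group clonality summary: medians of CF-10 and CFEx, mean Hill-1."""

    group_label: str
    mcf10: float
    ex_mcf: float
    mean_hill1: float
    per_sample: list[tuple[str, float, float, float]]  # (sample, CF10, CFEx, 1D)


@dataclass
class SharedClonotype:
    """A clonotype observed in >= 2 samples of a cohort."""

    key: ClonotypeKey
    samples: set[str]
    groups: set[str]
    group_specific: bool
    db_hits: dict[str, bool] = field(default_factory=dict)
    biased: bool = True

    @property
    def public_across_groups(self) -> bool:
        return len(self.groups) >= 2


@dataclass(frozen=True)
class CodingVariant:
    """A coding variant in HGVS 'c.' style coordinates (1-based CDS)."""

    gene: str
    cds_ref: str
    hgvs_c: str
    kind: str  # "substitution" | "deletion" | "insertion"
    positions: tuple[int, ...]
    ref: str = ""
    alt: str = ""


@dataclass
class MutantProtein:
    """Reference and mutant protein with the altered residue positions."""

    gene: str
    ref_protein: str
    mut_protein: str
    altered_positions: set[int]
    frameshift: bool = False
    frameshift_start: Optional[int] = None


@dataclass
class EpitopeCandidate:
    """A mutant-derived k-mer peptide with its immunogenicity score."""

    peptide: str
    source_spans: list[tuple[int, int]]  # 1-based inclusive protein coords
    p_imm: Optional[float] = None
    filtered_in: bool = False

    @property
    def k(self) -> int:
        return len(self.peptide)


@dataclass(frozen=True)
class BindingPair:
    """A scored (clonotype, peptide, MHC allele) triple."""

    clonotype_key: ClonotypeKey
    peptide: str
    mhc_allele: str
    b: float
    selected: bool
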