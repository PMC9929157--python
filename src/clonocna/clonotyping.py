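"""Clonotype calling: read filters, grouping, frequencies and the major set.

Filters follow the study design: only productive rearrangements are kept,
reads whose V segment shows less than 95% germline identity are discarded
(sequencing-error guard; the boundary value 95.0 itself is kept), and
reads without a CDR3 cannot form a clonotype.  Clonotypes are unique
(allele-stripped TRBV gene, CDR3 aa) pairs per sample; the relative
frequency of a clonotype is its read count over the sample's total
filtered-in reads.  The ten highest-frequency clonotypes per sample are
the "major" clonotypes.
"""

from __future__ import annotations

from typing import Optional, Sequence

from .airr_io import normalize_v_gene
from .errors import InputError, StatisticError
from .models import Clonotype, Rearrangement, SampleRepertoire

#: Reads below this percent V germline identity are discarded.
MIN_V_IDENTITY = 95.0

REASON_NON_PRODUCTIVE = "non-productive"
REASON_LOW_V_IDENTITY = "v_identity<95"
REASON_EMPTY_CDR3 = "empty-cdr3"


def filter_rearrangements(
    rows: Sequence[Rearrangement],
    min_v_identity: float = MIN_V_IDENTITY,
) -> tuple[list[Rearrangement], list[tuple[Rearrangement, str]]]:
    """Partition reads into (kept, discarded-with-reason).

    A read is kept iff it is productive, has v_identity >= ``min_v_identity``
    and a non-empty CDR3.  Each discarded read is labelled with the first
    failing rule, in that order.
    """
    kept: list[Rearrangement] = []
    discarded: list[tuple[Rearrangement, str]] = []
    for row in rows:
        if not row.productive:
            discarded.append((row, REASON_NON_PRODUCTIVE))
        elif row.v_identity < min_v_identity:
            discarded.append((row, REASON_LOW_V_IDENTITY))
        elif not row.cdr3_aa:
            discarded.append((row, REASON_EMPTY_CDR3))
        else:
            kept.append(row)
    return kept, discarded


def _rank_key(item: tuple[tuple[str, str], int]):
    (v_gene, cdr3), count = item
    return (-count, cdr3, v_gene)


def call_clonotypes(
    kept: Sequence[Rearrangement],
    group_label: Optional[str] = None,
    n_reads_discarded: int = 0,
) -> SampleRepertoire:
    """Group filtered-in reads into clonotypes with frequencies and ranks.

    Grouping key is (allele-stripped V gene, CDR3 aa); read counts are
    duplicate_count-weighted.  Ranks are deterministic: read count
    descending, then CDR3 then V gene lexicographically.
    """
    if not kept:
        raise StatisticError("cannot call clonotypes from zero kept reads")
    sample_ids = {r.sample_id for r in kept}
    if len(sample_ids) > 1:
        raise InputError(f"mixed sample_ids in input: {sorted(sample_ids)}")
    sample_id = kept[0].sample_id

    counts: dict[tuple[str, str], int] = {}
    for row in kept:
        key = (normalize_v_gene(row.v_call), row.cdr3_aa)
        counts[key] = counts.get(key, 0) + row.duplicate_count

    total = sum(counts.values())
    clonotypes = [
        Clonotype(
            sample_id=sample_id,
            v_gene=v_gene,
            cdr3_aa=cdr3,
            read_count=count,
            frequency=count / total,
            rank=rank,
        )
        for rank, ((v_gene, cdr3), count) in enumerate(
            sorted(counts.items(), key=_rank_key), start=1
        )
    ]
    return SampleRepertoire(
        sample_id=sample_id,
        clonotypes=clonotypes,
        group_label=group_label,
        n_reads_kept=total,
        n_reads_discarded=n_reads_discarded,
    )


def build_repertoire(
    rows: Sequence[Rearrangement],
    group_label: Optional[str] = None,
    min_v_identity: float = MIN_V_IDENTITY,
) -> SampleRepertoire:
    """Filter reads and call clonotypes in one step."""
    kept, discarded = filter_rearrangements(rows, min_v_identity)
    n_discarded = sum(r.duplicate_count for r, _ in discarded)
    return call_clonotypes(kept, group_label=group_label, n_reads_discarded=n_discarded)


def major_clonotypes(rep: SampleRepertoire, n: int = 10) -> list[Clonotype]:
    """The top-``n`` clonotypes by rank (all of them when fewer exist)."""
    if n < 1:
        raise InputError(f"n must be >= 1, got {n}")
    ordered = sorted(rep.clonotypes, key=lambda c: c.rank)
    return ordered[:n]
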