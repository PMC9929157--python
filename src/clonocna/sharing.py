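"""Clonotype sharing across samples and reference-database comparison.

A clonotype (V gene + CDR3 aa, exact match) present in at least two
samples is *shared*; shared only within one genomic-aberration group it is
*group-specific*, across groups it is *public*.  A shared clonotype absent
from every external reference repertoire is flagged *biased* (observed
only in this disease context).  Because the published "public" tally mixes
the within-group and cross-group readings, :func:`summarize_sharing`
reports both.
"""

from __future__ import annotations

import logging
from typing import Sequence

from .models import ReferenceClonotypeDB, SampleRepertoire, SharedClonotype

logger = logging.getLogger(__name__)


def find_shared(cohort: Sequence[SampleRepertoire]) -> list[SharedClonotype]:
    """All clonotypes occurring in >= 2 distinct samples, with their sample
    and group sets; deterministic (key-sorted) order."""
    if len(cohort) < 2:
        return []
    samples_by_key: dict[tuple[str, str], set[str]] = {}
    groups_by_key: dict[tuple[str, str], set[str]] = {}
    for rep in cohort:
        group = rep.group_label or "ungrouped"
        for c in rep.clonotypes:
            samples_by_key.setdefault(c.key, set()).add(rep.sample_id)
            groups_by_key.setdefault(c.key, set()).add(group)
    shared = [
        SharedClonotype(
            key=key,
            samples=samples,
            groups=groups_by_key[key],
            group_specific=len(groups_by_key[key]) == 1,
        )
        for key, samples in samples_by_key.items()
        if len(samples) >= 2
    ]
    shared.sort(key=lambda s: s.key)
    return shared


def annotate_bias(
    shared: Sequence[SharedClonotype],
    dbs: Sequence[ReferenceClonotypeDB],
) -> list[SharedClonotype]:
    """Fill db_hits per reference database and the biased flag (no hit in
    any database).  An empty database list makes every clonotype vacuously
    biased; this is flagged with a warning."""
    if not dbs:
        logger.warning(
            "no reference databases given: all shared clonotypes "
            "are vacuously flagged as biased"
        )
    for s in shared:
        s.db_hits = {db.name: s.key in db for db in dbs}
        s.biased = not any(s.db_hits.values())
    return list(shared)


def summarize_sharing(shared: Sequence[SharedClonotype]) -> dict:
    """Tallies of the sharing structure.

    ``n_shared`` counts every clonotype in >= 2 samples;
    ``n_public_cross_group`` restricts to >= 2 groups;
    ``n_group_specific`` maps each group to its exclusively shared count;
    ``n_biased`` counts shared clonotypes absent from all databases.
    """
    per_group: dict[str, int] = {}
    for s in shared:
        if s.group_specific:
            group = next(iter(s.groups))
            per_group[group] = per_group.get(group, 0) + 1
    return {
        "n_shared": len(shared),
        "n_public_cross_group": sum(1 for s in shared if s.public_across_groups),
        "n_group_specific": per_group,
        "n_biased": sum(1 for s in shared if s.biased),
    }
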