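"""Data-driven classification of significantly expanded clonotypes.

The procedure avoids an arbitrary frequency cut-off: each sample's
clonotype frequency distribution is transformed to z-scores; clonotypes
with z > 2 are taken as clearly expanded, and the minimum frequency among
them becomes that sample's threshold.  The median of the defined
per-sample thresholds is the cohort-wide discerning frequency; any
clonotype at or above it is classified as significantly expanded.  The
cumulative frequency of a sample's expanded clonotypes is CFEx.

Two z-score scopes are available: ``per_sample`` (default — each sample's
own mean/sd, consistent with a per-sample threshold) and ``pooled``
(one z-transform over all samples' frequencies).
"""

from __future__ import annotations

import statistics
from typing import Optional, Sequence

import numpy as np

from .errors import StatisticError
from .models import ClonotypeKey, ExpansionResult, SampleRepertoire

DEFAULT_Z_CUT = 2.0

#: The cohort-level discerning frequency reported by the original study
#: (0.216%), usable as a fixed threshold instead of re-deriving one.
PUBLISHED_THRESHOLD = 0.00216


def zscores(
    sample: SampleRepertoire, ddof: int = 1
) -> dict[ClonotypeKey, float]:
    """z-score of every clonotype frequency within one sample.

    Uses the sample standard deviation (``ddof=1``) by default.  When the
    frequency distribution is degenerate (sd = 0) every z is NaN, which
    downstream selection treats as "no clonotype exceeds the cut".
    """
    freqs = np.asarray(sample.frequencies(), dtype=float)
    if freqs.size < 2:
        raise StatisticError(
            f"sample {sample.sample_id}: z-scores need >= 2 clonotypes"
        )
    sd = freqs.std(ddof=ddof)
    if sd == 0:
        z = np.full(freqs.shape, np.nan)
    else:
        z = (freqs - freqs.mean()) / sd
    return {c.key: float(zi) for c, zi in zip(sample.clonotypes, z)}


def per_sample_threshold(
    sample: SampleRepertoire,
    z_cut: float = DEFAULT_Z_CUT,
    ddof: int = 1,
    z: Optional[dict[ClonotypeKey, float]] = None,
) -> Optional[float]:
    """Minimum frequency among clonotypes with z strictly above ``z_cut``.

    Returns None when no clonotype qualifies.  Precomputed z-scores (e.g.
    from a pooled transform) may be passed in via ``z``.
    """
    if z is None:
        z = zscores(sample, ddof=ddof)
    selected = [c.frequency for c in sample.clonotypes if z[c.key] > z_cut]
    return min(selected) if selected else None


def cohort_threshold(thresholds: Sequence[Optional[float]]) -> float:
    """Median of the defined per-sample thresholds (midpoint for even
    counts); undefined thresholds contribute nothing."""
    defined = [t for t in thresholds if t is not None]
    if not defined:
        raise StatisticError("no sample has a defined expansion threshold")
    return statistics.median(defined)


def classify_expanded(
    sample: SampleRepertoire, tau: float
) -> dict[ClonotypeKey, bool]:
    """Expanded iff frequency >= tau (inclusive boundary)."""
    if not (0 < tau <= 1):
        raise StatisticError(f"threshold must be in (0, 1], got {tau}")
    return {c.key: c.frequency >= tau for c in sample.clonotypes}


def cfex(sample: SampleRepertoire, tau: float) -> float:
    """Cumulative frequency of the sample's significantly expanded
    clonotypes (CFEx)."""
    flags = classify_expanded(sample, tau)
    return sum(c.frequency for c in sample.clonotypes if flags[c.key])


def _pooled_zscores(
    samples: Sequence[SampleRepertoire], ddof: int = 1
) -> dict[str, dict[ClonotypeKey, float]]:
    all_freqs = np.concatenate([np.asarray(s.frequencies()) for s in samples])
    if all_freqs.size < 2:
        raise StatisticError("pooled z-scores need >= 2 clonotypes in total")
    mean, sd = all_freqs.mean(), all_freqs.std(ddof=ddof)
    out: dict[str, dict[ClonotypeKey, float]] = {}
    for s in samples:
        if sd == 0:
            out[s.sample_id] = {c.key: float("nan") for c in s.clonotypes}
        else:
            out[s.sample_id] = {
                c.key: float((c.frequency - mean) / sd) for c in s.clonotypes
            }
    return out


def analyze_cohort(
    samples: Sequence[SampleRepertoire],
    z_cut: float = DEFAULT_Z_CUT,
    ddof: int = 1,
    scope: str = "per_sample",
    fixed_threshold: Optional[float] = None,
) -> ExpansionResult:
    """Run the full expansion pipeline over a cohort.

    ``fixed_threshold`` bypasses the data-driven derivation (e.g. to apply
    the study's published 0.216% constant); z-scores and per-sample
    thresholds are still reported.
    """
    if scope not in ("per_sample", "pooled"):
        raise StatisticError(f"unknown z-score scope {scope!r}")
    if scope == "pooled":
        per_z = _pooled_zscores(samples, ddof=ddof)
    else:
        per_z = {s.sample_id: zscores(s, ddof=ddof) for s in samples}

    per_tau = {
        s.sample_id: per_sample_threshold(s, z_cut=z_cut, z=per_z[s.sample_id])
        for s in samples
    }
    tau = (
        fixed_threshold
        if fixed_threshold is not None
        else cohort_threshold(list(per_tau.values()))
    )
    expanded = {s.sample_id: classify_expanded(s, tau) for s in samples}
    return ExpansionResult(
        per_clonotype_z=per_z,
        per_sample_threshold=per_tau,
        cohort_threshold=tau,
        expanded=expanded,
        z_cut=z_cut,
    )
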