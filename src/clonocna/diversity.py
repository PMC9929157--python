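"""Hill-number diversity, clonality metrics, and group comparisons.

Diversity is summarised by Hill numbers ^qD — the effective number of
clonotypes at order q.  ^0D is clonotype richness; ^1D = exp(Shannon
entropy) weights each clonotype exactly by its proportional abundance.
The plug-in estimator is used; the ``hill_estimator`` argument of
:func:`mean_hill1` accepts any callable with the same signature so a
coverage-corrected estimator can be substituted.

Clonality is summarised by CF-10 (cumulative frequency of the top-10
"major" clonotypes of a sample), its per-group median MCF-10, CFEx
(cumulative frequency of the significantly expanded clonotypes) and its
per-group median ex-MCF.

Group comparisons use non-parametric Kruskal-Wallis / Mann-Whitney tests
(or one-way ANOVA for diversity), with Benjamini-Hochberg adjustment.
"""

from __future__ import annotations

import logging
import statistics
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .clonotyping import major_clonotypes
from .errors import StatisticError
from .expansion import cfex
from .models import GroupSummary, SampleRepertoire

logger = logging.getLogger(__name__)

NORMALIZATION_TOL = 1e-9


def hill_diversity(frequencies: Sequence[float], q: float = 1.0) -> float:
    """Hill number ^qD of a normalized frequency vector.

    q=0 is richness; q=1 is exp(Shannon entropy); otherwise
    (sum f_i^q)^(1/(1-q)).
    """
    f = np.asarray(frequencies, dtype=float)
    if f.size == 0:
        raise StatisticError("empty frequency vector")
    if np.any(f <= 0):
        raise StatisticError("frequencies must be strictly positive")
    if abs(f.sum() - 1.0) > 1e-6:
        raise StatisticError(f"frequencies sum to {f.sum():.6g}, expected 1")
    if q == 0:
        return float(f.size)
    if q == 1:
        return float(np.exp(-np.sum(f * np.log(f))))
    return float(np.sum(f**q) ** (1.0 / (1.0 - q)))


def cf_top(sample: SampleRepertoire, n: int = 10) -> float:
    """Cumulative frequency of the sample's top-``n`` (major) clonotypes;
    equals 1 when the sample has at most ``n`` clonotypes."""
    if not sample.clonotypes:
        raise StatisticError(f"sample {sample.sample_id} has no clonotypes")
    return sum(c.frequency for c in major_clonotypes(sample, n))


def group_summary(
    samples_by_group: Mapping[str, Sequence[SampleRepertoire]],
    tau: float,
    n_major: int = 10,
    hill_estimator: Callable[[Sequence[float], float], float] = hill_diversity,
) -> dict[str, GroupSummary]:
    """Per-group MCF-10, ex-MCF and mean ^1D with the per-sample values.

    Medians use the midpoint convention for even counts.  Empty groups are
    skipped with a warning.
    """
    out: dict[str, GroupSummary] = {}
    for group, samples in samples_by_group.items():
        if not samples:
            logger.warning("group %s has no samples; skipped", group)
            continue
        rows = []
        for s in samples:
            rows.append(
                (
                    s.sample_id,
                    cf_top(s, n_major),
                    cfex(s, tau),
                    hill_estimator(s.frequencies(), 1.0),
                )
            )
        out[group] = GroupSummary(
            group_label=group,
            mcf10=statistics.median(r[1] for r in rows),
            ex_mcf=statistics.median(r[2] for r in rows),
            mean_hill1=float(np.mean([r[3] for r in rows])),
            per_sample=rows,
        )
    return out


def compare_group_metric(
    values_by_group: Mapping[str, Sequence[float]],
    method: str = "kruskal",
) -> tuple[float, float]:
    """Compare a metric across groups; returns (statistic, p).

    ``method``: "kruskal" (>=2 groups), "mannwhitney" (exactly 2 groups,
    two-sided) or "anova".
    """
    groups = [np.asarray(v, dtype=float) for v in values_by_group.values()]
    if len(groups) < 2 or any(g.size == 0 for g in groups):
        raise StatisticError("need >= 2 non-empty groups")
    if method == "kruskal":
        res = stats.kruskal(*groups)
    elif method == "mannwhitney":
        if len(groups) != 2:
            raise StatisticError("mannwhitney compares exactly 2 groups")
        res = stats.mannwhitneyu(groups[0], groups[1], alternative="two-sided")
    elif method == "anova":
        if any(g.size < 2 for g in groups):
            raise StatisticError("anova needs >= 2 values per group")
        res = stats.f_oneway(*groups)
    else:
        raise StatisticError(f"unknown method {method!r}")
    return float(res.statistic), float(res.pvalue)


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values (q-values), clipped at 1,
    returned in the input order."""
    if len(p_values) == 0:
        return []
    _, q, _, _ = multipletests(list(p_values), method="fdr_bh")
    return [float(x) for x in q]
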