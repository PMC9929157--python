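"""TRBV gene usage at the clonotype level and differential usage.

Gene frequencies count clonotypes, not reads: the frequency of a TRBV
gene within a scope (all / major / expanded / background clonotypes of a
sample) is the number of clonotypes using it over the total number of
clonotypes in that scope.

Differential usage contrasts the expanded-clonotype repertoire with the
remaining polyclonal background across samples.  Each gene is tested with
a paired two-sided Wilcoxon signed-rank test on its per-sample (expanded,
background) frequency pair — a rank-based stand-in for a moderated linear
model — followed by Benjamini-Hochberg adjustment.  A gene observed in
fewer than two samples is reported as untestable rather than tested.  The
test backend is pluggable via ``test_fn``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .diversity import bh_adjust
from .errors import StatisticError
from .models import Clonotype

SCOPES = ("all", "major", "expanded", "background")


@dataclass
class GeneUsageTable:
    """Per-gene clonotype counts and frequencies within one scope."""

    scope: str
    rows: pd.DataFrame  # columns: v_gene, clonotype_count, frequency

    @property
    def frequencies(self) -> dict[str, float]:
        return dict(zip(self.rows["v_gene"], self.rows["frequency"]))


def trbv_frequencies(clonotypes: Sequence[Clonotype], scope: str = "all") -> GeneUsageTable:
    """Clonotype-level TRBV gene frequencies within a scope."""
    if scope not in SCOPES:
        raise StatisticError(f"unknown scope {scope!r}")
    if not clonotypes:
        raise StatisticError("empty clonotype scope")
    counts: dict[str, int] = {}
    for c in clonotypes:
        counts[c.v_gene] = counts.get(c.v_gene, 0) + 1
    total = len(clonotypes)
    rows = pd.DataFrame(
        sorted(
            ({"v_gene": g, "clonotype_count": n, "frequency": n / total}
             for g, n in counts.items()),
            key=lambda r: (-r["clonotype_count"], r["v_gene"]),
        )
    )
    return GeneUsageTable(scope=scope, rows=rows)


def _paired_wilcoxon(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided paired Wilcoxon signed-rank p; 1.0 when all pairs tie."""
    d = x - y
    if np.all(d == 0):
        return 1.0
    res = stats.wilcoxon(x, y, alternative="two-sided", zero_method="wilcox")
    return float(res.pvalue)


def differential_usage(
    expanded_by_sample: Mapping[str, GeneUsageTable],
    background_by_sample: Mapping[str, GeneUsageTable],
    test_fn: Optional[Callable[[np.ndarray, np.ndarray], float]] = None,
) -> pd.DataFrame:
    """Per-gene differential usage between expanded and background scopes.

    Samples must contribute both scopes; genes absent from a sample's scope
    get frequency 0.  Returns a DataFrame with columns
    v_gene, n_samples_observed, direction (+1 up in expanded, -1 down,
    0 no change), p, q, testable.
    """
    samples = sorted(set(expanded_by_sample) & set(background_by_sample))
    if len(samples) < 3:
        raise StatisticError(
            f"differential usage needs >= 3 samples with both scopes, got {len(samples)}"
        )
    test = test_fn or _paired_wilcoxon

    genes: set[str] = set()
    for s in samples:
        genes |= set(expanded_by_sample[s].frequencies)
        genes |= set(background_by_sample[s].frequencies)

    records = []
    for gene in sorted(genes):
        ex = np.array([expanded_by_sample[s].frequencies.get(gene, 0.0) for s in samples])
        bg = np.array([background_by_sample[s].frequencies.get(gene, 0.0) for s in samples])
        observed = int(np.sum((ex > 0) | (bg > 0)))
        testable = observed >= 2
        mean_diff = float(np.mean(ex - bg))
        direction = int(np.sign(mean_diff))
        p = test(ex, bg) if testable else float("nan")
        records.append(
            {
                "v_gene": gene,
                "n_samples_observed": observed,
                "direction": direction,
                "p": p,
                "testable": testable,
            }
        )
    df = pd.DataFrame(records)
    df["q"] = float("nan")
    testable_mask = df["testable"]
    if testable_mask.any():
        df.loc[testable_mask, "q"] = bh_adjust(df.loc[testable_mask, "p"].tolist())
    return df
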