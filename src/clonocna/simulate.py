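"""Synthetic AIRR cohorts and variant fixtures with known ground truth.

The generator emulates the statistical structure of a CLL TRB sequencing
cohort: per-sample repertoires of ~10,000 clonotypes drawn from a skewed
(oligoclonal) clone-size distribution, sampled to ~185,000 reads; planted
significantly-expanded clones at exact target frequencies; clonotypes
shared across samples (public) or within one aberration group
(group-specific); group-biased TRBV gene usage; and a small quota of
intentionally filter-failing reads (non-productive, low germline
identity).  Background clone sizes follow a symmetric Dirichlet whose
concentration controls skew — lower concentration gives the more
oligoclonal, lower-diversity repertoires typical of copy-number-aberration
groups.

Planted clonotypes carry a reserved CDR3 prefix that background generation
never produces, so recovery tests can compare against ground truth without
collision accounting.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .errors import ConfigError
from .models import ClonotypeKey

#: CDR3s of planted clonotypes start with this; background CDR3s never do.
PLANTED_PREFIX = "CPT"

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

#: Human TRBV genes used for background V calls, with convergent-usage
#: weights (TRBV12-3/29-1/19/5-1/6-5 dominate healthy and CLL repertoires).
DEFAULT_VGENES: dict[str, float] = {
    "TRBV12-3": 8.0, "TRBV29-1": 8.0, "TRBV19": 7.0, "TRBV5-1": 6.0,
    "TRBV6-5": 6.0, "TRBV20-1": 4.0, "TRBV28": 4.0, "TRBV27": 3.0,
    "TRBV7-9": 3.0, "TRBV9": 3.0, "TRBV2": 2.0, "TRBV3-1": 2.0,
    "TRBV4-1": 2.0, "TRBV6-1": 2.0, "TRBV7-2": 2.0, "TRBV10-3": 1.5,
    "TRBV11-2": 1.5, "TRBV11-3": 1.0, "TRBV6-9": 1.0, "TRBV25-1": 1.0,
    "TRBV30": 1.0, "TRBV7-4": 0.5, "TRBV13": 0.5, "TRBV15": 0.5,
}

AIRR_COLUMNS = [
    "sequence_id", "sample_id", "v_call", "d_call", "j_call",
    "junction_aa", "cdr3_aa", "productive", "v_identity", "duplicate_count",
]


@dataclass
class SharedPlan:
    """How many public (cross-group) and per-group-specific clonotypes to
    plant, each into ``copies`` samples."""

    n_public: int = 0
    per_group: dict[str, int] = field(default_factory=dict)
    copies: int = 2


@dataclass
class CohortConfig:
    """Study-conditions knobs for :func:`simulate_cohort`.

    Defaults mirror the scale of the real cohort: ~10,000 clonotypes and
    ~185,000 productive reads per sample.  ``expansion_plan`` gives the
    target frequencies of planted expanded clones, either one list applied
    to every sample or a per-sample mapping.  ``dirichlet_concentration``
    may be a single value or a per-group mapping (lower = more skewed,
    less diverse).
    """

    groups: Sequence[tuple[str, int]]
    clonotypes_per_sample: int = 10_000
    reads_per_sample: int = 185_000
    expansion_plan: Union[Sequence[float], Mapping[str, Sequence[float]]] = (
        0.05, 0.02, 0.01,
    )
    shared_plan: SharedPlan = field(default_factory=SharedPlan)
    vgene_bias: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    dirichlet_concentration: Union[float, Mapping[str, float]] = 0.25
    frac_nonproductive: float = 0.02
    frac_low_identity: float = 0.01
    cdr3_len_range: tuple[int, int] = (8, 20)
    seed: int = 0


@dataclass
class GroundTruth:
    """What was planted where, keyed the way the pipeline reports results."""

    planted_expanded: dict[str, list[ClonotypeKey]] = field(default_factory=dict)
    planted_expanded_freqs: dict[str, list[float]] = field(default_factory=dict)
    planted_public: dict[str, list[str]] = field(default_factory=dict)  # key-str -> samples
    planted_group_specific: dict[str, dict[str, list[str]]] = field(default_factory=dict)
    planted_immunogenic_peptides: list[str] = field(default_factory=list)
    planted_binding_triples: list[tuple] = field(default_factory=list)
    variant_truth: dict = field(default_factory=dict)

    def to_json(self) -> str:
        def _enc(obj):
            if isinstance(obj, tuple):
                return list(obj)
            raise TypeError(type(obj))

        return json.dumps(
            {
                "planted_expanded": {
                    s: [list(k) for k in keys]
                    for s, keys in self.planted_expanded.items()
                },
                "planted_expanded_freqs": self.planted_expanded_freqs,
                "planted_public": self.planted_public,
                "planted_group_specific": self.planted_group_specific,
                "planted_immunogenic_peptides": self.planted_immunogenic_peptides,
                "planted_binding_triples": [list(t) for t in self.planted_binding_triples],
                "variant_truth": self.variant_truth,
            },
            indent=2,
            default=_enc,
        )


def _random_cdr3(rng: np.random.Generator, lo: int, hi: int) -> str:
    length = int(rng.integers(lo, hi + 1))
    return "".join(AA_ALPHABET[i] for i in rng.integers(0, len(AA_ALPHABET), length))


def _background_cdr3(rng: np.random.Generator, lo: int, hi: int) -> str:
    while True:
        cdr3 = _random_cdr3(rng, lo, hi)
        if not cdr3.startswith(PLANTED_PREFIX):
            return cdr3


def _encode_int(n: int, width: int = 4) -> str:
    """Encode an integer in base 20 over the amino-acid alphabet so planted
    CDR3s remain valid amino-acid strings."""
    s = ""
    while n:
        s = AA_ALPHABET[n % 20] + s
        n //= 20
    return s.rjust(width, "A")


def _planted_cdr3(tag: str, index: int) -> str:
    return f"{PLANTED_PREFIX}{tag}{_encode_int(index)}"


def _group_value(mapping_or_value, group: str, default):
    if isinstance(mapping_or_value, Mapping):
        return mapping_or_value.get(group, default)
    return mapping_or_value


def simulate_cohort(
    config: CohortConfig,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame, GroundTruth]:
    """Generate AIRR rearrangement tables for a cohort.

    Returns (tables per sample, metadata sample->group, ground truth).
    Fully reproducible from ``config.seed``.  Planted expanded clones are
    realized at their exact target read counts; background counts are
    multinomial over Dirichlet clone sizes scaled to the residual mass.
    """
    rng = np.random.default_rng(config.seed)
    sample_groups: list[tuple[str, str]] = []
    for group, n in config.groups:
        if n < 1:
            raise ConfigError(f"group {group} has {n} samples")
        for i in range(1, n + 1):
            sample_groups.append((f"{group}_s{i:02d}", group))

    truth = GroundTruth()

    # --- assign planted shared clonotypes to samples -----------------------
    shared_assignment: dict[str, list[ClonotypeKey]] = {
        sid: [] for sid, _ in sample_groups
    }
    vgenes = list(DEFAULT_VGENES)
    plan = config.shared_plan
    by_group: dict[str, list[str]] = {}
    for sid, group in sample_groups:
        by_group.setdefault(group, []).append(sid)

    for i in range(plan.n_public):
        key = (vgenes[i % len(vgenes)], _planted_cdr3("P", i))
        # spread across >= 2 groups when possible
        groups = list(by_group)
        chosen: list[str] = []
        for g in groups[: max(2, min(plan.copies, len(groups)))]:
            chosen.append(by_group[g][i % len(by_group[g])])
        chosen = chosen[: max(2, plan.copies)]
        for sid in chosen:
            shared_assignment[sid].append(key)
        truth.planted_public["|".join(key)] = sorted(chosen)

    group_order = {g: gi for gi, g in enumerate(by_group)}
    for group, n_keys in plan.per_group.items():
        if group not in by_group:
            raise ConfigError(f"shared_plan references unknown group {group!r}")
        sids = by_group[group]
        if len(sids) < 2:
            raise ConfigError(f"group {group} needs >= 2 samples for sharing")
        truth.planted_group_specific[group] = {}
        for i in range(n_keys):
            key = (
                vgenes[(i + 7) % len(vgenes)],
                _planted_cdr3("G" + _encode_int(group_order[group], 2), i),
            )
            chosen = [sids[i % len(sids)], sids[(i + 1) % len(sids)]]
            chosen = sorted(set(chosen))[: plan.copies]
            for sid in chosen:
                shared_assignment[sid].append(key)
            truth.planted_group_specific[group]["|".join(key)] = sorted(chosen)

    # --- per-sample tables --------------------------------------------------
    tables: dict[str, pd.DataFrame] = {}
    lo, hi = config.cdr3_len_range
    for sample_index, (sid, group) in enumerate(sample_groups):
        if isinstance(config.expansion_plan, Mapping):
            planted_freqs = list(config.expansion_plan.get(sid, ()))
        else:
            planted_freqs = list(config.expansion_plan)
        if sum(planted_freqs) >= 1:
            raise ConfigError(f"{sid}: planted frequencies sum to >= 1")

        weights = dict(DEFAULT_VGENES)
        for gene, w in config.vgene_bias.get(group, {}).items():
            weights[gene] = w
        gene_names = list(weights)
        gene_p = np.array([weights[g] for g in gene_names], dtype=float)
        gene_p /= gene_p.sum()

        shared_keys = shared_assignment[sid]
        n_planted_exp = len(planted_freqs)
        n_background = (
            config.clonotypes_per_sample - n_planted_exp - len(shared_keys)
        )
        if n_background <= 0:
            raise ConfigError(f"{sid}: no room for background clonotypes")

        reads = config.reads_per_sample
        exp_counts = [max(1, round(f * reads)) for f in planted_freqs]
        shared_counts = [max(1, round(0.0001 * reads))] * len(shared_keys)
        residual = reads - sum(exp_counts) - sum(shared_counts)
        if residual <= 0:
            raise ConfigError(f"{sid}: planted mass leaves no residual reads")

        conc = float(_group_value(config.dirichlet_concentration, group, 0.25))
        bg_props = rng.dirichlet(np.full(n_background, conc))
        bg_counts = rng.multinomial(residual, bg_props)

        # planted expanded clonotypes
        rows: list[dict] = []
        exp_keys: list[ClonotypeKey] = []
        for i, (f_target, count) in enumerate(zip(planted_freqs, exp_counts)):
            gene = gene_names[int(rng.integers(0, len(gene_names)))]
            key = (gene, _planted_cdr3("E" + _encode_int(sample_index, 3), i))
            exp_keys.append(key)
            rows.append(
                {"v_call": key[0] + "*01", "cdr3_aa": key[1], "count": count}
            )
        truth.planted_expanded[sid] = exp_keys
        truth.planted_expanded_freqs[sid] = planted_freqs

        for key, count in zip(shared_keys, shared_counts):
            rows.append(
                {"v_call": key[0] + "*01", "cdr3_aa": key[1], "count": count}
            )

        # background clonotypes (unique CDR3s within the sample)
        seen: set[str] = {r["cdr3_aa"] for r in rows}
        bg_genes = rng.choice(len(gene_names), size=n_background, p=gene_p)
        for gi, count in zip(bg_genes, bg_counts):
            if count == 0:
                continue
            cdr3 = _background_cdr3(rng, lo, hi)
            while cdr3 in seen:
                cdr3 = _background_cdr3(rng, lo, hi)
            seen.add(cdr3)
            rows.append(
                {"v_call": gene_names[gi] + "*01", "cdr3_aa": cdr3, "count": int(count)}
            )

        records = []
        for i, r in enumerate(rows, start=1):
            records.append(
                {
                    "sequence_id": f"{sid}_r{i:06d}",
                    "sample_id": sid,
                    "v_call": r["v_call"],
                    "d_call": "TRBD1*01",
                    "j_call": "TRBJ2-1*01",
                    "junction_aa": "C" + r["cdr3_aa"] + "F",
                    "cdr3_aa": r["cdr3_aa"],
                    "productive": "T",
                    "v_identity": round(float(rng.uniform(96.0, 100.0)), 2),
                    "duplicate_count": int(r["count"]),
                }
            )

        # intentionally filter-failing rows to exercise the read filters
        n_np = round(config.frac_nonproductive * len(records))
        n_low = round(config.frac_low_identity * len(records))
        for j in range(n_np):
            cdr3 = _background_cdr3(rng, lo, hi) + "*"
            records.append(
                {
                    "sequence_id": f"{sid}_np{j:04d}",
                    "sample_id": sid,
                    "v_call": gene_names[int(rng.integers(0, len(gene_names)))] + "*01",
                    "d_call": "TRBD1*01",
                    "j_call": "TRBJ2-1*01",
                    "junction_aa": "C" + cdr3 + "F",
                    "cdr3_aa": cdr3,
                    "productive": "F",
                    "v_identity": round(float(rng.uniform(96.0, 100.0)), 2),
                    "duplicate_count": 1,
                }
            )
        for j in range(n_low):
            cdr3 = _background_cdr3(rng, lo, hi)
            records.append(
                {
                    "sequence_id": f"{sid}_lo{j:04d}",
                    "sample_id": sid,
                    "v_call": gene_names[int(rng.integers(0, len(gene_names)))] + "*01",
                    "d_call": "TRBD1*01",
                    "j_call": "TRBJ2-1*01",
                    "junction_aa": "C" + cdr3 + "F",
                    "cdr3_aa": cdr3,
                    "productive": "T",
                    "v_identity": round(float(rng.uniform(85.0, 94.9)), 2),
                    "duplicate_count": 1,
                }
            )
        tables[sid] = pd.DataFrame(records, columns=AIRR_COLUMNS)

    meta = pd.DataFrame(sample_groups, columns=["sample_id", "group"])
    return tables, meta, truth


STOP_CODONS = {"TAA", "TAG", "TGA"}
_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in STOP_CODONS and a + b + c != "ATG"
]

_CODON_TABLE: dict[str, str] = {}


def _codon_aa(codon: str) -> str:
    if not _CODON_TABLE:
        from Bio.Seq import Seq

        for c in [a + b + d for a in "ACGT" for b in "ACGT" for d in "ACGT"]:
            _CODON_TABLE[c] = str(Seq(c).translate())
    return _CODON_TABLE[codon]


def simulate_variants(
    n_missense: int,
    n_frameshift: int,
    protein_length: int = 60,
    seed: int = 0,
    gene_prefix: str = "GENE",
) -> tuple[dict[str, str], list[dict], dict]:
    """Random CDS fixtures with planted missense substitutions and 2-base
    frameshift deletions.

    Returns (fasta name->CDS, variant descriptor rows, ground truth with the
    expected altered protein positions).  Missense changes are
    non-synonymous and non-stop by construction; frameshift deletions avoid
    the start codon.
    """
    if protein_length < 31:
        raise ConfigError("protein_length must be >= 31")
    rng = np.random.default_rng(seed)
    fasta: dict[str, str] = {}
    variants: list[dict] = []
    truth: dict = {}

    def random_cds() -> str:
        codons = ["ATG"]
        codons += [_CODONS[int(i)] for i in rng.integers(0, len(_CODONS), protein_length - 1)]
        codons.append("TAA")
        return "".join(codons)

    for i in range(n_missense):
        gene = f"{gene_prefix}M{i+1}"
        cds = random_cds()
        # pick an interior codon and a substitution that changes the residue
        while True:
            codon_idx = int(rng.integers(1, protein_length))  # 0-based, skips ATG
            offset = int(rng.integers(0, 3))
            pos = codon_idx * 3 + offset + 1  # 1-based CDS
            ref = cds[pos - 1]
            alts = [b for b in "ACGT" if b != ref]
            rng.shuffle(alts)
            old_codon = cds[codon_idx * 3 : codon_idx * 3 + 3]
            chosen = None
            for alt in alts:
                new_codon = old_codon[:offset] + alt + old_codon[offset + 1 :]
                if new_codon not in STOP_CODONS and _codon_aa(new_codon) != _codon_aa(old_codon):
                    chosen = alt
                    break
            if chosen is not None:
                break
        fasta[gene] = cds
        variants.append({"gene": gene, "hgvs_c": f"c.{pos}{ref}>{chosen}"})
        truth[gene] = {
            "kind": "missense",
            "altered_positions": [codon_idx + 1],
            "frameshift": False,
        }

    from .neoepitopes import apply_variant, parse_hgvs_c

    for i in range(n_frameshift):
        gene = f"{gene_prefix}F{i+1}"
        # retry until the shifted frame yields an altered suffix long enough
        # to enumerate epitopes from (no immediate stop codon)
        while True:
            cds = random_cds()
            codon_idx = int(rng.integers(1, protein_length - 10))
            start = codon_idx * 3 + 1  # delete 2 bases at a codon boundary
            hgvs = f"c.{start}_{start+1}del"
            mp = apply_variant(parse_hgvs_c(gene, cds, hgvs))
            if (
                mp.frameshift_start is not None
                and len(mp.mut_protein) - mp.frameshift_start + 1 >= 9
            ):
                break
        fasta[gene] = cds
        variants.append({"gene": gene, "hgvs_c": hgvs})
        truth[gene] = {
            "kind": "frameshift",
            "frameshift": True,
            "frameshift_start": mp.frameshift_start,
            "altered_suffix_length": len(mp.mut_protein) - mp.frameshift_start + 1,
        }

    return fasta, variants, truth


def write_cohort(
    outdir: str | Path,
    tables: Mapping[str, pd.DataFrame],
    meta: pd.DataFrame,
    truth: Optional[GroundTruth] = None,
) -> None:
    """Write per-sample AIRR TSVs, meta.tsv and groundtruth.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for sid, df in tables.items():
        df.to_csv(outdir / f"{sid}.airr.tsv", sep="\t", index=False)
    meta.to_csv(outdir / "meta.tsv", sep="\t", index=False)
    if truth is not None:
        (outdir / "groundtruth.json").write_text(truth.to_json())
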