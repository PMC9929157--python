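"""End-to-end pipeline: ingest/simulate -> clonotypes -> expansion ->
diversity -> gene usage -> sharing -> neoepitopes -> report.

A single YAML config drives every stage; all analysis thresholds default
to the study's values (95% germline identity, z > 2, immunogenicity > 0.9,
binding > 0.8, top-10 major clonotypes) and are overridable.  Stage
outputs are written as TSV/JSON into the run directory together with a
manifest (config snapshot, seed, input digests, thresholds) so every
report row is traceable.  Given the same config and seed, reruns are
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path
from typing import Mapping, Optional

import pandas as pd
import yaml

from . import __version__
from . import airr_io, clonotyping, diversity, expansion, gene_usage, neoepitopes, sharing
from .errors import ConfigError, InputError
from .models import SampleRepertoire
from .simulate import CohortConfig, SharedPlan, simulate_cohort, write_cohort

logger = logging.getLogger(__name__)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    return cfg


def _cohort_config(block: Mapping, seed: int) -> CohortConfig:
    kwargs = dict(block)
    kwargs["groups"] = [tuple(g) for g in kwargs["groups"]]
    if "shared_plan" in kwargs and isinstance(kwargs["shared_plan"], Mapping):
        kwargs["shared_plan"] = SharedPlan(**kwargs["shared_plan"])
    if "expansion_plan" in kwargs and isinstance(kwargs["expansion_plan"], list):
        kwargs["expansion_plan"] = tuple(kwargs["expansion_plan"])
    kwargs.setdefault("seed", seed)
    return CohortConfig(**kwargs)


def build_repertoires(
    tables: Mapping[str, pd.DataFrame],
    groups: Mapping[str, str],
    min_v_identity: float = clonotyping.MIN_V_IDENTITY,
) -> dict[str, SampleRepertoire]:
    """Parse in-memory AIRR tables into filtered repertoires."""
    reps: dict[str, SampleRepertoire] = {}
    for sid, df in tables.items():
        parsed = airr_io.read_rearrangements_frame(
            df.astype(str), sample_id=sid, source=sid
        )
        reps[sid] = clonotyping.build_repertoire(
            parsed.records, group_label=groups.get(sid), min_v_identity=min_v_identity
        )
    return reps


def run_pipeline(config: dict | str | Path, outdir: str | Path) -> Path:
    """Run every configured stage; returns the report directory."""
    if not isinstance(config, dict):
        config = load_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    manifest: dict = {
        "clonocna_version": __version__,
        "seed": seed,
        "config": config,
        "inputs": {},
        "thresholds": {},
    }

    # --- stage: cohort acquisition -----------------------------------------
    if "simulate" in config:
        cc = _cohort_config(config["simulate"], seed)
        tables, meta, truth = simulate_cohort(cc)
        write_cohort(outdir / "cohort", tables, meta, truth)
        groups = dict(zip(meta["sample_id"], meta["group"]))
    elif "input" in config:
        indir = Path(config["input"]["rearrangements_dir"])
        meta_path = Path(config["input"]["meta"])
        meta = pd.read_csv(meta_path, sep="\t", dtype=str)
        groups = dict(zip(meta["sample_id"], meta["group"]))
        tables = {}
        for sid in groups:
            p = indir / f"{sid}.airr.tsv"
            if not p.exists():
                raise InputError(f"stage ingest: missing rearrangement file {p}")
            manifest["inputs"][str(p)] = _sha256(p)
            tables[sid] = pd.read_csv(p, sep="\t", dtype=str, keep_default_na=False)
        manifest["inputs"][str(meta_path)] = _sha256(meta_path)
    else:
        raise ConfigError("config needs a 'simulate' or 'input' block")

    # --- stage: clonotypes ---------------------------------------------------
    min_vid = float(config.get("filters", {}).get("min_v_identity", 95.0))
    manifest["thresholds"]["min_v_identity"] = min_vid
    reps = build_repertoires(tables, groups, min_v_identity=min_vid)
    clono_dir = outdir / "clonotypes"
    clono_dir.mkdir(exist_ok=True)
    for sid, rep in sorted(reps.items()):
        airr_io.write_clonotype_table(clono_dir / f"{sid}.tsv", rep.clonotypes)
        logger.info(
            "%s: %d reads kept, %d discarded, %d clonotypes",
            sid, rep.n_reads_kept, rep.n_reads_discarded, len(rep),
        )

    # --- stage: expansion ----------------------------------------------------
    exp_cfg = config.get("expansion", {})
    z_cut = float(exp_cfg.get("z_cut", 2.0))
    result = expansion.analyze_cohort(
        list(reps.values()),
        z_cut=z_cut,
        scope=exp_cfg.get("scope", "per_sample"),
        fixed_threshold=exp_cfg.get("fixed_threshold"),
    )
    manifest["thresholds"]["z_cut"] = z_cut
    manifest["thresholds"]["cohort_threshold"] = result.cohort_threshold
    exp_rows = []
    for sid, rep in sorted(reps.items()):
        for c in rep.clonotypes:
            exp_rows.append(
                {
                    "sample_id": sid, "v_gene": c.v_gene, "cdr3_aa": c.cdr3_aa,
                    "frequency": repr(c.frequency),
                    "z": repr(result.per_clonotype_z[sid][c.key]),
                    "expanded": result.expanded[sid][c.key],
                }
            )
    pd.DataFrame(exp_rows).to_csv(outdir / "expansion.tsv", sep="\t", index=False)
    (outdir / "expansion.json").write_text(
        json.dumps(
            {
                "cohort_threshold": result.cohort_threshold,
                "per_sample_threshold": result.per_sample_threshold,
                "z_cut": z_cut,
            },
            indent=2,
            sort_keys=True,
        )
    )

    # --- stage: diversity & clonality ---------------------------------------
    n_major = int(config.get("diversity", {}).get("n_major", 10))
    by_group: dict[str, list[SampleRepertoire]] = {}
    for rep in reps.values():
        by_group.setdefault(rep.group_label or "ungrouped", []).append(rep)
    summaries = diversity.group_summary(by_group, result.cohort_threshold, n_major)
    sum_rows, cmp_rows = [], []
    for g, s in sorted(summaries.items()):
        for sid, cf10, cfex_v, d1 in s.per_sample:
            sum_rows.append(
                {"group": g, "sample_id": sid, "cf10": cf10, "cfex": cfex_v, "hill1": d1}
            )
    pd.DataFrame(sum_rows).to_csv(outdir / "diversity_per_sample.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "group": g, "mcf10": s.mcf10, "ex_mcf": s.ex_mcf,
                "mean_hill1": s.mean_hill1, "n_samples": len(s.per_sample),
            }
            for g, s in sorted(summaries.items())
        ]
    ).to_csv(outdir / "group_summary.tsv", sep="\t", index=False)

    if len(summaries) >= 2:
        metric_values = {
            "cf10": {g: [r[1] for r in s.per_sample] for g, s in summaries.items()},
            "cfex": {g: [r[2] for r in s.per_sample] for g, s in summaries.items()},
            "hill1": {g: [r[3] for r in s.per_sample] for g, s in summaries.items()},
        }
        ps = []
        for metric, vals in metric_values.items():
            method = "anova" if metric == "hill1" else "kruskal"
            try:
                stat, p = diversity.compare_group_metric(vals, method)
            except Exception as exc:  # degenerate groups
                logger.warning("comparison %s failed: %s", metric, exc)
                continue
            cmp_rows.append({"metric": metric, "method": method, "statistic": stat, "p": p})
            ps.append(p)
        if cmp_rows:
            qs = diversity.bh_adjust(ps)
            for row, q in zip(cmp_rows, qs):
                row["q"] = q
            pd.DataFrame(cmp_rows).to_csv(
                outdir / "group_comparisons.tsv", sep="\t", index=False
            )

    # --- stage: gene usage ---------------------------------------------------
    usage_rows = []
    exp_tabs, bg_tabs = {}, {}
    for sid, rep in sorted(reps.items()):
        flags = result.expanded[sid]
        expanded_cl = [c for c in rep.clonotypes if flags[c.key]]
        background_cl = [c for c in rep.clonotypes if not flags[c.key]]
        for scope, cl in (("all", rep.clonotypes), ("expanded", expanded_cl),
                          ("background", background_cl)):
            if not cl:
                continue
            tab = gene_usage.trbv_frequencies(cl, scope)
            if scope == "expanded":
                exp_tabs[sid] = tab
            elif scope == "background":
                bg_tabs[sid] = tab
            for r in tab.rows.to_dict("records"):
                usage_rows.append({"sample_id": sid, "scope": scope, **r})
    pd.DataFrame(usage_rows).to_csv(outdir / "gene_usage.tsv", sep="\t", index=False)
    shared_sids = sorted(set(exp_tabs) & set(bg_tabs))
    if len(shared_sids) >= 3:
        diff = gene_usage.differential_usage(exp_tabs, bg_tabs)
        diff.to_csv(outdir / "differential_usage.tsv", sep="\t", index=False)

    # --- stage: sharing --------------------------------------------------------
    dbs = [
        airr_io.read_reference_db(p)
        for p in config.get("sharing", {}).get("dbs", [])
    ]
    shared = sharing.annotate_bias(sharing.find_shared(list(reps.values())), dbs)
    pd.DataFrame(
        [
            {
                "v_gene": s.key[0], "cdr3_aa": s.key[1],
                "n_samples": len(s.samples), "samples": ";".join(sorted(s.samples)),
                "n_groups": len(s.groups), "groups": ";".join(sorted(s.groups)),
                "group_specific": s.group_specific,
                "public_across_groups": s.public_across_groups,
                "biased": s.biased,
            }
            for s in shared
        ]
    ).to_csv(outdir / "shared_clonotypes.tsv", sep="\t", index=False)
    (outdir / "sharing_summary.json").write_text(
        json.dumps(sharing.summarize_sharing(shared), indent=2, sort_keys=True)
    )

    # --- stage: neoepitopes -----------------------------------------------------
    neo_cfg = config.get("neoepitopes", {})
    if neo_cfg.get("enabled"):
        for key in ("cds_fasta", "variants", "hla"):
            if key not in neo_cfg:
                raise ConfigError(f"stage neoepitopes: missing config key {key!r}")
            if not Path(neo_cfg[key]).exists():
                raise InputError(
                    f"stage neoepitopes: missing file {neo_cfg[key]} ({key})"
                )
        _run_neoepitope_stage(neo_cfg, reps, outdir, manifest)

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
    return outdir


def _run_neoepitope_stage(
    neo_cfg: Mapping,
    reps: Mapping[str, SampleRepertoire],
    outdir: Path,
    manifest: dict,
) -> None:
    fasta = airr_io.read_fasta(neo_cfg["cds_fasta"])
    variants_df = pd.read_csv(neo_cfg["variants"], sep="\t", dtype=str)
    alleles = airr_io.read_hla_list(neo_cfg["hla"])
    scorer = neoepitopes.make_scorer(neo_cfg.get("scorer", "stub:seed=0"))
    predictor = neoepitopes.make_predictor(neo_cfg.get("predictor", "stub:seed=0"))
    manifest["thresholds"]["immunogenicity_cut"] = neoepitopes.IMMUNOGENICITY_CUT
    manifest["thresholds"]["binding_cut"] = neoepitopes.BINDING_CUT

    candidates: list[neoepitopes.EpitopeCandidate] = []
    for row in variants_df.to_dict("records"):
        gene = row["gene"]
        if gene not in fasta:
            raise InputError(f"stage neoepitopes: gene {gene!r} not in CDS FASTA")
        variant = neoepitopes.parse_hgvs_c(gene, fasta[gene], row["hgvs_c"])
        mp = neoepitopes.apply_variant(variant)
        candidates.extend(neoepitopes.enumerate_kmers(mp))
    scored = neoepitopes.score_immunogenicity(candidates, scorer)
    neo_dir = outdir / "neoepitopes"
    neo_dir.mkdir(exist_ok=True)
    pd.DataFrame(
        [
            {
                "peptide": c.peptide, "k": c.k,
                "spans": ";".join(f"{a}-{b}" for a, b in c.source_spans),
                "p_imm": c.p_imm, "filtered_in": c.filtered_in,
            }
            for c in scored
        ]
    ).to_csv(neo_dir / "candidates.tsv", sep="\t", index=False)

    sample_ids = neo_cfg.get("samples") or sorted(reps)
    summary = []
    for sid in sample_ids:
        rep = reps[sid]
        pairs = neoepitopes.predict_binding(
            rep.clonotypes, scored, alleles, predictor
        )
        sel = [p for p in pairs if p.selected]
        pd.DataFrame(
            [
                {
                    "v_gene": p.clonotype_key[0], "cdr3_aa": p.clonotype_key[1],
                    "peptide": p.peptide, "mhc_allele": p.mhc_allele, "b": p.b,
                }
                for p in sel
            ]
        ).to_csv(neo_dir / f"{sid}.pairs.tsv", sep="\t", index=False)
        summary.append(
            {
                "sample_id": sid,
                "n_putative_neoepitopes": sum(c.filtered_in for c in scored),
                "n_specific_clonotypes": len(neoepitopes.specific_clonotypes(pairs)),
                "pct_specific_clonotypes": neoepitopes.neoepitope_specific_fraction(
                    len(rep), pairs
                ),
            }
        )
    pd.DataFrame(summary).to_csv(neo_dir / "summary.tsv", sep="\t", index=False)


def report_digests(outdir: str | Path) -> dict[str, str]:
    """sha256 of every report file, for determinism checks."""
    outdir = Path(outdir)
    return {
        str(p.relative_to(outdir)): _sha256(p)
        for p in sorted(outdir.rglob("*"))
        if p.is_file()
    }
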