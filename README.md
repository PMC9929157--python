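# clonocna

T-cell receptor beta-chain (TRB) repertoire analysis for cohorts of
patients stratified by genomic aberration — built for chronic lymphocytic
leukemia (CLL) groups such as del(11q), del(13q), del(17p), trisomy 12,
and *TP53*/*NOTCH1* mutations, but applicable to any grouped AIRR-seq TRB
cohort.

The package takes annotated AIRR-style rearrangement tables (one row per
sequencing read, with V/D/J calls, CDR3 amino-acid sequence, productivity
and V germline identity) and provides, as a library and a `clonocna` CLI:

- **Clonotype calling** — a clonotype is a unique (TRBV gene, CDR3 aa)
  pair within a sample. Only productive rearrangements with V germline
  identity ≥ 95% and a non-empty CDR3 are counted; the relative frequency
  *f* of a clonotype is its read count over the sample's filtered-in
  total, and the top-10 clonotypes are the "major" set.
- **Data-driven expansion threshold** — per sample, clonotype frequencies
  are transformed to z-scores `z_i = (f_i − mean f) / sd f`; the minimum
  frequency among clonotypes with z > 2 is that sample's threshold τ_s,
  and the cohort threshold τ is the median of the defined τ_s. A
  clonotype with f ≥ τ is *significantly expanded*.
- **Diversity and clonality** — Hill numbers `^qD` (with
  `^1D = exp(−Σ f_i ln f_i)`, the abundance-weighted effective clonotype
  number), CF-10 (cumulative frequency of the major clonotypes), CFEx
  (cumulative frequency of the expanded clonotypes), and their per-group
  medians MCF-10 and ex-MCF, compared across groups with
  Kruskal–Wallis / Mann–Whitney / ANOVA and Benjamini–Hochberg
  adjustment.
- **TRBV gene usage** — clonotype-level gene frequencies per scope
  (all / major / expanded / background) and rank-test differential usage
  of the expanded repertoire against the polyclonal background.
- **Clonotype sharing** — exact-match public (cross-group) and
  group-specific shared clonotypes, cross-compared against reference
  clonotype databases to flag disease-biased clonotypes.
- **Neoepitope workflow** — HGVS-style coding variants applied to a CDS
  and translated; 9–15-mer peptides enumerated from the ±15-aa window
  around each mutated position (or the whole altered suffix after a
  frameshift); candidates kept at immunogenicity > 0.9; every
  (clonotype, peptide, MHC allele) triple scored by a pluggable binding
  predictor, selected at score > 0.8; and the neoepitope-specific
  fraction of the repertoire reported. Trained external
  immunogenicity/binding models plug in behind two small interfaces;
  deterministic seeded stubs are bundled.
- **Synthetic cohorts** — a generator that emulates the statistical
  structure of such a study (oligoclonal Dirichlet clone sizes, planted
  expanded clones, planted sharing, group-biased V gene usage, planted
  variants) with full ground truth, so every stage is testable without
  patient data.

## Worked example

```python
from clonocna.simulate import CohortConfig, SharedPlan, simulate_cohort
from clonocna import pipeline, expansion, diversity, sharing

cfg = CohortConfig(
    groups=[("tri12", 4), ("TP53", 4)],
    clonotypes_per_sample=1000,
    reads_per_sample=20_000,
    expansion_plan=(0.05, 0.02, 0.01),          # planted expanded clones
    shared_plan=SharedPlan(n_public=3, per_group={"tri12": 2}),
    dirichlet_concentration={"tri12": 0.3, "TP53": 2.0},
    seed=7,
)
tables, meta, truth = simulate_cohort(cfg)
reps = pipeline.build_repertoires(tables, dict(zip(meta["sample_id"], meta["group"])))

res = expansion.analyze_cohort(list(reps.values()))
print(f"cohort threshold tau = {100*res.cohort_threshold:.3f}%")

by_group = {}
for r in reps.values():
    by_group.setdefault(r.group_label, []).append(r)
for g, s in diversity.group_summary(by_group, res.cohort_threshold).items():
    print(f"{g}: MCF-10 = {100*s.mcf10:.1f}%  ex-MCF = {100*s.ex_mcf:.1f}%  "
          f"mean 1D = {s.mean_hill1:.0f}")
print(sharing.summarize_sharing(sharing.find_shared(list(reps.values()))))
```

prints

```
cohort threshold tau = 0.863%
tri12: MCF-10 = 16.7%  ex-MCF = 19.1%  mean 1D = 305
TP53: MCF-10 = 10.5%  ex-MCF = 8.0%  mean 1D = 648
{'n_shared': 5, 'n_public_cross_group': 3, 'n_group_specific': {'tri12': 2}, 'n_biased': 5}
```

The threshold (0.863% of a sample's reads) is derived from the cohort
itself, not assumed. The copy-number-like `tri12` arm, generated with a
more skewed clone-size distribution, shows the higher clonality (MCF-10,
ex-MCF) and lower effective diversity (`^1D`) expected of oligoclonal
repertoires, and the planted public / group-specific sharing structure is
recovered exactly.

The same analysis runs from the shell:

```bash
clonocna simulate --groups tri12=4,TP53=4 --clonotypes 1000 --reads 20000 --seed 7 --out cohort/
clonocna run --config run.yaml --out report/
```

where `run.yaml` selects the stages and thresholds (all default to the
values above).

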