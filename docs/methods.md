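# Methods

## Clonotype model

A clonotype is the pair (TRBV gene without allele, CDR3 amino-acid
sequence) within one sample. Reads contribute to clonotypes only if they
are productive, carry a V segment at ≥ 95% germline identity, and have a
non-empty CDR3. The 95% cut is read literally as "< 95% discarded", so a
read at exactly 95.0% is kept. When only a junction amino-acid sequence
is available, the CDR3 is obtained by stripping one residue at each end
(the conserved cysteine and phenylalanine/tryptophan anchors). Ambiguous
V calls (comma-separated candidate lists) are resolved to the first
listed gene; allele suffixes (`*01`) are stripped before grouping,
because clonotypes are defined at the gene level.

Clonotype frequency is the duplicate-count-weighted read count divided by
the sample's filtered-in total. Ranks are deterministic: read count
descending, then CDR3 and V gene lexicographically — the tie-break makes
the top-10 ("major") set reproducible across runs and platforms.

## Expansion threshold

The "significantly expanded" classification avoids a fixed empirical
cut-off. Within each sample the clonotype frequency vector is
standardized, `z_i = (f_i − mean)/sd`, with the n−1 (sample) standard
deviation; a `ddof` switch selects the population denominator. Clonotypes
with z strictly greater than 2 define the sample threshold τ_s (their
minimum frequency); the cohort threshold τ is the median of the defined
τ_s (midpoint convention for even counts), and a clonotype is expanded
iff f ≥ τ (boundary inclusive). Degenerate samples (uniform frequencies,
sd = 0) define no τ_s and contribute nothing to the median.

The z-transform is applied per sample by default, because the procedure
then takes a *per-sample* minimum; a pooled transform over all samples'
frequencies is available via `scope="pooled"` for sensitivity analyses.
A `fixed_threshold` option applies an externally derived constant (for
example the 0.216% frequency published for the original 44-patient CLL
cohort) instead of re-deriving τ; re-deriving is the default, since τ is
a property of the cohort being analyzed.

## Diversity and clonality

Diversity is summarized by Hill numbers: `^0D` is clonotype richness and
`^1D = exp(−Σ f_i ln f_i)` weights every clonotype exactly by its
abundance. The estimator is the plug-in (maximum-likelihood) form; it
does not attempt to reconstruct unseen clonotypes from the clone-size
distribution, so `^1D` here is a lower bound on the true effective
number under heavy undersampling. The estimator is passed into the
group-summary machinery as a callable, so a coverage-corrected
(Recon/Chao-style) estimator can be substituted without touching callers.

Clonality metrics: CF-10 is the cumulative frequency of a sample's major
clonotypes (1 when a sample has ≤ 10 clonotypes), CFEx the cumulative
frequency of its significantly expanded clonotypes; MCF-10 and ex-MCF
are the per-group medians. Group contrasts use Kruskal–Wallis (≥ 2
groups), exact-where-possible two-sided Mann–Whitney (2 groups), or
one-way ANOVA for diversity; p-values are Benjamini–Hochberg adjusted.
α = 0.05 is a reporting convention only — nothing is filtered.

## TRBV gene usage

Gene frequencies count clonotypes, not reads: within a scope (all,
major, expanded, or background clonotypes) the frequency of a gene is
the number of clonotypes using it over the scope's clonotype count.
Differential usage between the expanded repertoire and the polyclonal
background is tested per gene with a paired two-sided Wilcoxon
signed-rank test on per-sample frequency pairs, BH-adjusted; a gene
absent from a sample's scope enters as an explicit 0 so absence is
signal. This is a deliberately simple rank-based stand-in for a
moderated linear model: with the small per-group sample sizes typical of
these cohorts, empirical-Bayes variance shrinkage adds machinery without
changing the rank-level conclusions, and the test backend is pluggable
(`test_fn`) for anyone who wants a different model. Genes observed in
fewer than two samples are reported as untestable rather than given a
p-value.

## Clonotype sharing

Sharing is exact string equality of the normalized clonotype key — no
Hamming/Levenshtein clustering — matching how shared clonotypes are
reported in the immunogenetics literature. A clonotype in ≥ 2 samples is
shared; within one group only, group-specific; across ≥ 2 groups,
public. Because published "public" tallies sometimes mix the two
readings, the summary reports both `n_shared` (≥ 2 samples, any groups)
and `n_public_cross_group` (≥ 2 groups). Shared clonotypes absent from
every supplied reference database are flagged "biased" (observed only in
this disease context); an empty database list makes the flag vacuous and
is warned about.

## Neoepitope workflow

Coding variants in HGVS `c.` notation (substitutions, deletions,
insertions; 1-based CDS coordinates) are applied to the reference CDS
and translated with the standard code to the first stop codon. Altered
protein positions are found by direct comparison; an indel of length not
divisible by 3 is a frameshift, and every residue from the first
divergent position to the mutant protein's end counts as altered.

For point changes, the window of 15 residues on each side of every
altered position (clipped at the termini, no padding) is dissected into
all k-mers, k ∈ [9, 15], that lie wholly inside the window and contain
the altered position; for frameshifts the entire altered suffix is
enumerated. K-mers are constrained to lie wholly inside the window
(peptides extending past it while still containing the mutation are not
emitted); likewise, frameshift enumeration uses only the altered suffix,
with junction-spanning k-mers available behind `include_junction`
(default off). Duplicate peptides from overlapping windows are emitted
once with all source spans kept.

Immunogenicity and TR–peptide–MHC binding are delegated to pluggable
scorer/predictor interfaces; candidates with immunogenicity strictly
above 0.9 are filtered in, and (clonotype, peptide, allele) pairs with
binding strictly above 0.8 are selected — both boundaries exclusive, for
stringency. A clonotype in at least one selected pair is
neoepitope-specific; the per-sample summary reports the count and the
percentage of all clonotypes (rounded to 2 decimals). Two bundled
implementations exist: a seeded SHA-256 hash scorer (deterministic,
approximately uniform on [0, 1] — useful for plumbing and determinism
checks, not biologically meaningful; note that with many peptide×allele
trials per clonotype the 0.2 selection tail will mark most clonotypes
specific) and a planted-table scorer for controlled recovery
experiments. An empty MHC allele list is an error, because binding is
conditioned on the sample's alleles.

## Synthetic cohort generator

The generator's defaults mirror the scale of a real grouped CLL cohort:
10,000 clonotypes and 185,000 productive reads per sample. Background
clone sizes are drawn from a symmetric Dirichlet over the non-planted
clonotypes and sampled multinomially; the concentration parameter
controls skew (default 0.25, giving oligoclonal repertoires; per-group
values let copy-number-like arms be generated more skewed — hence lower
`^1D` — than mutation-like arms). Planted expanded clones are realized
at their exact target read counts, planted shared clonotypes are
injected verbatim at background scale (0.01% of reads), and 2% of rows
are emitted non-productive plus 1% below the identity cut to exercise
the read filters. CDR3s are uniform random strings of length 8–20 over
the 20-letter alphabet; planted clonotypes use a reserved CDR3 prefix
(`CPT`) that background generation never produces, so recovery tests
compare against ground truth without collision accounting.

The generator emulates the *statistical* structure only: no V(D)J
recombination machinery, no nucleotide-level sequencing error, no
CDR3 length or amino-acid composition model, and no biological
convergence between samples beyond the planted sharing. Passing recovery
tests therefore demonstrates correctness of the analysis procedures
under the stated generative assumptions, not performance on real
repertoires with their unknown clone-size laws and annotation noise.

## Numerical and design choices

- Frequencies must sum to 1 within 1e-6 for diversity computations;
  clonotype tables serialize frequencies at full float precision so the
  write→read round-trip is exact.
- Medians use the midpoint convention throughout.
- `v_identity` given as a fraction in [0, 1] is auto-scaled to percent
  with a warning.
- `duplicate_count` defaults to 1 (one row = one read).
- The null-uniformity property tests for rank statistics use a
  Kolmogorov–Smirnov distance bound of 0.12–0.15, which allows for the
  lattice (discreteness) of exact rank-test p-values at small sample
  sizes on top of ordinary sampling error.
- Problem sizes in the test-suite and acceptance runs are scaled-down
  analogues of the real cohort (2 groups × 5 samples, 2,000 clonotypes
  and 40,000 reads per sample; 100 random small cohorts for oracle
  equivalence; 1,000 random proteins for enumeration equivalence) —
  large enough for every statistical behaviour checked, small enough to
  run comfortably on one CPU.

## Known limitations

- The plug-in `^1D` understates true diversity for deeply undersampled
  repertoires; published group means computed with reconstruction-based
  estimators are not directly comparable.
- The expansion threshold depends on the cohort composition; cohorts of
  uniformly polyclonal samples may define no threshold at all (this is
  surfaced as an error, not silently defaulted).
- Differential usage with < 5 samples per arm has little power; the
  Wilcoxon backend's p-values are discrete at such sizes.
- The neoepitope stage is a workflow harness: its biological validity is
  entirely determined by the scorer/predictor plugged in.
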