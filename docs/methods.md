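# Methods

## Coordinates and colocalization

An LDU genetic map is stored as ordered anchors (position bp, cumulative LDU)
per chromosome; positions strictly increase, cumulative LDU is non-decreasing.
Interpolation between anchors is **piecewise linear** — the simplest monotone
interpolant, and the one the map's usual graphical rendering implies. Flat
runs are LD "blocks", steep rises are "steps". Positions outside the anchored
extent raise an error rather than extrapolate: LD structure cannot be
extrapolated meaningfully.

`bp_window(center, δ)` inverts the map: the smallest position with
LDU ≥ LDU(center) − δ and the largest with LDU ≤ LDU(center) + δ, clamped to
the map ends. Within a block the window absorbs the whole block; across a
step it stops within a few bp — so windows are generally asymmetric about
their center. `kb_per_ldu_summary` evaluates ±1-LDU windows **at anchor
positions** (the only scale-free sampling choice; a fixed bp grid would
weight dense-anchor regions arbitrarily) and reports median/min/max width in
kb. Because the sampling scheme of the original genome-wide medians
(48 kb; 34–57 kb per chromosome) is not specified, ours is a stated
convention, not a reproduction.

Replicated disease loci are **single-linkage clusters** on the LDU axis:
sorted estimates chain whenever the gap to the previous cluster member is
≤ 1 LDU (the transitive closure of the stated pairwise rule — in one
dimension adjacent-gap chaining *is* single linkage). A cluster is a locus
when it spans ≥ 2 distinct cohorts; its representative is the most
significant member (least arbitrary choice; ties broken by position);
tier is "bonferroni" when any member clears 1×10⁻⁵ (≈ 0.05 / 5,000
independent genomic tests), otherwise "nominal" (< 1×10⁻³). Tiers are
annotations, not filters. A locus is cosmopolitan when any member comes from
an African-ancestry cohort; such estimates are compared on the European map
through their shared b37 position.

An expression estimate (p < 0.05) is a disease-eQTL when it lies within
1 LDU of **any** member estimate of a locus (each member carries its own
window; the strict all-members rule is available via
`ThresholdConfig(require_all_members=True)`). Cross-chromosome distance is
infinite. Cis-genes are genes whose annotated span, padded by ±1.5 Mb,
covers the locus representative position; a gene supported by several loci
is one call with the locus count recorded.

Symbol matching (NEMG flagging, set overlaps) is case-insensitive after
undoing spreadsheet date-mangling (`Mar-05` → *MARCH5*) and applying a small
alias table (e.g. *MARCHF5* → *MARCH5*); the packaged cis-NEMG table keeps
the mangled form exactly as curated upstream, so the normalizer is exercised
on real input.

## Differential expression

Probe-level input is assumed already normalized on a log2 (RMA-like) scale.
Per gene: one probe → OLS of expression on phenotype (plus available
age/BMI covariates), z = β̂/SE; several probes → linear mixed model on the
long (probe, sample) layout with fixed phenotype (+covariate) effects and
**crossed random intercepts for probe and for sample**, z = Wald statistic
of the phenotype coefficient. The shared fixed slope is deliberately
conservative: probes disagreeing in direction shrink the gene effect toward
zero. Probe-only grouping is a config option (`probe_random_only`), since
the appropriate grouping is not uniquely determined by the design. The
response is centred (and the subtraction's float dust rounded away at 1e-8)
before optimisation so the fit is invariant to constant offsets; REML with
L-BFGS, 200 iterations. On non-convergence the gene falls back to
probe-averaged OLS, flagged `fallback` in the output — the pipeline must be
total on messy data. Positive z always means higher expression in cases.
The family-history variant regresses on the number of affected parents
(0/1/2), probing genetic susceptibility without disease-onset confounding.

## Meta-analysis

Per-study z-scores are combined per tissue by DerSimonian–Laird with
within-study variance fixed at 1 (the effects *are* z-scale summaries;
no small-sample d-correction applies). τ² is truncated at zero; k = 1
returns the study z unchanged; with no heterogeneity the combined statistic
is Stouffer's mean·√k. Genes are combined over the **union** of studies in a
tissue with k recorded — platforms differ, and an intersection policy would
silently shrink coverage. The hand-rolled estimator is cross-checked in the
tests against `statsmodels.stats.meta_analysis.combine_effects(method_re="dl")`
(which stores the untruncated moment estimate — the only difference).

## GSEA

The observed statistic is the Wilcoxon rank-sum (midranks for ties) of the
set within the background, oriented by class: `down` ranks z, `up` ranks −z,
`mixed` ranks |z| (our stated reading of "mixed differential expression";
the original directional rule is not specified). The null is **competitive
gene sampling**: random same-size gene sets drawn without replacement from
the background; p = (1 + #extreme)/(n_perm + 1), never zero. The reported
direction class is the minimum-p of the three (all three p's are emitted);
BH-FDR is applied within each comparison family. A set equal to its whole
background has p = 1 by construction. The standard battery mirrors the
four-comparison design: cis-genes and cis-NEMGs vs the genomic background,
cis-NEMGs vs all NEMGs, and three random non-cis NEMG sets vs all NEMGs as
negative controls.

## Correlation-stratified NEMG regression

For each NEMG not called as a cis-gene: gene-level expression is the mean of
annotated probes over **control samples only** (both the correlations and
the mean-expression covariate use controls, keeping the substrate consistent
and free of case effects); its profile is the mean Pearson correlation with
the cis-NEMG group; the regression is z_meta ~ mean_r + mean_expr. The
robust variant emulates Stata's `rreg` sequence — drop Cook's distance > 1,
Huber IRLS (c = 1.345), then Tukey biweight (c = 4.685) started from the
Huber fit, weights converged to 1e-6 — with final weight < 0.01 reported as
an outlier. The outlier count is data-dependent and never asserted on
synthetic data. Zero-variance genes are excluded pairwise.

## Count enrichment

Observed statistic: |cis ∩ set| after symbol normalization. Random null:
uniform draws of |cis| genes (the count is hypergeometric; the tests verify
the empirical p against the closed-form tail). Structured null: reproduce
the observed **per-locus cis-gene count multiset** — for each locus size s,
a random anchor gene plus s−1 genes whose spans overlap the anchor's span
± 1.5 Mb (anchor-based, mirroring how cis-genes relate to one locus
position; chain-linked clusters would allow unbounded sprawl). Reproducing
the full multiset, not just the total, is the faithful-variance choice.
Structured sampling leaves the mean overlap at the random-null level but
inflates its variance for physically clustered pathways — exactly the
locus-clustered discovery effect it exists to absorb. p-values are
one-sided (enrichment only), add-one rule. `curate_mito_sets` keeps sets
with strictly more than 25% NEMG membership.

## Synthetic data

The generators emulate the study conditions at desk scale: 3 chromosomes ×
30 Mb, ~630 genes (7/Mb), maps from exponential blocks (mean 50 kb) and
steps (mean 0.8 LDU over 2 kb); 20 true loci with per-cohort jitter
σ = 0.2 LDU from three cohorts (two European, one African-American; 65% of
loci replicate in the AA cohort), 20 isolated single-cohort decoys ≥ 3 LDU
from any truth; 2 planted cis-genes per locus with eQTL within 0.8 LDU and
a planted case shift of −0.5 ± 0.15 log2 units; 25% of genes are NEMGs
sharing a per-sample factor with loadings U(0.2, 0.8) — the factor itself
shifts by −0.4 in cases, so a gene's induced case effect is proportional to
its loading (generalized mitochondrial down-regulation, and the planted
basis of the correlation-stratified regression); two case-control studies
per tissue (adipose, muscle, liver, pancreas) at n = 30 plus a
family-history muscle study (10/15/10 individuals with 0/1/2 affected
parents, dosage effect half the case effect); 1–3 probes per gene with
offset and noise SD 0.3; age/BMI covariates mildly confounded with case
status; 12 pathway sets of 30 genes, 3 enriched 4-fold for cis-genes.

The NEMG fraction and per-locus cis-gene count are higher than genomic
reality so that desk-scale runs retain power for every stage. The generator
does **not** emulate LD-map estimation noise, probe cross-hybridisation,
batch effects, or heavy-tailed expression — passing tests show the
machinery is correct and calibrated under the planted model, not that real
data would yield the discovery-scale counts. All randomness flows from one
seed through named `SeedSequence` spawns; bundles are byte-identical per
seed, written to a temporary directory and atomically renamed so a partial
write never leaves a manifest.

## Numerical and reporting choices

Empirical p-values always use the add-one rule. GSEA permutation defaults to
10,000 draws; the determinism test and the acceptance script run the
pipeline at 1,000–2,000 draws, which leaves permutation standard errors of
0.5–1 percentage points — ample for the planted effects they measure. The
discovery-scale counts (763 cis-genes, 167 supported loci, 50 cis-NEMGs,
21,215 annotated background genes with 1,155 NEMGs) are packaged **inputs**
to the summary arithmetic and Fisher test; the package recomputes the
derived quantities (4.6 genes/locus, 6.6% vs 5.4%, Fisher p ≈ 0.2) but does
not re-estimate the counts, which would require the original genotype and
expression cohorts. Likewise the printed regression p = 2.5E-08 of the
correlation-stratified analysis depends on the original data; the tests
assert the recoverable properties instead (negative slope on planted
dependence, robustness to gross outliers).

## Known limitations

- The mixed model's crossed random intercepts can fail to converge on very
  small studies; the flagged OLS fallback changes the gene's z slightly.
- Single-linkage clustering can, in principle, chain distinct signals
  through intermediate estimates; the replicated-locus count is therefore a
  lower bound on signal multiplicity.
- The structured null's anchor re-draw (100 retries) biases cluster
  placement toward gene-dense regions when the annotation is very sparse
  relative to the window.
- `kb_per_ldu_summary` medians depend on the anchor-sampling convention
  (above) and are not comparable across maps with different anchor density.
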