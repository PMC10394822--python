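# Methods

This note documents the models and procedures the package implements, the
parameters that matter, what the synthetic data generator does and does not
emulate, and the numerical choices made where the design was open.

## CIMP scoring

**Signature selection.** Candidate probes are promoter probes
(`tss_relation` in the configured categories, default `{TSS200}`). A probe
enters the signature iff (a) its β-values differ across the lCIMP/iCIMP/hCIMP
groups by a Kruskal–Wallis test, Benjamini–Hochberg-corrected at α = 0.05
across all tested probes, and (b) group mean β rises by more than 0.2 from
lCIMP to iCIMP **and** from iCIMP to hCIMP. The monotone-increasing
requirement encodes the definition of a methylator phenotype
(hypermethylation); probes with equally large decreasing gradients are
excluded. The across-group test is a parameter (`test="anova"` swaps in
one-way ANOVA): a rank-based default was chosen to match the nonparametric
style of the rest of the pipeline, and whether the original array analyses
corrected the probe test is not knowable from outside, so both the
correction (always applied here) and the delta statistic (means of available
samples) are explicit parameters. Probes missing in more than 20% of samples
are dropped before testing.

**Score.** The CIMP score of a sample is the plain sum of β over signature
probes — deliberately unnormalized, so it ranges in [0, |signature|]. Samples
missing more than `max_missing` (default 10%) of signature probes get a
missing score rather than a silently shrunken one.

## Causal modelling

All partial correlations are residual-based: each variable is regressed on
the controls with an intercept by least squares, and the Pearson correlation
of the residuals is taken; the p-value uses the t distribution with
n − 2 − #controls degrees of freedom. Missing data are removed pairwise for
marginal correlations and listwise across all variables for partial
correlations, keeping degrees of freedom well defined.

`mediation_report` computes the three quantities in the README and issues a
verdict with thresholds (α = 0.05, minimum direct partial r = 0.2, maximum
residual |r| = 0.15 — all configurable): *mediation_consistent* when the
marginal association holds, every DNMT keeps a significant positive partial
association with CIMP given proliferation, and the proliferation–CIMP
partial correlation given the DNMTs is both non-significant and small;
*common_cause_consistent* when the marginal association holds but no DNMT
survives conditioning on proliferation; *no_association* when even the
marginal association is absent; *inconclusive* otherwise. The verdict is a
pure function of the stored statistics (`derive_verdict` recomputes it),
so reports are auditable. Note that the residual-|r| bound is an absolute
threshold: at n = 80 the null sampling spread of a partial correlation is
≈ 0.11, so even under perfect mediation roughly a fifth of cohorts land in
*inconclusive* — the verdict rule favors specificity over sensitivity.

**Purity adjustment.** Bulk methylation dilutes with stromal content, so the
CIMP score is residualized on tumor purity (linear regression with
intercept) before the partial-correlation analysis. Constant purity cannot
be adjusted for; the centered score is returned with a warning.

**Composite scores.** The stemness score is the mean log2 expression of a
six-gene marker panel (POU5F1, SOX2, KLF4, MYC, NANOG, SALL4; common aliases
are mapped). The module-activity score is the first principal component of
the gene-wise z-scored log2 submatrix of a gene module, sign-oriented to
correlate positively with the module's mean expression. This is a
deliberate simplification of module-activity tools that additionally test
overdispersion against randomized gene sets: only the activity score itself
is consumed downstream, and on synthetic cohorts it recovers the latent
proliferation drive with r > 0.95 from a 20-gene module.

## Enrichment

Genes are ranked by the signal-to-noise ratio
(μ_a − μ_b)/(σ_a + σ_b), each group's standard deviation floored at
max(σ, 0.2·|μ|, 1e−8) — the classical convention; the floor fraction is a
parameter since the convention is not universal. Ties are broken by gene
identifier so rankings are platform-independent; because a running sum can
peak at exactly opposite deviations (±k/(N−k) patterns), peak selection
treats deviations within 1e−12 as tied and takes the earliest rank.

The enrichment score is the classic weighted running sum: increments of
|s|^p (p = 1 by default) normalized over in-set genes, decrements of
1/(N − |set|); the ES is the signed maximum deviation and the leading edge
is the in-set prefix (positive ES) or suffix (negative ES) at the peak.
Significance uses phenotype-label permutations when both groups have at
least 7 samples and gene-set permutations otherwise (override with
`permutation_type`). NES divides the ES by the mean of same-sign null ES;
the nominal p is the same-sign null tail; FDR q follows the pooled
positive/negative null-NES procedure, clipped to [0, 1] and made monotone
by a running minimum from the least extreme set toward the most extreme.
A set whose null distribution contains no same-sign ES is flagged
`inconclusive` rather than divided by zero.

Unranked over-representation uses the one-sided hypergeometric tail within a
caller-supplied universe, BH-corrected across sets.

## Immune deconvolution

Population abundance is the arithmetic mean of log2(x + 1) marker expression
— a relative score, comparable across samples within a population, never
across populations. Marker sets are a user input (a small illustrative
human marker collection ships for tests and demonstrations). Group
comparison is Kruskal–Wallis per population followed by Dunn's pairwise
z-tests on pooled ranks with tie-corrected variance,
z = (R̄_i − R̄_j) / √((N(N+1)/12 − Σ(t³−t)/(12(N−1)))(1/n_i + 1/n_j)),
with BH correction across the pairwise family *within* each population
(matching per-population figure annotation; a global family is a
configuration away).

## Methylation–expression integration

Genomic coordinates are 0-based half-open everywhere, including the DMR TSV
on disk; overlap means any shared base. Promoter windows are strand-aware:
[tss − 1000, tss + 200) on the plus strand, mirrored on the minus strand,
clipped at the chromosome origin with a warning.

**Reactivated genes** (demethylation experiment): called iff ≥ 1 DMR
overlaps the promoter with p < 0.05 and demethylation delta > 0.2 (the
table stores control − treated β, so demethylation under treatment is
positive; `invert_delta` accommodates the opposite convention), and the DE
record shows p < 0.05 with fold change > 2 upward (log2 fold change > 1,
evaluated on the linear scale).

**Repressed genes** (tumor cohort): called iff the gene's expression
correlates negatively with the continuous CIMP score (Spearman, BH at 0.05)
and ≥ 1 promoter or gene-body probe is hypermethylated in hCIMP versus
lCIMP (two-sided Wilcoxon rank-sum p < 0.05 and mean Δβ > 0.1). Both the
correlation test and the differential-methylation rule are documented
interpretations — the original tumor-side criteria are underspecified in
public descriptions of such pipelines — and every threshold is a parameter.
The hypermethylation direction is required for body probes as well as
promoter probes; this symmetric choice is the simplest defensible default.
Tightening any threshold can only shrink the call set (property-tested).

## Survival

Kaplan–Meier estimation and the k-group log-rank test delegate to lifelines
behind typed wrappers; tests verify them against hand-computed product-limit
values and a direct observed-minus-expected tabulation. Stratification by a
gene's expression uses equal-size rank strata (default tertiles) with ties
broken deterministically by sample id; constant expression is a degenerate
input, not a silent single stratum. The Bonferroni family is the set of
genes examined in one session (`n_genes_tested`), matching the practice of
adjusting across the genes shown in a figure.

## The synthetic cohort generator

`simulate_cohort` draws, per sample: latent proliferation P ~ N(0, 1);
per-locus copy-number gain/loss (P(gain) = 0.3, P(loss) = 0.05); DNMT
expression D_k = 1.0·gain_k + 1.0·P + ε (σ = 0.5) on the log2 scale; CIMP
latent C = 0.7·D₁ + 0.7·D₂ + δ·P + ε (σ = 0.5) with δ = 0 by default —
setting the DNMT→CIMP coefficients to zero and δ > 0 produces the
common-cause structure D ← P → C. Group labels are tertiles of C.
Signature-probe β-values are inverse-logit(a + 2.2·C_std + ε) with probe
intercepts a ~ U(−0.4, 0.4) and logit noise σ = 0.25, then diluted by tumor
purity (Beta(27, 3), mean 0.9) against an unmethylated (β = 0.05) normal
background; non-signature probes are C-independent Beta draws around
probe-level means m ~ U(0.05, 0.95) with concentration 30. Immune marker
genes lose 0.8 log2 units per SD of C; fibroblast and endothelial markers do
not respond; 20 proliferation marker genes gain 0.8 log2 units per SD of P;
DNMT1/DNMT3A expression tracks the latent D_k. Survival is exponential with
log-hazard 0.9 per SD of mean DNMT expression over a baseline hazard of
10⁻³/day, censored by an independent uniform time calibrated to ≈ 30%
censoring. Mitotic rate is Poisson with log-mean linear in P.

The coefficient defaults were calibrated by simulation so that the
qualitative findings the pipeline targets — signature recovery, mediation
discrimination, immune depletion, survival separation — are recoverable at
the default cohort size of n = 80, since published analyses report
correlations, not generative parameters. The survival coefficient in
particular corresponds to a hazard ratio ≈ 5 across extreme expression
tertiles; weaker settings (HR ≈ 3) leave the three-group log-rank
underpowered at n = 80.

What the generator does **not** emulate: batch and platform effects, probe
cross-reactivity and array chemistry, spatially correlated methylation,
realistic linkage between copy-number segments, non-exponential survival,
informative censoring, and cell-line-specific methylation levels. Passing
recovery tests on this generator therefore demonstrates that the
*procedures* are correct and adequately powered under the assumed causal
structure — not that the structure holds in any real cohort.

`simulate_demethylation_experiment` builds planted-truth DMR/DE tables:
planted genes sit strictly inside both filter arms, and six decoy classes
each violate exactly one criterion (weak delta, weak DMR p, DMR outside the
promoter, weak fold change, weak DE p, fully null), so integration calls can
be compared to ground truth exactly.

## Problem sizes and runtime

Recovery checks in the test suite and `scripts/acceptance.py` use the
cohort sizes the procedures are designed for: n = 80 samples, 2000 probes
with 50 planted signature probes, 500 genes; seed sweeps of 10–100 cohorts
per property; 1000 permutations for enrichment. Layers irrelevant to a
given check (e.g. the probe layer in survival sweeps) are thinned to keep
simulation time proportionate. The full suite runs in about a minute on one
CPU; the acceptance script in under a minute.

## Known limitations

* One TSS per gene id; transcript-level promoter multiplicity is out of scope.
* The mediation verdict's fixed residual-|r| bound makes its sensitivity
  depend on cohort size (see above).
* Dunn's test uses the large-sample normal approximation; very small groups
  (< 5) give conservative p-values.
* `module_activity_score` reflects the dominant covariance axis of the
  module; modules mixing up- and down-regulated programs need splitting
  before scoring.
* The GSEA FDR is the permutation-pool estimate, which can be 0 when no
  null NES exceeds the observed; it is not a BH-adjusted p-value.
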