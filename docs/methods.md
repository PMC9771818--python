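# Methods

This note documents the statistical models implemented in `transmeta`, the
choices made where the design was genuinely open, and what the synthetic
data used for validation does and does not emulate.

## Setting

The package analyses cohort-level GWAS summary statistics contributed by K
studies of diverse genetic ancestry.  Each study k reports, per variant j,
an effect estimate b_jk on the alternate allele, its standard error s_jk, a
Z statistic, the allele frequency p_jk and the imputation quality R²_jk.
No individual-level data are required except for an external genotype
reference panel used to estimate linkage disequilibrium (LD).

## Quality control and harmonisation

Study-level filters: studies with N < 100 are removed, as are studies whose
genomic-control value lies outside [0.9, 1.1] unless N ≥ 10,000 (large
studies are expected to show polygenic inflation).  Variant records with
imputation quality below 0.3 are dropped.  Meta-analysis inclusion requires
presence in ≥ 3 studies, an effective-sample-size (Σ N_k·R²_jk) to maximum
ratio ≥ 0.1, and MAF above 0.001 (multi-ancestry and EUR-stratified
analyses) or 0.01 (AFR/AMR/EAS-stratified).

Alleles are aligned across cohorts on (chromosome, position), using the
first reporting study's ref/alt orientation; a swapped pair flips the signs
of b and Z and maps p → 1−p.  Strand-ambiguous (A/T, C/G) variants cannot
be disambiguated without a strand column, so they are kept only when the
aligned frequency agrees with the reference study within 0.2; all other
allele pairs are dropped as mismatches.  Positions are 1-based and
chromosome names are normalised by stripping a leading "chr".

Genomic control is applied only to low-frequency variants (MAF < 1%):
λ = median(χ²)/0.4549 over those variants, and their statistics are divided
by max(λ, 1).  Common variants are left untouched, because λ inflation at
very large sample sizes reflects polygenicity rather than stratification,
and λ < 1 never inflates statistics.

## Ancestry components

The genetic distance between studies k and k′ is the Euclidean distance
between their allele-frequency vectors, d_kk′ = sqrt(Σ_j (f_jk − f_jk′)²).
Classical (Torgerson) multidimensional scaling of this matrix — double
centring −½·J·D∘²·J, top-L eigenvectors scaled by √eigenvalue — yields up
to four ancestry axes C_1..C_4.  Open choices resolved here:

* **Variant set.** Distances use variants common (MAF > 0.05) in all
  studies where observed, so the embedding reflects genome-wide ancestry
  rather than rare-variant noise.  Missing frequencies are handled
  pairwise-complete, each pair's squared distance rescaled by
  J_total/J_pair.
* **Standardisation.** Each axis is standardised to mean 0 / SD 1 across
  studies, so meta-regression coefficients are interpretable as the effect
  change per 1 SD of ancestry.
* **Sign.** An MDS axis has arbitrary sign; each axis is oriented so a
  designated anchor study (by default the study with the largest-magnitude
  coordinate) is positive, making moderation signs reproducible.

## Stratified and multi-ancestry meta-analysis

Ancestry-stratified scans use the weighted-Z combination
Z_META = Σ_k w_k Z_k / (Σ_k w_k²)^½ with w_k = sqrt(N_k p_k (1−p_k) R²_k),
which accommodates differing phenotype scales, imputation quality and
sample sizes.

The multi-ancestry scan is the mixed-effects meta-regression

    b_jk = Σ_{l=0}^{L} C_lk γ_jl + e_jk + ε_jk,
    e_jk ~ N(0, τ²),  ε_jk ~ N(0, s²_jk),

with C_0k ≡ 1.  Setting L = 0 and τ² = 0 recovers fixed-effects
inverse-variance meta-analysis exactly; keeping e but no components is a
standard random-effects model; dropping e gives plain meta-regression.

Numerical choices:

* τ² is estimated by bounded one-dimensional profile likelihood on
  [0, 100·median s²].  The default criterion is **REML**: with five fixed
  effects estimated from a few dozen studies, the ML τ̂² is biased low
  enough to push 95% Wald interval coverage below 0.93 in simulation,
  while REML restores near-nominal coverage (0.94–0.95 at K=60).  ML
  remains available (`method="ml"`).  The gradient at τ²=0 is checked
  first; if non-positive the estimate is the boundary (τ̂²=0), which also
  makes null-variant scans fast.
* Association is tested by the joint Wald chi-square over all L+1
  coefficients (df = L+1), matching the (T+1)·log K parameter count used
  by the fine-mapping Bayes factor.
* Models with L = 0..4 components are combined by Bonferroni minimum-P:
  combined_p = min(1, M·min_l p_l) over the M fittable models.  This is
  conservative (the models are nested and correlated) but simple and
  valid; null simulations show rejection rates of ~2% at the 5% level.
* A model is skipped when the variant is present in fewer than L+2
  studies or the component design over contributing studies is collinear.
* Genome-wide significance uses P < 5×10⁻⁹, appropriate for scans
  including low-frequency variants.

## Effect-size-moderation mixture

Each variant is assigned a posterior over six sub-models: NULL (no effect,
no heterogeneity) and MR_0..MR_4 (intercept plus 0–4 ancestry components,
with the random effect).  Sub-model evidence is approximated by BIC-style
weights exp(−BIC_l/2) with BIC_l = −2·loglik_l + (l+1)·log K, mirroring the
Bayes-factor penalty; the log-likelihood entering BIC is the marginal ML
log-likelihood at the fitted parameters so that sub-models with different
fixed-effect counts are comparable.  A single NULL-vs-alternative weight,
shared across variants and initialised at (0.5, 0.5), is estimated by EM;
within the alternative the five models carry a uniform prior (an EM-updated
model prior was evaluated and found to cost detection power for moderated
variants with no false-positive benefit).  Convergence: 1e-6 on the
log-likelihood, maximum 1,000 iterations; non-convergence returns the best
iterate flagged.

Classification: the variant is *homogeneous* when NULL or MR_0 has the
largest posterior; otherwise at least *weakly heterogeneous*; *strongly
heterogeneous* additionally requires some non-intercept coefficient of the
selected model to have Wald p < 0.05/4 (Bonferroni over the four axes) and
the variant to be polymorphic (MAF > 0.01) in at least two
ancestry-stratified datasets.  With the random effect free in MR_0, part of
a true component-moderation signal is absorbed by τ², so detection power
for a coefficient three standard errors from zero is ≈ 0.75–0.80 at K=60
rather than the ≈ 0.84 a fixed-τ calculation would suggest; this trade-off
is inherent to letting MR_0 carry unexplained heterogeneity.

## Conditional analysis and loci

Sentinel variants (P < 5×10⁻⁹) seed ±500 kb windows, merged transitively
per chromosome.  Within a window, sequential forward selection builds the
independent set ϕ: the conditional Z of variant v given the selected set S
is

    z_cond = (z_v − r_vSᵀ R_SS⁻¹ z_S) / sqrt(1 − r_vSᵀ R_SS⁻¹ r_vS)

with R estimated from reference-panel dosage correlations and a 1e-3 ridge
on R_SS for stability with finite panels; selection stops when no
conditional P clears 5×10⁻⁹.  On simulated individual-level data (n=5,000)
this summary-statistic procedure reproduces exact stepwise multiple
regression in ≥95% of replicates.  Each independent variant then defines a
locus as all variants with r² > 0.1 against it; overlapping loci are
collapsed, and the sentinel is the minimum-P member (ties break to smaller
position, then lexicographic allele).

Reference panels are pooled across ancestries by largest-remainder
allocation to requested proportions; stratified analyses use the
ancestry-matched panel.

## Fine-mapping

Under a one-causal-variant-per-locus assumption, the approximate Bayes
factor for variant j is Λ_j = exp[(X_j − (T+1)·log K)/2], where X_j is the
joint Wald chi-square of the variant's selected moderation model, T its
component count (forced to 0 in single-ancestry mode) and K the number of
contributing studies.  Posterior inclusion probabilities are π_j = Λ_j/Σ_i
Λ_i within the locus and the 90% credible set is the smallest PIP-ranked
subset with cumulative mass ≥ 0.90 (the crossing variant included).  All
Bayes-factor arithmetic is done in log space.  Multi-signal loci are
fine-mapped on marginal statistics; genomic-control-corrected chi-squares
are used for low-MAF variants for consistency with the scan.

Genes are mapped by the nearest-gene rule (inside a gene body wins;
otherwise the nearer boundary; ties to the smaller start).  "High-priority"
genes come from credible sets with ≤ 4 variants; the enrichment background
is genes mapped from variants with PIP < 0.01 within associated loci, and
the relative risk between the two proportions carries a 95% CI from 2,000
seeded bootstrap resamples of each gene set.

## TWAS

For each meta-regression model, per-variant effect estimates (the model's
intercept coefficient, i.e. the effect at the ancestry centroid after
adjusting for the included axes) are projected through expression weights:

    z_gene = Σ_i w_i σ_i (β̂_i/se_i) / sqrt(wᵀ S R S w),  σ_i = sqrt(2 p_i (1−p_i)),

an S-PrediXcan-style burden statistic reconstructed here (the quadratic
form is not printed in the method's source description).  The four
component statistics (1–4 axes) are combined per tissue by Bonferroni
minimum-P; the intercept-only statistic is reported separately.  Tissues
are combined per gene by the Cauchy combination test with equal weights
(T = Σ w_i tan((0.5−p_i)π), p = 0.5 − arctan(T)/π), with p-values clipped
to [1e-15, 1−1e-15] and tail-stable approximations below 1e-10.
Significance uses a Bonferroni threshold of α/(n_genes·n_tissues); at the
consortium scale of 22,121 genes × 49 tissues this is ≈ 4.6×10⁻⁸.

## Synthetic data

The generator emulates the structure the analysis assumes, at desk scale:

* **Frequencies**: Balding–Nichols draws around a shared base frequency
  (Uniform(0.05, 0.95)) with per-ancestry F = 0.1 by default (continental-
  scale differentiation); study frequencies are ancestry-proportion
  mixtures (Dirichlet(0.2) proportions, so most cohorts are nearly
  single-ancestry, as in real consortia), plus a small fourth-axis
  within-ancestry gradient so all four MDS axes are recoverable.
* **Effects**: drawn exactly from the meta-regression generative model
  with the standardised-trait standard error s = 1/sqrt(2·N·p(1−p)·R²),
  which closes the loop with the weighted-Z weights and makes analytic
  power checks exact.  Cohort sizes are log-uniform on [1,000, 50,000]
  (K = 60 by default) and imputation quality is Beta(20, 2).
* **LD**: haplotypes from a latent Gaussian AR(1) process thresholded at
  frequency quantiles; genotypes are haplotype sums.
* **Locus effects**: for fine-mapping and conditional experiments,
  per-study Z vectors are drawn as N(sqrt(ncp/K)·R[:,c], R), giving the
  causal variant a specified pooled noncentrality with LD-propagated
  signal.

What the generator does **not** emulate: binary traits and case-control
ascertainment (all traits are quasi-continuous; logistic-scale effects are
upstream of this package's entry point), realistic recombination-driven LD
(AR(1) is a caricature with monotone decay), allele-frequency-dependent
genetic architecture, imputation error correlated with frequency, sample
overlap between cohorts, and population stratification within studies.
Passing tests therefore demonstrate internal statistical correctness and
calibration under the stated model, not robustness to those real-data
complications.

## Validation scale

Simulation-based checks use problem sizes chosen to exercise the
asymptotics the method relies on while staying comfortably reproducible on
a laptop: 10,000-variant null scans at K=40 for calibration; 1,000
replicates at K=60 for parameter recovery and interval coverage; 500
single-causal loci of 50 variants for credible-set coverage; 200
replicates of n=5,000 individual-level cohorts for conditional-selection
fidelity; and a full 60-study × 20,000-variant pipeline run for stage
invariants.  `scripts/acceptance.py` re-runs the credible-set coverage
experiment from scratch and writes the empirical coverage percentage.

## Known limitations

* One causal variant per locus is assumed in fine-mapping; multi-causal
  loci are handled only through conditional selection, not joint credible
  sets.
* The minimum-P combinations (across component models, and across TWAS
  component statistics) are Bonferroni-conservative.
* Conditional Z-scores degrade when the reference panel mismatches the
  contributing cohorts' LD; the ridge term stabilises but does not remove
  this.
* The moderation classifier's power is limited by τ²/moderation
  confounding (see above); strongly heterogeneous calls additionally
  depend on per-ancestry MAF tables supplied by the caller.
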