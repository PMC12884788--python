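# Methods

This note documents the statistical models, the synthetic-data generator,
the numerical choices, and the known limitations of `gweistools`.

## The analysis pipeline

The pipeline identifies gene-environment interactions on imaging
phenotypes in three consecutive steps — discover, confirm, verify —
followed by characterization stages.

### Phenotype preparation

Imaging phenotypes pooled across scanners carry location and scale batch
effects.  `combat_harmonize` implements parametric empirical-Bayes ComBat:
per-scanner, per-phenotype means and variances are estimated on
standardized residuals, shrunk toward across-phenotype priors (normal for
locations, inverse-gamma for scales, hyperparameters moment-matched), and
removed; protected biological covariates are fit jointly and re-added.
Shrinkage deliberately leaves residual batch differences at the sampling
noise scale, so the "scanner means agree after harmonization" property is
asymptotic in the per-scanner n.  Because the subsequent normal-score
transform depends only on ranks, the transform itself is exactly
idempotent; re-running the whole prep pair on its own output moves values
only where a second EB pass swaps adjacent ranks across scanners
(quantile-gap scale, ~10⁻² at n ≈ 10³).

The normal-score transform is rank-based with the Blom offset:
Φ⁻¹((r − 3/8)/(n + 1/4)), tied ranks averaged, missing values preserved.
Blom's offset is the standard small-sample choice; nothing downstream is
sensitive to the offset convention.

Covariate designs are assembled per IDP category: age, sex, and 10 genetic
principal components always; plus total intracranial volume for gray
matter volumes, total surface area for surface areas, mean cortical
thickness for thicknesses, and mean framewise displacement for the
functional categories (amplitude, connectivity, homogeneity).  Tract FA
gets the base design only.  Genetic PCs are computed from the
column-standardized dosage matrix by SVD with a deterministic sign
convention (largest-magnitude loading positive).

### Exposome structure

Exposures are correlated by pairwise-complete Spearman correlation and
clustered agglomeratively on the sign-blind distance 1 − |ρ| with average
linkage: inversely related exposures (vegetation cover and air pollution,
say) measure the same environmental axis and belong in one category.  The
number of categories k maximizes the Calinski-Harabasz index
CH(k) = [B/(k−1)]/[W/(n−k)], computed on the rows of the correlation
matrix as the coordinate embedding (the index needs coordinates; the
correlation profile of an exposure is its natural feature vector).  Ties
break toward the smallest k and are flagged; a flat CH profile (best value
within 20% of the runner-up) marks the clustering unreliable, which is the
expected outcome on structureless exposomes.  Candidate k values that the
tied merge heights of the tree cannot realize are skipped.

### Univariate scan

At each variant with MAF ≥ 0.05 the interaction model
y = μ + β_G x_G + β_E x_E + β_GE x_G x_E + β_C x_C + ε is fit by OLS with
genotype and exposure standardized on the analysis rows and the product
formed after standardization, so the scan is invariant to exposure units
and the interaction coefficient is on a per-SD scale.  Classical
(homoskedastic) standard errors are the default.  The scan is vectorized
by Frisch-Waugh residualization against the variant-independent block
(intercept, covariates, exposure), which reproduces full-design OLS
exactly; monomorphic or missing variants are skipped and logged.
Complete cases are taken per scan, maximizing n per analysis.

Genomic control: λ_GC is the median of the per-variant 1-df χ² statistics
divided by 0.4549 (the χ²₁ median).  When λ_GC > 1, every χ² is divided by
λ_GC and p recomputed from the χ²₁ tail; deflation is never applied
(λ ≤ 1 leaves p unchanged).  λ is computed per exposure-IDP scan.

Male non-PAR X-chromosome dosages (hemizygous, raw 0–1) are doubled into
the 0–2 range; females, PAR variants and autosomes are untouched.  A male
non-PAR raw dosage above 1 is treated as a data inconsistency.

### Clumping, conditioning, loci

Significant records are greedily clumped: the most significant remaining
variant becomes a lead (equal p broken toward the lower position) and
absorbs variants within 500 kb AND r² > 0.1 — both conditions required.
r² is the squared Pearson correlation of dosages on the analysis sample
(no external reference panel).

Within one variant-IDP pair, interactions of correlated exposures are
pruned by iterative conditioning: the most significant interaction is
selected, every remaining candidate is refit with the selected exposures'
interaction terms AND their main effects added as covariates (adding the
main effect prevents attributing main-effect signal to the conditioned
interaction term), and candidates still below 5×10⁻⁸ continue.
Rank-deficient refits drop the candidate with a log entry.

Lead windows (±500 kb, starts clipped to 1) merge when they overlap, when
leads are in r² > 0.1 on the same chromosome, and when they touch the MHC
(chr6:25,119,106–33,854,733) or chr8p23.1 inversion
(chr8:7,242,715–12,483,982) regions — one locus per special region.
Coordinates are 1-based inclusive internally; BED exports convert to
0-based half-open.

### Structured LMM confirmation

The multivariate model places a random interaction slope on the genotype
with covariance structured by environmental similarity:
Var(y) = σ²_GxE·diag(G)EEᵀdiag(G) + σ²_e·EEᵀ + σ²_n·I, fixed effects
[X, G].  Exposure columns are standardized and EEᵀ trace-normalized to n
so the variance components share a scale.  The stage uses participants
with complete data for all exposures.

The null (σ²_GxE = 0) is fit by REML, profiling the ratio
δ = σ²_e/σ²_n on the log scale (bounded scalar optimization after a coarse
grid, with an explicit δ→0 boundary check).  Because EEᵀ has rank
k = n_exposures ≪ n, all likelihood evaluations use the thin SVD of E:
O(nk) per evaluation, no dense eigendecomposition.

The score statistic Q = ½·yᵀPK_gPy (P the REML projection, K_g the
genotype-scaled kernel) is referred to its null, a weighted sum of χ²₁
with weights the nonzero eigenvalues of ½FᵀPF, F = diag(G)E — a k×k
problem.  P-values use Imhof's characteristic-function inversion
(`scipy.integrate.quad`); when the oscillatory integral fails its accuracy
check the Liu-Tang-Zhang moment-matching approximation takes over (exact
for equal weights, conservative in the far tail).  Score-test p-values are
BH-FDR corrected across variant-IDP pairs (own step-up implementation,
cross-checked against statsmodels in the tests).

### Per-exposure Bayes factors and the verification rule

BF_k is leave-one-in: the restricted log-likelihood gain of adding a
rank-one interaction component built from exposure k alone
(u = G∘E_k, kernel trace-normalized), with the null variance components
held at their REML estimates and only the rank-one variance profiled
(Sherman-Morrison update, 1-D bounded optimization; BF clipped at 0 since
the null is nested).  This plug-in construction is deterministic, O(n) per
likelihood evaluation, and rank-faithful, which is all the verification
rule consumes.  Under the null roughly half the profiled variances hit the
zero boundary, producing exact BF ties at 0; tied BFs are ordered by the
single-exposure score statistic — a continuous, null-symmetric tie-break —
and only exposures tied on both (e.g. duplicated columns) share the
minimum rank and are flagged.  Non-convergent exposures rank last,
flagged.

An interaction is verified iff its pair's score-test q < 0.05 AND its
exposure's BF rank ≤ the number of univariate independent interactions
found for the pair.  The verified set is therefore always a subset of the
univariate discoveries: the multivariate stage only prunes.

### Effects decomposition

Main effects are estimated in separate models (y ~ g + C and y ~ e + C)
rather than read off the interaction model, because main-effect
significance inside an interaction model depends on variable coding.
Eta-squared uses add-last (partial) sums of squares over the mean-centered
total sum of squares; the spec-level wording does not fix the SS type, and
add-last is the choice that makes η² the unique contribution of the term
given everything else.  Wilcoxon rank-sum comparisons of η² lists use the
tie-corrected normal approximation, switching to exact enumeration when
both samples have n ≤ 10.

Genotype subgroups hard-call dosage at 0–0.2 / 0.8–1.2 / 1.8–2.0 (outside
→ missing genotype); a minor-homozygote bin under 30 participants merges
into the heterozygote bin; the per-bin exposure slope is tested at
α = 0.05/bins; any analyzed bin still under 30 skips the analysis.

### Distributed-lag sensitive periods

For 18-year exposure histories the DLM constrains both the exposure lag
curve α(j) and the interaction lag curve γ(j) through a natural cubic
spline with 3 degrees of freedom: boundary knots at lags 1 and 18,
internal knots equally spaced between (the even-spacing wording does not
pin the boundary convention; boundary-at-edges is the standard one).  The
fit is OLS on the cross-basis transforms W_α = E·C and W_γ = (E∘G)·C;
per-age γ̂ⱼ = Cⱼθ̂ with Wald 95% CIs from the coefficient covariance.  A
sensitive period is a maximal run of consecutive ages whose CI excludes
zero.  Exposure lag histories with heavy missingness are truncated from
the edges (never interior ages), dropping whichever edge lag carries more
missing cells until the complete-case sample reaches the floor (default
500); interactions analyzed on truncated ranges are excluded from the
cohort-level period-frequency profile.

A 3-df spline over 18 lags has limited resolution: a planted window at
ages 4–7 is recovered as a hump whose flagged run extends toward the left
boundary (the basis cannot return to zero left of the first internal
knot), so window midpoints are accurate to about a year while window
edges blur.  Cohort-level frequency profiles over windows planted at 4–7
and 12–15 show the corresponding two-peak structure with a left plateau.

## The synthetic cohort generator

The generator produces the statistical structure the analysis assumes, so
passing tests demonstrate correctness of the machinery on data of that
structure — not performance on real cohorts.

- **Genotypes.** Two latent AR(1) Gaussian haplotype processes per person,
  thresholded at the per-variant allele-frequency quantile and summed:
  dosages in {0,1,2} with MAF uniform in [0.05, 0.5] by default and
  adjacent-variant LD decaying geometrically with the latent
  autocorrelation (`ld_decay`).  This gives tunable LD without haplotype
  panels; it does not reproduce human block structure or recombination
  hotspots.  Hard genotypes, not fractional imputed dosages, are emulated;
  imputation INFO filtering is modeled as a pass-through input filter.
- **Exposome.** 41 exposures in 4 correlated clusters by default (block
  factor model, within-cluster correlation 0.5, across ≈ 0), with ~20%
  dichotomized to emulate binary questionnaire items.
- **Trajectories.** Per-age series = the participant's long-run value plus
  AR(1) deviations (coefficient 0.7 by default) centered so the mean over
  ages equals the stored time-invariant value exactly; deviation SD equals
  the cross-sectional SD — over an 18-year span, exposures like night-time
  lights or PM2.5 change within a person as much as they differ between
  people.  Missingness is injected completely at random.
- **Phenotypes.** Each IDP is covariate signal (10% of variance) + planted
  β_G·g + β_E·e + β_GE·g·e on standardized terms + Gaussian noise filling
  the variance to 1, then per-scanner shift (SD 0.3) and log-normal scale
  (SD 0.1) batch effects.  Coefficients are solved analytically from the
  target variance shares using the realized variance of each term on the
  simulated cohort, so planted η² is matched without iterative tuning;
  realized shares are recorded in the truth object before noise.  Planted
  effects with a sensitive window interact through the window-averaged
  trajectory, making the window the DLM ground truth.
- **Determinism.** Every stage draws from an independent stream derived
  from the config seed; identical configs give identical cohorts.

Default effect scale for planted interactions is η² ≈ 0.005 (0.5% of
phenotype variance), the scale at which the pipeline's power properties
are evaluated; at n = 2000 such effects sit below the genome-wide
threshold by design, so demonstration configs use stronger effects
(η² ≈ 0.02–0.03).

## Problem sizes and numerical choices

- Test-suite simulations use n = 500–5000 participants, 20–4000 variants,
  and 10–80 replicates per calibration check; the acceptance script uses
  2000 replicates for the univariate size check, 1500 for the score-test
  size check, 10–20 seeds for recovery rates.  These sizes put binomial
  error comfortably inside the asserted bands on a single CPU.
- REML optimization: log-δ grid on [−12, 8] (41 points) then bounded
  Brent refinement; δ below 10⁻¹⁰ is truncated to the OLS boundary.
- Imhof integration accepts the result only if the quadrature error
  estimate is below 10⁻⁴ and the value lies in [0, 1]; eigenvalues below
  10⁻¹⁰ of the largest are dropped from the mixture.
- OLS uses `lstsq`/normal equations on designs that are standardized
  first; rank deficiency raises rather than silently pseudo-inverting.
- Wald CIs use the 1.96 normal quantile.
- p-values are clipped away from exact 0 (at the smallest positive
  float), so downstream −log₁₀ transforms and BH-FDR stay finite.

## Known limitations

- OLS with genetic PCs, not a kinship mixed model: close relatedness is
  out of scope.
- The BF construction is the leave-one-in REML plug-in, not a fully
  Bayesian marginal likelihood; it is used only through its ranks.
- ComBat is parametric EB only; non-parametric and longitudinal variants
  are out of scope.
- The DLM models a linear interaction-response; nonlinear
  exposure-response surfaces and penalized smoothing-parameter selection
  are out of scope.
- The generator's LD, exposome and noise models are deliberately simple;
  results on real cohorts additionally depend on imputation quality,
  population structure, and exposure measurement error that the generator
  does not emulate.
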