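# Methods

This note documents the models, the numerical choices behind them, what the
synthetic data does and does not emulate, and the known limitations.

## Empirical Bayes matrix factorization

### The normal-means solver

Every factor update reduces to the empirical Bayes normal-means problem:
observations x_i = θ_i + N(0, s_i²) with known s_i, prior
θ ~ π₀·δ₀ + (1−π₀)·slab. Two slab families are implemented: a zero-mean
normal with variance τ² ("point-normal") and a zero-mean Laplace with rate
b ("point-laplace"). (π₀, scale) are chosen by maximizing the marginal
likelihood with L-BFGS-B on (logit π₀, log scale) from a small set of
moment-matched starts; inside iterative refits the previous optimum is the
first start. Posterior means and second moments are closed-form: for the
normal slab, ridge shrinkage weighted by the slab responsibility; for the
Laplace slab, a two-component mixture of half-line-truncated normals with
means x ∓ b s². All marginal densities and truncated-normal hazard ratios
go through exponentially scaled complementary error functions (`erfcx`),
with the reflection erfcx(u) = 2e^{u²} − erfcx(−u) applied below u = −20,
so arbitrarily extreme observations neither overflow nor lose precision.
A brute-force quadrature oracle in the test suite pins the posterior
moments to 1e−6.

### Greedy + backfit

A new factor is initialized from the leading singular pair of the running
residual (deterministic; LAPACK SVD). Rank-1 coordinate ascent alternates
the two collapsed EBNM problems — loading observations
x_j = (Σ_i R_ij E[f_i]) / Σ_i E[f_i²] with s_j² = ψ_j / Σ_i E[f_i²], and
the symmetric score side weighted by 1/ψ_j — followed by the Ψ update
(per-column mean expected squared residual, floored at 1e−8). Convergence
is declared when the variational lower bound changes by less than
tol·(1+|bound|), tol = 1e−6 by default, at most 200 inner iterations. The
bound is the Gaussian expected log-likelihood plus, per side and factor,
(marginal log-likelihood − expected data log-likelihood), which equals
−KL(posterior‖prior) up to the shared terms; it is non-decreasing over
backfit sweeps and is used only for convergence, never for model
selection.

**Nullcheck.** A converged candidate factor is kept only if the bound with
the factor beats the bound with the factor removed (Ψ refit). Without this
check, standardized pure-noise matrices retain one or two spurious sparse
factors (point-mass weight ≈ 0.97, PVE ≈ 0.2%) that live at a genuine
fixed point of the coordinate ascent; the nullcheck removes them (the KL
cost exceeds the fit gain by several nats) while leaving planted factors,
whose bound improvement is orders of magnitude larger, untouched.

**Identifiability.** Scores are scaled to unit sample variance with the
scale absorbed into the loadings, each factor's sign is chosen so its
largest-|loading| entry is positive, and factors are ordered by PVE.

### Orthogonal cross-validation

Rows and columns are independently partitioned into `folds` groups; fold t
holds out the (row-group, col-group) blocks with (g_r + g_c) mod folds = t,
so the test sets partition all cells and every row and column keeps
(folds−1)/folds of its entries. Masked cells get zero weight in every sum
and Ψ is updated from observed cells only; held-out cells are predicted by
FΓ. RMSE and Pearson r are averaged over folds and reported per repeat.
Backfitting (10 sweeps by default) matters here: greedy-only fits leave
systematic completion error on held-out cells.

## Enrichment

PVE_kc = Σ_{j∈c} λ_kj² / Σ_j λ_kj². The null draws compound sets of the
class's size from *all* compounds (annotated or not) without replacement,
1000 times per (factor, class) by default, independently per combination;
p = (1 + #{null ≥ observed}) / (1 + n_draws), the +1 preventing zero
Monte-Carlo p-values. Classes with fewer than five compounds are excluded.
q-values use Storey's plug-in π̂₀ at λ = 0.5 jointly across all factor ×
level × class tests, falling back to Benjamini–Hochberg below 50 tests
where the plug-in is unstable. Note the granularity limit: with n_draws
permutations the smallest attainable p is 1/(n_draws+1), so the smallest
attainable q scales with (number of tests)/(rank of the hit); sparse
enrichment signals need either more permutations or more true signals to
clear a q threshold.

## Subpopulation screening

One-way ANOVA per metabolite with BH adjustment (flag at p_BH < 0.01).
Pst = (c/h²·σ̂²_B)/(c/h²·σ̂²_B + 2σ̂²_W) with σ̂²_B = max(0,(MSB−MSW)/n₀),
n₀ the standard unequal-group-size coefficient, and c/h² = 1 by default —
the estimator is invariant to affine transforms of the phenotype. The
genetic baseline is the per-locus multi-population Weir–Cockerham θ
(lines treated as diploid individuals; dosage 1 = heterozygote;
monomorphic loci excluded); a metabolite is flagged when its Pst exceeds
the 80th percentile of the locus-wise Fst distribution over the
MAF-filtered set. Factor–structure association uses the fixed-effect
group-means R² per factor, in percent.

## GWAS

GRM: VanRaden method 1 (pooled scaling) or method 2 (per-marker scaling,
default for association); principal components come from the GRM
eigenvectors — two for association fixed effects, ten for the R²_GWAS
models. The null model y = Xb + u + e is fit by REML through one
eigendecomposition of G and a bounded 1-D optimization of log γ
(γ = σ²_u/σ²_e ∈ [e⁻¹², e¹²]); an identity-proportional G is detected and
reported as degenerate (components not separately identifiable). Marker
tests fix the variance components at the null estimates and run
generalized least squares on spectrally decorrelated data: effects, SEs,
and two-sided t p-values (df = n − rank(X) − 1) are fully vectorized, and
markers collinear with the fixed effects get p = 1 and a flag. A
brute-force GLS oracle (explicit covariance inverse) agrees to 1e−8.

Meff is the Li–Ji estimator Σ_i [I(λ_i ≥ 1) + (λ_i − ⌊λ_i⌋)] on the marker
correlation eigenvalues; above 5000 markers the sum is taken over
non-overlapping windows (between-window correlation is ignored, which can
only increase the estimate — conservative for thresholding). The per-test
level is α_p = 1 − (1−α_e)^{1/(Meff·K)}, evaluated via expm1/log1p.
R²_GWAS compares OLS fits with and without the significant markers on top
of ten GRM PCs and is reported both as (RSS_red − RSS_full)/RSS_red and as
the raw difference.

## Whole-genome regression

Bayes Cπ and BayesB share one numba-compiled Gibbs sampler over
spike-and-slab marker effects. Per sweep: intercept; optional independent
trial effects; per marker, inclusion sampled from its conditional odds and
the effect from its Gaussian conditional (residuals maintained through
line-level aggregates, so each marker update is O(n_lines) even for
multi-trial record data); the slab variance (common, scaled-inv-χ²
conjugate for Cπ; per-marker, giving marginally scaled-t effects, for
BayesB); π from its beta conditional — uniform prior for Cπ,
Beta(π₀c,(1−π₀)c) with π₀ = 0.5, c = 2 for BayesB; the residual variance.
Hyperpriors are weakly informative scaled-inv-χ² with 5 df, scales matched
to an even genetics/noise split of var(y). Genomic h² is computed per
stored draw as var(Wa)/(var(Wa)+σ²_e) and averaged. Chains default to a
desk-scale 20,000 iterations with half (Cπ) or a quarter (BayesB)
discarded and thinning 10; all draws flow from one seed, so chains
reproduce exactly. The polygenicity of a trait is the posterior mean of
1 − π; the architecture analysis ranks polygenicity, loading density, and
h², regresses the first two rank vectors on the third, and correlates the
residuals (partial Spearman; p from the t transform with n − 3 df).

## Multi-kernel prediction

Marker partitioning: the informed set is the GWAS hits present in the
prediction panel plus every marker whose squared dosage correlation with
any hit exceeds 0.25 (LD computed on the prediction panel); the complement
forms the second kernel. Both kernels are VanRaden method-1 GRMs on their
subsets; the count-weighted kernel sum reconstructs the all-marker GRM.

Fitting is a Gibbs sampler on the eigen-representation of each kernel
(random regression on U·diag(√λ) columns, coefficients N(0, σ²_kernel)),
plus a 0/1 trial-incidence block with its own variance and a Gaussian
residual; test-line genomic values come from the kernel rows of the
eigenbasis, i.e. through the kernel covariance with the training lines.
The genomic value is the sum over kernels. An empty informed set falls
back to single-kernel gBLUP.

**Prior allocation across kernels.** The genetic-variance prior scale is
split between kernels by `kernel_shares`. The default is an even split,
but when the kernels partition a marker panel, shares proportional to the
marker counts are the right choice and are what the pipeline passes: with
an even split, a small uninformative kernel (say 12 of 800 markers)
receives a prior scale ~25× its data share, absorbs noise, and
systematically *loses* accuracy relative to gBLUP; with count-proportional
shares the same decoy kernel is inert (win fraction 0.5) while a kernel
holding genuine large QTL still dominates its prior and delivers its full
accuracy gain.

Cross-validation is by line: lines are partitioned into five folds, every
trial record of a test line is held out, accuracy is the fold-averaged
Pearson correlation between held-out records and predicted genomic
values, and resampling repeats the partition (50 by default). A model
"significantly" beats a baseline when its accuracy is higher in at least
90% of resamplings; both models see identical folds and chain seeds, so
the comparison is paired.

## The synthetic generator

The generator is the package's study design. Defaults: 335 lines in six
subpopulations at Balding–Nichols divergence 0.1 (allele frequencies
Beta-distributed around a U(0.1, 0.9) ancestral frequency, clipped to
[0.01, 0.99]); 2000 markers in 5-marker LD blocks, each block sharing one
frequency, non-seed markers copying the block seed with a 0.1 per-line
redraw probability (intra-block r² ≈ 0.7); eight factors spanning
heritabilities 0.1–0.8, loading densities 0.15–0.8, and oligogenic (3–10
QTL carrying 90% of the genetic variance over a polygenic background) to
fully polygenic architectures — sparse factors oligogenic and dense ones
polygenic, so density and polygenicity are positively coupled as the
enrichment-prediction workflow expects; 600 metabolites with exact
per-factor loading counts, Laplace(1) nonzero loadings, and N(0, 0.4²)
column noise, standardized afterwards; a third of compounds annotated in a
five-level nested hierarchy (permuted round-robin parent assignment, so
every class has descendants) with three planted (factor → class)
enrichments — two lipid, one amino-acid, mirroring the dominance of lipid
classes in real seed metabolomes and giving the joint q-value machinery
enough true signals to operate at its usual granularity; and two two-trial
traits (h² = 0.5) whose genetic values are linear in the factors' genetic
values, the first tracking the first planted lipid factor. Scores are
built as √h²·(standardized genetic value) + √(1−h²)·(standardized noise),
so realized heritabilities track targets closely at n ≥ 300. All stages
draw from per-stage streams derived from one seed (CRC-stable), so a
configuration reproduces bit-for-bit.

What it does not emulate: mass-spectral missingness and batch drift,
field-trial spatial structure, pedigree relatedness, residual metabolite
covariance beyond the diagonal factor model, genotyping error, and real
LD decay (blocks are exchangeable, not positional). Tests passing on this
generator therefore certify the statistical machinery — recovery,
calibration, ordering, prediction gain under the stated architectures —
not robustness to those real-data artifacts.

## Problem sizes in the test suite

The shipped tests run the full pipeline at 100–335 lines, 200–2000
markers, 120–600 metabolites, chains of 800–8000 iterations, and 2–20
cross-validation resamplings, sizes at which every stage's statistical
behavior (type-I error, power, ordering, win fractions) is already stable;
all the corresponding knobs accept larger values.

## Known limitations

* The adaptive-shrinkage (nonparametric mixture) prior family is not
  implemented; model selection is between point-normal and point-Laplace.
* The greedy factor count is sensitive to convergence depth on noiseless
  or near-noiseless data: an under-converged residual can admit one extra
  factor that backfitting later redistributes; cap `max_factors` when the
  rank is known.
* Exact per-marker REML (rather than null-fixed variance components) is
  out of scope, as are multi-locus association models and G×E kernels.
* The windowed Meff ignores between-window LD and therefore upper-bounds
  the exact estimator.
* Single-chain MCMC with fixed seeds; no formal convergence diagnostics
  are run beyond the reproducibility guarantees.
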