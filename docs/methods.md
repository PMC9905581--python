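# Methods

## The prediction problem

A breeding trial phenotypes a population in m environments (years or
sites). Replicated designs observe the same lines everywhere (doubled
haploids, clones); heterogeneous designs observe disjoint individuals per
site, related only through family structure (open-pollinated half-sib
families). In both cases the goal is to predict unobserved
(individual, environment) cells from genome-wide SNP markers, in the
presence of genotype-by-environment interaction: genetic effects whose
magnitude or sign changes across environments.

## Kernels and marker weights

Genetic similarity between individuals i and k is encoded by a Gaussian
kernel exp(−h·d²_ik/s) on dosage vectors (0/1/2), with s the maximum of
d² over all record pairs, so entries lie in (0, 1] and the most distant
pair sits at exp(−h). The bandwidth h defaults to 1 and is exposed in the
configuration but not tuned (bandwidth grids and empirical-Bayes tuning
are out of scope).

The weighted kernel replaces the Euclidean distance by
d*² = Σ_l w_l (x_il − x_kl)². Weights combine:

* **Rare-variant mass** — a Beta(MAF_l; α, β) density, α = 1, which decays
  in MAF; β controls how sharply rare variants are up-weighted
  (grid {12, 25, 50, 100, 200}).
* **Association evidence** — inverse shifted FDR-adjusted p-values
  1/(0.1 + p) for the marker main effect and the marker×environment
  interaction. The 0.1 shift caps a zero p-value's contribution at 10.
* **The constant c1** scales the Beta term so its maximum matches the
  largest association term: c1 = max(1/(0.1+p))/Beta(min MAF; α, β).
  When the smallest adjusted p-value and the smallest MAF are both ~0,
  c1 ≈ 10/β — which is why β cannot grow without bound: it would only
  shrink c1 toward zero, never remove the MAF term entirely.

Because weights enter d*²/s* as a ratio, a common factor cancels: uniform
weights reproduce the Gaussian kernel to machine precision, which the test
suite asserts.

**Normalizer scope.** For multi-environment kernels, one global maximum
squared distance over *all* records scales every within- and
cross-environment block. This is the only convention under which the
assembled kernel matrix is positive semidefinite as a whole; a
single-environment kernel used alone takes its own per-environment
maximum. For replicated lines the two conventions coincide.

## The G×E association scan

Per marker, the fixed-effects model
`value ~ intercept + environment + marker + marker×environment`
is fitted by least squares on the stacked records, with sum-to-zero
environment coding so the marker coefficient is the environment-averaged
slope (a pure crossover interaction therefore nulls the main-effect test).
p-value 1 is the 1-df t-test of that coefficient; p-value 2 is the joint
F-test of the m−1 interaction columns against the nested model. Both raw
vectors are Benjamini–Hochberg adjusted, separately. BH was chosen over
q-values as parameter-free and deterministic; the nominal 0.05 level is
metadata only, since adjusted p-values enter the weights continuously.
There is no kinship correction inside the scan — the downstream kernel
mixed model absorbs relatedness — which is a known divergence risk if the
scan's p-values are interpreted as standalone GWAS results. Constant
markers get p = 1 (flagged), keeping weight vectors aligned with the
kernel's marker set. The least-squares internals are validated against
statsmodels OLS/ANOVA in the tests.

## Bayesian samplers

Scalar variances carry scaled-inverse-χ² priors (df 5, scale = half the
phenotypic variance of the relevant environment) — proper and weakly
informative. The samplers were built here because the model's
Hadamard-structured multi-environment covariance is not available in
off-the-shelf mixed-model software.

**SE sampler.** Works in the eigenbases of K and B, so each Gibbs sweep is
O(n²) and exactly handles singular kernels (zero-eigenvalue directions are
pinned at zero). Defaults 12000 iterations, 6000 burn-in.

**ME, kronecker regime** (replicated lines, identity background): with
identical individuals per environment, Σ_g = G_env ⊗ K. In K's eigenbasis
the latent genetic values decouple into n independent m-dimensional
normals, and G_env has a conjugate inverse-Wishart update
(df m + 2, scale = diag of per-environment phenotypic variances / 2).
Defaults 20000/10000.

**ME, general regime** (disjoint individuals): Σ_g[i,k] =
G_env[env(i), env(k)]·K[i,k] breaks conjugacy, so G_env moves by
random-scan Metropolis-within-Gibbs — random-walk proposals on log
variances and Fisher-z correlations (uniform(−1, 1) priors on
correlations, with the appropriate Jacobians), one randomly chosen
component per sweep. Step sizes adapt every 50 proposals during burn-in
toward a 20–45% acceptance rate and are frozen afterwards to preserve
detailed balance. Non-positive-definite proposals are rejected outright
and never stored; every stored G_env draw passes a Cholesky
factorization. The latent g is drawn by Matheron's rule (one Cholesky of
Σ_g + Σ_e per sweep); writing Σ_g = P·(R∘C)·P with P the per-record sd
diagonal lets variance-only proposals reuse the cached correlation factor,
so only correlation moves pay a fresh factorization. Defaults
100000/50000. In half-sib mode the background covariance matrix is updated
the same way with B blocks; in identity mode cross-environment background
covariances are fixed at zero and the per-environment background variances
are conjugate.

The exact priors and proposal mechanism are this package's own choices —
chosen to be proper, conjugate where conjugacy exists, and otherwise
standard — and are stated here rather than inherited from any external
implementation.

**Prediction (CV2).** For each thinned posterior draw (thin = 10), the
held-out records' conditional mean
μ_TST + Σ_(TST,TRN) Σ_(TRN,TRN)⁻¹ (y_TRN − μ_TRN) is computed under that
draw's parameters and averaged — closer to the Bayesian predictive than
plugging in posterior means. A singular training covariance gets one 1e−6
ridge retry. All covariance factorizations add a 1e−8 diagonal jitter.

**Heritability** is the posterior mean of σ²_g/(σ²_g + σ²_b + σ²_e) per
environment (diagonal of G_env for ME fits), under the GBLUP convention of
an additive kernel ZZ′/c with c the mean diagonal.

## Identifiability caveat

With an identity background matrix, b and e are iid and only their sum is
identifiable; the proper priors keep both finite, and h² (which uses their
sum) is unaffected. More importantly, when the marker count p reaches or
exceeds the number of lines, the additive kernel spans the whole line
space and the genetic term can imitate iid noise: null heritability then
floors near 0.15 rather than 0, and h² recovery is mildly biased downward.
The recovery tests therefore simulate with p < n, where the variance split
is identifiable; real data with p ≫ n inherits the same softness, which is
a property of the model, not of this implementation.

## Cross-validation harness

70/30 TRN/TST, 50 replicates by default. Two holdout modes are
first-class: `line` removes the same individual ids from every environment
(matching an (n_70 × m) description of the split), `cell` removes
(individual, environment) cells independently per environment (the
classical CV2 pattern). MAF, GWAS p-values, weights and β are recomputed
per partition from training records only; each replicate records a hash of
its training keys so leakage is auditable. β is chosen by an inner 80/20
split repeated 5 times within the training records, maximizing mean inner
PCOR with ties toward smaller β; a single-element grid short-circuits the
inner loop. Failed replicate×variant runs are recorded and excluded with a
warning, never silently dropped. Scores are Pearson correlation (PCOR) and
mean squared error (MSE) per environment.

## Synthetic data

The generator reproduces the statistical structure the models assume, not
any particular dataset:

* **dh_shared_lines** — fully homozygous lines (dosage 0/2), genotyped
  once, phenotyped in all m environments. MAF spectrum: a two-component
  mixture with a rare mass below 0.2 (default 64% of markers, as in a
  wheat DH panel) and a common mode in 0.4–0.5.
* **half_sib_disjoint** — families with one common parent; each offspring
  inherits one parental gamete and one population gamete, so realized
  within-family relatedness varies around the expected 0.25. Individuals
  are disjoint across environments, families span them. Default 88% of
  markers below MAF 0.2, as in conifer panels. A `subsample_families`
  helper equalizes family sizes.

Phenotypes follow y = μ + g + b + e. QTL effects per environment are drawn
from an m-variate normal with the configured genetic correlation matrix
(exact PSD square root, so correlation 1 gives identical effects), and by
default are standardized by marker heterozygosity (κ = 1), i.e. each QTL
contributes equal expected variance — the classical inverse relationship
between effect size and allele frequency, which also keeps realized
genetic correlations concentrated near their targets (scatter ~1/√n_qtl).
Residual variance is set per environment to hit the target heritability
exactly in expectation; realized h² and genetic correlations are recorded
as ground truth.

**What the simulator does not emulate:** linkage disequilibrium (markers
are independent), selection and drift, unbalanced replication, and
non-additive gene action. Passing tests therefore demonstrate correctness
of the machinery under the model's own assumptions, not performance on
real LD-structured genomes.

## Problem sizes used in the validation suite

The automated suite scales the study designs to what a single workstation
core handles comfortably: parameter recovery of the general-regime sampler
uses 20 datasets of 200 lines × 2 environments with chains of 10000
iterations (5000 burn-in); the GWAS null calibration uses 50 replicates of
300 records × 200 markers; the qualitative model comparisons use 10 CV
replicates of 100-line populations with 2000-iteration chains. The
defaults in `RunConfig` remain at the full reference settings.

## Known limitations

* The general-regime sampler costs one-to-two dense Cholesky
  factorizations per sweep (O(N³), N = total records); a few thousand
  records is the practical ceiling on one core.
* Identity-background b/e confounding and p ≥ n kernel softness, as
  discussed above.
* The β grid is searched, not modelled; kernel averaging over β is out of
  scope, as are dominance/epistatic kernels, multi-trait models, and
  environmental covariates.
* The per-marker scan assumes homoscedastic Gaussian errors within the
  two-way layout; heavy-tailed traits should be transformed first.
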