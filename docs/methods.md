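# Methods

## Model

`phenosim` generates an N × P phenotype matrix as the sum of five additive
components, each optionally split into a trait-shared and a trait-independent
part and each rescaled to a prescribed share of total phenotypic variance.
The underlying assumption — phenotypes as an additive linear combination of
genetic fixed effects, a kinship-structured random effect, covariate fixed
effects and noise — is exactly the generative model of the standard linear
mixed model used in genetic association studies, which makes the simulator a
natural benchmark source for LMM-family methods (and, by the same token,
biased in their favour when comparing against non-LMM methods).

### Genotypes and kinship

Simulated genotypes are unlinked biallelic SNPs: the dosage of sample i at
SNP j is `Binomial(2, f_j)`, with per-SNP allele frequencies either given or
drawn uniformly from a range (default 0.05–0.5, a typical common-variant
spectrum). Columns are independent, so there is **no linkage
disequilibrium**; realistic LD requires importing panels from an external
simulator (coalescent, forward-time or resampling-based), which the import
readers support.

Kinship is `K = X Xᵀ / m`, `m = mean(diag(X Xᵀ))`, so `mean(diag K) = 1` by
construction. By default X is column-centered and unit-scaled first (the
usual GRM estimator); since the raw-dosage variant is equally defensible, a
`standardize=False` mode keeps X as-is, and the 1/m normalization applies in
both so the diagonal invariant always holds. Zero-variance SNPs are dropped
(with a logged count) before standardization and kept in raw mode.

### Shared and independent effect designs

Shared effect-size matrices are outer products `B = b_s b_pᵀ` (rank one), so
every trait column is a scalar multiple of the same predictor loading
vector: pairwise trait correlations within the component are exactly ±1.
Under the normal law, `b_s ~ N(μ, σ²)` (user-set) and `b_p ~ N(0, 1)`.

Under the uniform law the generator vectors are transformed exponentials:
each entry of `b_s` and `b_p` is `exp(-g)` with `g ~ Gamma(1/2, 1)`. The
negative log of any product `b_s[i] b_p[j]` is then the sum of two
independent Gamma(1/2, 1) variables, i.e. Exp(1), so the product itself is
**exactly** Uniform(0, 1); an affine map puts it on the requested
`[low, high]`. This was a genuinely open design point: a batchwise min–max
normalization of `-log(e₁e₂)` with `e ~ Exp(1)` was considered and rejected
because it is undefined for single-entry batches and its min–max-normalized
logistic-like distribution is far from uniform. The chosen construction is
exact, seedable and batch-size independent. One consequence: the affine
offset makes the uniform-law shared matrix rank 2 rather than rank 1 when
`low ≠ 0`; the substantive guarantee — perfectly correlated trait columns —
is unchanged and is what the tests assert.

Independent effect matrices are filled iid from the chosen law and then
`P − P_ind` randomly selected traits have their columns zeroed. One trait
subset is drawn per matrix (all predictor rows share it); a per-row masking
mode exists behind the `per_row` flag for architectures where each predictor
hits its own trait subset.

### Infinitesimal effects and the Kronecker identity

The polygenic background is `vec(U) ~ N(0, C ⊗ K)`, sampled as
`U = B Z Aᵀ` with `K = B Bᵀ`, `C = A Aᵀ` and `Z` iid N(0, 1), since
`cov(vec(B Z Aᵀ)) = (A A ᵀ) ⊗ (B Bᵀ)`. The kinship factor uses a symmetric
eigendecomposition, not Cholesky, so rank-deficient K is supported:
eigenvalues below `max(λ)·1e-12` are treated as zero and dropped (factor
width M = numerical rank), and an eigenvalue below −1e-8 raises, reporting
the value. A has L = P columns; the shared design fills only column one
(column rank one → trait correlations ±1), the independent design is
diagonal. The Kronecker identity is verified in the suite by a Monte-Carlo
oracle (150 000 replicates at N = 3, P = 2; the empirical covariance of
vec(U) must match C ⊗ K within 5% relative error on entries above 0.05 —
at that replicate count the Monte-Carlo standard error on the smallest
checked entry is ≈0.7% relative, so the band is several standard errors
wide).

### Correlated effects and observational noise

The correlated non-genetic effect has rows iid `N(0, C)`; C is either
user-supplied (validated symmetric within 1e-8 and PSD within
`-1e-8·max(λ)`, small negative eigenvalues clipped with a warning) or the
exponential-decay family `C_ij = r^|i−j|`, positive definite for |r| < 1.
Observational noise is `Ψ = B A` with `B` an N × P standard normal matrix;
shared design: A with one normal row (perfect trait correlation);
independent design: diagonal A.

### Scaling and assembly

A component with average column variance `V̄` (sample variance, n−1
denominator, mean over traits) targeted at share `x` is multiplied by
`sqrt(a)` with `a = x / V̄`. The factor is a **variance** scale: multiplying
entries by `a` itself would yield variance `a²V̄` and miss the stated goal,
so the entry-level multiplier is its square root. Components are not
re-centered: variance, not the second moment, is scaled, and covariate
components keep their means. Split components receive sub-budgets `x·s` and
`x·(1−s)` from the component total `x` and shared fraction `s`; structurally
empty parts (θ = 1, γ = 1, ...) are explicit zero matrices with sub-budget
zero, so assembly is uniform. The budget must sum to 1 within 1e-6 — there
is deliberately no silent renormalization, because a budget that does not
sum to 1 is almost always a configuration mistake.

Consequences: every component's realized mean column variance equals its
budget entry to ~1e-10 and the realized shares sum to 1 exactly, but the
total empirical variance of Y equals 1 only in expectation — independently
simulated components have O(1/√N) sample cross-covariances that
per-component scaling cannot remove (at N = 200 the realized total is
typically within a few percent of 1).

## Randomness and determinism

Every public operation accepts an integer seed or `numpy.random.Generator`.
The pipeline derives one child stream per stage from a single
`SeedSequence`, in a fixed order independent of which components are
enabled, so runs are bitwise reproducible and adding a component does not
perturb the others' draws. Output files use fixed-notation floats (default
6 decimals, '.' separator, fixed column order), making bundles
byte-identical across runs and platforms.

## The packaged case study

`phenosim.casestudy` fixes a desk-scale reference simulation: N = 200,
a 100-SNP panel, P = 3 traits, 10 causal SNPs with shared-only effects
(θ = 1), four covariates, infinitesimal, correlated and observational
noise; total genetic variance 40%, and 80% shared within each split
component. Several of its parameters are this package's own defaults where
only the headline structure is externally fixed: the 40% genetic budget is
split 20% variant / 20% infinitesimal (an even split, absent a stated one);
the 60% non-genetic budget is 20% covariates, 10% correlated, 30%
observational noise; the covariates are two Bernoulli (p = 0.5, 0.3, e.g.
sex and a binary exposure) and two standard normals with γ = 0.5; the
correlated effect uses r = 0.7. Analyses built on this configuration should
rely on the 40/60 genetic/non-genetic split and the 80/20 shared split —
those are exact by construction of the scaling — not on the internal
sub-splits, which are conventions.

Problem sizes throughout the test suite (N up to 50 000 for distributional
checks, 150 000 replicates for the Kronecker oracle, N = 200 for pipeline
runs) keep the full suite in the low minutes on one core while leaving
Monte-Carlo bands several standard errors wide.

## What the simulated data does and does not show

The generator reproduces the *covariance structure* assumed by LMMs:
additive effects, separable trait/sample covariance, Gaussian noise. It does
not simulate LD (unless imported), epistasis or gene–environment
interaction, dominance (dosages are additive), selection, or non-Gaussian
trait distributions. Passing benchmarks on these phenotypes therefore shows
a method handles the canonical additive multi-trait model — it does not
certify performance on real data where those excluded features are present.

## Numerical and interface choices

* Counts from fractions (`θ·S`, `γ·K`) use round-half-away-from-zero, so
  subset sizes are platform-stable.
* Categorical covariates enter the effect product as integer level codes
  0..L−1 (a single column of W); one-hot encoding is a possible alternative
  but is not the default since a single covariate column matches the model.
* PLINK text is written with effect allele 'A' / other allele 'B'; the
  reader counts a configurable effect allele. Missing genotype codes are
  never written; on import they are an error unless mean-imputation is
  explicitly requested.
* Genotype probability triples (Oxford .gen) collapse to expected dosage
  `p(AB) + 2·p(BB)` on import; continuous dosages are encoded as
  `(1 − d/2, 0, d/2)` on export so round trips are exact.
* The kinship eigenvalue tolerance (−1e-8), the PSD clip for user C, and
  the 1e-10 scaling-exactness bound are absolute tolerances on matrices
  normalized to unit mean diagonal / unit target variance.

## Limitations

Besides the modelling exclusions above: the binomial genotype simulator
draws SNPs independently, so kinship estimated from small simulated panels
reflects only sampling noise, not population structure — structured K must
be imported or estimated from imported genotypes; binary PLINK (.bed) is not
written (text formats only); and the simulator provides no association
testing of its own — outputs are formatted for PLINK, GEMMA, BIMBAM and
SNPTEST to do that downstream.
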