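# Methods

## The problem

A genome-wide association scan tests m markers against one phenotype, and
the per-marker significance threshold u must be chosen so that the
family-wise error rate — the probability that the *minimum* p-value across
all m correlated tests falls below u under the global null — equals a target
level α.  The permutation test is the classical answer, but it is invalid
when the scan is performed with a linear mixed model (LMM): shuffling the
phenotype destroys the phenotype–kinship dependence that the LMM explicitly
models, so statistics computed on permuted data are not draws from the null.

This package estimates LMM-aware thresholds by sampling vectors of null
association statistics directly from a multivariate normal (MVN), and
validates them against a parametric-bootstrap gold standard.

## Model

The phenotype model is

    y = μ1 + x_i β_i + g + e,   g ~ N(0, σg² K),   e ~ N(0, σe² I),

with K the n×n genetic relatedness matrix (here the standardized-genotype
cross-product X Xᵀ/m) and heritability h² = σg²/(σg²+σe²).  Writing
V = σg² K + σe² I, the whitened scan statistic for marker i is the z-score
of the regression of V^{-1/2} y on V^{-1/2} x_i after both are centered
(which absorbs the intercept).  Under the null the vector (S₁,…,S_m) is
asymptotically MVN with unit margins and

    Cov(S_i, S_j) = Cor(V^{-1/2} x_i, V^{-1/2} x_j) ≡ r^M_ij,

the Pearson correlation of the *transformed* genotypes.  At σg² = 0 this
reduces to the plain genotype correlation r_ij, the covariance valid under
the ordinary linear model.  The threshold search is therefore: build the
correlation matrix of transformed genotypes, sample many statistic vectors
from MVN(0, Σ^M), record each replicate's minimum pointwise p-value, and
return the empirical α-quantile.

## Sliding-window sampling

Genome-scale m makes dense Cholesky sampling infeasible, but after
structure correction statistic correlations are local (linkage
disequilibrium has finite range), so S_i is taken to be conditionally
independent of everything more than w markers back given its w
predecessors.  The chain-rule factorization
f(S₁)f(S₂|S₁)…f(S_m|S_{m-w}…S_{m-1}) then lets all replicates advance one
marker at a time: each step solves the w×w within-window correlation block
for the conditional mean coefficients and draws from
N(cᵀs_prev, 1 − cᵀρ).  Only within-window, within-chromosome correlations
are stored (an m×w band); cross-chromosome and beyond-window correlations
are set to zero, which ignores residual long-range dependence and is
therefore conservative (it can only overstate the effective number of
tests).  The per-marker block is refactorized in full (O(w³) per marker,
the method's published complexity); at the window sizes this package
targets (w ≤ 1000) a per-step incremental factor update was not worth the
extra machinery.

Two numerical points matter here:

- **Rank deficiency.** Whenever w ≥ n the window correlation blocks are
  exactly singular (the transformed genotypes live in an (n−1)-dimensional
  space).  The conditional solve is therefore always ridge-regularized
  (escalating 1e-8 → 1e-4); the ridge only *increases* the conditional
  variance estimate, i.e. it is conservative.  An unregularized Cholesky of
  a singular block can succeed numerically with meaningless pivots and
  produce explosive coefficients — this failure mode is guarded against
  and covered by the exact-sampler equivalence tests.
- **Perfectly predicted markers** (duplicates) get their conditional
  variance floored at 1e-8; the floored draw is valid and slightly
  conservative.

A dense-Cholesky sampler over the full Σ (m ≤ 5000) serves as the exact
oracle in the test suite.

## Statistic margins

Different pipeline branches produce statistics with slightly different
finite-sample null margins, and each is converted to p-values under its own
exact margin so that thresholds are always compared on the p-value scale
(where every variant is per-marker uniform):

- MVN samples: standard normal margins by construction.
- Fixed-V bootstrap: the whitened null phenotype is exactly a standard
  normal vector, so the score statistic (model variance treated as known)
  is exactly N(0,1) — normal margins.
- Studentized statistics (full bootstrap with per-replicate refit, the
  observed-data scan, refit permutation): S = √n·corr(x̃, ỹ) has the
  sample-correlation margin, mapped through t = r√(n−2)/√(1−r²) to a
  t_{n−2} reference.  At n = 100 the normal/t distinction shifts
  far-tail thresholds by ~30 %, so it cannot be ignored.

The user-facing `association_scan` reports conventional normal-margin
z-score p-values; the small-n discrepancy against t-based tools is the
price of consistency with the MVN machinery and is documented here.

## Parametric bootstrap and permutation

The gold standard draws null phenotypes y* ~ N(0, V̂) and rescans.  In
`fixedV` mode V̂ is reused (the fast path; equivalent to scoring the
transformed genotypes against white noise).  In `full` mode the variance
components are refit per replicate; everything runs in K's eigenbasis, so
a replicate costs O(nm) rather than O(n³), and centering is carried out by
projecting against Uᵀ1.  Checkpointing was considered and dropped — at
these costs a full-mode run of 10³ replicates finishes in seconds.

`permutation_test` exists to demonstrate the method's motivation and has
two variants.  With `refit=False` the covariance fitted to the *observed*
structured phenotype is applied to the shuffled data exactly as the model
prescribes: the shuffle has destroyed the structure the transform assumes,
the whitened phenotype no longer has unit variance in the model's
eigendirections, and pooled p-values are inflated.  With `refit=True` the
whole pipeline is rerun per permutation; REML on shuffled data typically
rediscovers h² ≈ 0 and the studentized statistic self-calibrates (measured
fraction of p < 0.05 between 0.042 and 0.049 across many structured
configurations) — a misleading kind of robustness, since the refit variant
is also the expensive one nobody runs at GWAS scale.  The calibration
comparison in the acceptance suite therefore uses the fixed-model variant
as the naive-permutation failure case, with the refit variant's
self-calibration asserted separately.

## Variance-component fitting

One eigendecomposition of K, then the profiled (restricted) likelihood is
maximized over δ = σe²/σg² on a 100-point log₁₀δ grid over [−10, 10]
refined by bounded Brent search to 1e-6; each objective evaluation is
O(n).  REML (one intercept fixed effect) is the default; ML is available.
One subtlety: K built from column-standardized genotypes satisfies K1 = 0
exactly, so the intercept direction carries zero genetic variance and the
*full* ML likelihood is unbounded (μ̂ fits that coordinate perfectly while
its residual variance → 0).  The ML objective therefore marginalizes the
intercept-aligned null direction out, which is exact and restores a
well-posed optimum.  Boundary optima are reported with a warning and
heritability clipped to [0, 1].

## Synthetic data

Real panels are not bundled; the generator supplies the two features the
method exercises — structure (K far from I) and local LD (non-trivial
Σ^M) — with two knobs:

- **Balding–Nichols divergence**: ancestral frequency p₀ ~ U(maf_range),
  per-population frequency ~ Beta(p₀(1−F)/F, (1−p₀)(1−F)/F) with F = fst
  (populations assigned round-robin; F = 0 shares p₀).
- **Markov haplotype copying**: within a haplotype, each marker copies its
  left neighbour's allele with probability ld_rho, else draws fresh from
  the population frequency, giving geometric LD decay with range
  ≈ 1/(1−ld_rho) markers.

Phenotypes are y = g + e with g ~ N(0, h²K), e ~ N(0, (1−h²)I); h² is the
population parameter, and realized sample variance is not renormalized.
Defaults (n = 100, m = 1000, 2 populations, fst = 0.2, ld_rho = 0.8,
MAF ∈ [0.1, 0.5], one chromosome) describe a small structured model-
organism panel.  What the generator does **not** emulate: allele-frequency
spectra of real ascertainment, recombination-map heterogeneity, long-range
admixture LD, non-Gaussian phenotypes, missingness patterns.  Passing
tests therefore certify the *machinery* (covariance construction, sampling
law, threshold estimation), not robustness to every property of real data
— in particular the permutation-test behaviour on a real skewed phenotype
can be worse than on Gaussian synthetics.

## Study conditions used by the acceptance checks

Calibration and threshold-grid experiments use the variance components at
their generating values (σg² = h², σe² = 1−h²) so the heritability grid
{0, 0.2, 0.5, 0.8} is exactly the quantity varied; end-to-end comparisons
(MVN vs bootstrap) fit the components from a simulated phenotype first.
The structured reference panel is n = 100, m = 500–1000, fst = 0.2–0.3,
ld_rho = 0.8 with kinship from all panel markers; the weak-relatedness
contrast panel is fst = 0.02, ld_rho = 0.2, m = 1000, chosen so that the
effective number of independent markers far exceeds n and K's bulk
spectrum concentrates near identity (with ld_rho = 0.8 and m = 500 the
effective marker count drops below n and K is noise-dominated, which makes
the transform active even without structure — that panel would not be a
near-identity control).  Sampler runs use 10⁵ replicates and window 100;
Monte-Carlo standard errors are reported with every threshold so method
differences can be judged against sampling noise.

## Known limitations

- Intercept-only fixed effects; no covariates, no multiple variance
  components, no per-marker exact REML refitting.
- Quantitative phenotypes only; binary-trait extensions are out of scope.
- The banded covariance never stores the full Σ^M; analyses needing dense
  Σ^M (m > 5000) are unsupported by design.
- Thresholds inherit Monte-Carlo error ∝ 1/√s at fixed α; the default CLI
  s = 10⁶ targets ~2 significant figures at α = 0.05 for genome-scale m.
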