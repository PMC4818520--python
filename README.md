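# multitrans

Multiple-testing correction for genome-wide association studies performed
with **linear mixed models** (LMMs).

## Why

A GWAS tests m markers against one phenotype, and the per-marker p-value
threshold u must satisfy P(min_i p_i ≤ u | null) = α, the family-wise
error rate.  The permutation test — the classical way to estimate u while
respecting linkage disequilibrium — is **invalid under an LMM**: shuffling
the phenotype destroys the phenotype–relatedness covariance that the model
explicitly fits, so permuted statistics are not null draws.  This package
provides:

- **MVN statistic sampling** (the main method): under the LMM
  y = μ1 + x_i β_i + g + e, g ~ N(0, σg²K), e ~ N(0, σe²I), the vector of
  null z-scores is asymptotically MVN with covariance
  Cov(S_i, S_j) = Cor(V̂^{-1/2}x_i, V̂^{-1/2}x_j), the correlation of
  genotypes whitened by V̂ = σ̂g²K + σ̂e²I.  Sampling statistic vectors from
  this MVN — via a sliding-window conditional Gaussian chain whose cost is
  independent of the cohort size n — and taking the empirical α-quantile
  of the per-replicate minimum p-value yields the threshold.
- **Parametric bootstrap** (the gold standard): draw null phenotypes from
  N(0, V̂) and rescan; slow but exact, used for validation.
- **Permutation test** (the negative control): demonstrates the inflation
  that motivates all of the above.
- **Synthetic panels**: Balding–Nichols population structure plus
  first-order Markov haplotype LD, so the entire pipeline is testable
  without any external downloads.

The scientific account of the model, margins, numerical choices and
limitations is in [docs/methods.md](docs/methods.md).

## Worked example

Simulate a structured panel, then run the whole pipeline (QC filter →
standardize → kinship → REML fit → genotype whitening → banded correlation
→ MVN sampling → threshold):

```python
import multitrans as mt
from multitrans.cli import run_multitrans

cfg = mt.SynthConfig(n_individuals=100, n_markers=1000,
                     fst=0.2, ld_rho=0.8, seed=4)
study = mt.make_study(cfg, h2=0.5)
mt.write_genotypes(study.genotypes_raw, "panel.geno.txt")
mt.write_phenotype(study.phenotype, "panel.pheno.txt")

res = run_multitrans("panel.geno.txt", "panel.pheno.txt",
                     window=100, n_samples=100_000, alpha=0.05, seed=1)
print(res)
```

prints (exactly, for these seeds):

```
{'alpha': 0.05, 'per_marker_threshold': 6.344511356175482e-05,
 'mc_se': 1.0273123613511898e-06, 'heritability': 0.34593095203256796,
 'sigma_g2': 0.31361528688648227, 'sigma_e2': 0.5929681947123447,
 'n': 100, 'm': 1000, 'window': 100, 'n_samples': 100000, 'seed': 1}
```

Reading it: the REML fit attributes ĥ² ≈ 0.35 of the phenotypic variance
to the kinship (a single n=100 draw of a true-h²=0.5 phenotype), and the
per-marker threshold at α = 0.05 is **6.34e-5 ± 0.10e-5** (Monte-Carlo
standard error from 10⁵ sampled statistic vectors).  Compare the
independence-based references `mt.bonferroni(0.05, 1000) = 5.00e-5` and
`mt.sidak(0.05, 1000) = 5.13e-5`: local LD among the 1000 markers makes
the effective number of tests smaller, so the correct threshold is less
stringent than Bonferroni; and because this panel is structured, the
threshold also *decreases* as the heritability of the analyzed trait
increases (whitening by V̂^{-1/2} removes more of the inter-marker
correlation).

The same pipeline is available from the shell:

```
multitrans run --geno panel.geno.txt --pheno panel.pheno.txt \
    --window 100 --n-samples 100000 --seed 1 --out-dir out/
```

with stage-level subcommands (`simulate`, `kinship`, `fit`, `transform`,
`sample`, `threshold`, `bootstrap`, `permute`) for partial runs; every
command writes a JSON manifest with parameters, seeds and input checksums.

## Validating against the gold standard

```python
vc = mt.fit_variance_components(study.phenotype, study.kinship)
boot = mt.parametric_bootstrap(study.genotypes, study.kinship, vc,
                               n_reps=10_000, seed=3)
t_boot = mt.per_marker_threshold(boot.null_distribution(), 0.05)
```

On this panel the bootstrap threshold agrees with the MVN-sampler
threshold to within a few percent (about one combined Monte-Carlo standard
error) while requiring a full rescan per replicate; the sampler needs
neither phenotypes nor the cohort once the banded correlation is built.

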