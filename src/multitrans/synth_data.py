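"""Synthetic genotype panels with population structure and local LD.

Genotypes follow a Balding-Nichols scheme: each marker has an ancestral
allele frequency drawn uniformly from ``maf_range``; each population draws
its own frequency from Beta(p0 (1-F)/F, (1-p0)(1-F)/F) with F the
divergence parameter, so populations drift apart as F grows.  Within an
individual, adjacent markers on a chromosome share haplotype state with
probability ``ld_rho`` (first-order Markov copying), giving geometric LD
decay.  Dosages are the sum of two haplotypes, in {0, 1, 2}.

Phenotypes are y = g + e with g ~ N(0, h2 K) and e ~ N(0, (1-h2) I); h2 is
the population heritability parameter, not a per-sample constraint, so the
realized sample variance fluctuates around h2 * mean(diag K) + (1 - h2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .genotype_io import GenotypeMatrix, PhenotypeVector, filter_markers, standardize
from .kinship import KinshipMatrix, compute_kinship

_FREQ_CLIP = (0.005, 0.995)


@dataclass
class SynthConfig:
    n_individuals: int = 100
    n_markers: int = 1000
    n_populations: int = 2
    fst: float = 0.2
    ld_rho: float = 0.8
    maf_range: tuple[float, float] = (0.1, 0.5)
    chromosomes: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals < 2 or self.n_markers < 1:
            raise ValidationError("need n_individuals >= 2 and n_markers >= 1")
        if self.n_populations < 1:
            raise ValidationError("n_populations must be >= 1")
        if not 0 <= self.fst < 1:
            raise ValidationError("fst must be in [0, 1)")
        if not 0 <= self.ld_rho < 1:
            raise ValidationError("ld_rho must be in [0, 1)")
        lo, hi = self.maf_range
        if not 0 < lo <= hi <= 0.5:
            raise ValidationError("maf_range must satisfy 0 < low <= high <= 0.5")
        if self.chromosomes < 1:
            raise ValidationError("chromosomes must be >= 1")


def population_labels(cfg: SynthConfig) -> np.ndarray:
    """Round-robin population assignment for each individual."""
    return np.arange(cfg.n_individuals) % cfg.n_populations


def simulate_genotypes(cfg: SynthConfig) -> GenotypeMatrix:
    """Draw a raw structured genotype panel (deterministic given the config)."""
    rng = np.random.default_rng(cfg.seed)
    pops = population_labels(cfg)
    n, P = cfg.n_individuals, cfg.n_populations
    per_chrom = np.full(cfg.chromosomes, cfg.n_markers // cfg.chromosomes)
    per_chrom[: cfg.n_markers % cfg.chromosomes] += 1
    dosage_blocks, mids, chroms, poss = [], [], [], []
    lo, hi = cfg.maf_range
    for c, L in enumerate(per_chrom):
        if L == 0:
            continue
        p0 = rng.uniform(lo, hi, size=L)
        if cfg.fst == 0:
            pop_freq = np.tile(p0, (P, 1))
        else:
            ratio = (1.0 - cfg.fst) / cfg.fst
            pop_freq = rng.beta(p0 * ratio, (1.0 - p0) * ratio, size=(P, L))
            pop_freq = np.clip(pop_freq, *_FREQ_CLIP)
        pf = pop_freq[pops]  # (n, L)
        hap = rng.random((n, 2, L)) < pf[:, None, :]
        if cfg.ld_rho > 0 and L > 1:
            copy = rng.random((n, 2, L - 1)) < cfg.ld_rho
            for j in range(1, L):
                hap[:, :, j] = np.where(copy[:, :, j - 1], hap[:, :, j - 1], hap[:, :, j])
        dosage_blocks.append(hap.sum(axis=1).astype(float))
        mids.extend(f"c{c + 1}m{j + 1}" for j in range(L))
        chroms.extend([str(c + 1)] * L)
        poss.extend(((np.arange(L) + 1) * 1000).tolist())
    dosages = np.concatenate(dosage_blocks, axis=1)
    ind_ids = [f"ind{i:04d}" for i in range(n)]
    return GenotypeMatrix(dosages, mids, chroms, poss, ind_ids)


def simulate_phenotype(k: KinshipMatrix, h2: float, seed: int) -> PhenotypeVector:
    """y = g + e with g ~ N(0, h2 K), e ~ N(0, (1 - h2) I)."""
    if not 0 <= h2 <= 1:
        raise ValidationError("heritability must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    lam, U = np.linalg.eigh(k.values)
    lam = np.clip(lam, 0.0, None)
    g = U @ (np.sqrt(h2 * lam) * rng.standard_normal(k.n))
    e = np.sqrt(1.0 - h2) * rng.standard_normal(k.n)
    return PhenotypeVector(g + e, k.individual_ids)


@dataclass
class SimulatedStudy:
    """A ready-to-analyze bundle: panel, kinship from all markers, phenotype."""

    genotypes_raw: GenotypeMatrix
    genotypes: GenotypeMatrix  # filtered + standardized
    kinship: KinshipMatrix
    phenotype: PhenotypeVector
    true_h2: float
    config: SynthConfig = field(repr=False, default=None)  # type: ignore[assignment]


def make_study(
    cfg: SynthConfig,
    h2: float,
    phenotype_seed: int | None = None,
    maf_min: float = 0.05,
    missing_max: float = 0.10,
) -> SimulatedStudy:
    """Simulate, QC-filter, standardize, estimate kinship, draw a phenotype."""
    raw = simulate_genotypes(cfg)
    std = standardize(filter_markers(raw, maf_min, missing_max))
    K = compute_kinship(std)
    seed = cfg.seed + 7919 if phenotype_seed is None else phenotype_seed
    y = simulate_phenotype(K, h2, seed)
    return SimulatedStudy(raw, std, K, y, h2, cfg)
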