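"""Resampling references: parametric bootstrap (gold standard) and permutation.

The parametric bootstrap samples null phenotype vectors y* ~ N(0, V-hat) and
recomputes the mixed-model association statistics for each; its min-p
distribution defines the reference threshold.  In ``fixedV`` mode the fitted
covariance is reused across replicates, which collapses to scoring the
transformed genotypes against standard-normal vectors (V^{-1/2} y* = z); in
``full`` mode the variance components are refit per replicate, the faithful
but slow gold standard.

Each statistic is converted to a p-value under its own exact null margin:
fixedV score statistics are exactly N(0, 1) under the model (normal
margins), while studentized statistics follow the sample-correlation law
(t margins).  On the p-value scale every variant is per-marker uniform, so
min-p thresholds from different variants are directly comparable.

The permutation test is the negative control: shuffling the phenotype
destroys its dependence on the relatedness structure that the mixed model
assumes, so under genetic structure the permuted statistics are spurious
(see :func:`permutation_test` for the two variants).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm, t as student_t

from .errors import ValidationError
from .genotype_io import GenotypeMatrix, PhenotypeVector
from .kinship import KinshipMatrix
from .lmm_core import (
    VarianceComponents,
    build_covariance_model,
    eigendecompose,
    fit_rotated,
)
from .mvn_sampler import NullMinPDistribution
from .transform_cov import transform_genotypes

logger = logging.getLogger(__name__)

_FULL_MODE_MAX_COST = 5e10  # ~ n_reps * n * m floating-point budget


@dataclass
class ResamplingRun:
    """Min-p values (and optionally pooled per-marker p-values) from resampling."""

    provenance: str
    n_reps: int
    seed: int
    min_p: np.ndarray
    m: int
    pooled_pvalues: np.ndarray | None = None

    def null_distribution(self) -> NullMinPDistribution:
        return NullMinPDistribution(self.min_p, self.m, self.provenance)


def _corr_margin_pvalues(stats: np.ndarray, n: int) -> np.ndarray:
    """Exact finite-sample p-values for the z-score S = sqrt(n) * corr(x, y).

    The resampled statistic studentizes by the realized phenotype norm, so
    its null margin is the sample-correlation law (|r| <= 1), equivalently a
    t_{n-2} margin through the monotone map t = r sqrt(n-2) / sqrt(1-r^2).
    Thresholds are compared on the p-value scale, where this margin and the
    MVN sampler's normal margin are both uniform per marker.
    """
    r = np.clip(np.abs(stats) / np.sqrt(n), 0.0, 1.0 - 1e-15)
    tval = r * np.sqrt((n - 2) / (1.0 - r * r))
    return np.clip(2.0 * student_t.sf(tval, n - 2), np.finfo(float).tiny, 1.0)


def _rotated_stats(dstar, xrot, yrot, u1, n):
    """Association z-scores computed entirely in K's eigenbasis.

    Centering in the original basis is projection against u1 = U^T 1; all
    inner products are invariant under the rotation, so the n x n inverse
    square root never needs to be formed.
    """
    ty = dstar * yrot
    ty = ty - u1 * (u1 @ ty) / n
    sd = np.linalg.norm(ty) / np.sqrt(n)
    ty = ty / sd
    tx = dstar[:, None] * xrot
    tx = tx - u1[:, None] * (u1 @ tx)[None, :] / n
    ss = np.einsum("ij,ij->j", tx, tx)
    return (tx.T @ ty) / np.sqrt(ss)


def _rotated_score_stats(dstar, xrot, yrot, u1, n):
    """Score z-statistics with the whitened phenotype variance taken as known.

    Same whitening and centering as :func:`_rotated_stats` but without the
    per-replicate studentization -- the fitted model asserts the whitened
    phenotype has unit variance, so the statistic is referred to N(0, 1).
    """
    ty = dstar * yrot
    ty = ty - u1 * (u1 @ ty) / n
    tx = dstar[:, None] * xrot
    tx = tx - u1[:, None] * (u1 @ tx)[None, :] / n
    ss = np.einsum("ij,ij->j", tx, tx)
    return (tx.T @ ty) / np.sqrt(ss)


def parametric_bootstrap(
    g: GenotypeMatrix,
    k: KinshipMatrix,
    vc: VarianceComponents,
    n_reps: int,
    seed: int,
    mode: str = "fixedV",
    collect_pvalues: bool = False,
    eig: tuple[np.ndarray, np.ndarray] | None = None,
    max_cost: float = _FULL_MODE_MAX_COST,
) -> ResamplingRun:
    """Parametric bootstrap of the null min-p distribution.

    ``fixedV`` reuses V-hat for every replicate (fast path); ``full`` refits
    the variance components per replicate and re-whitens the genotypes with
    the refitted covariance.
    """
    if not g.standardized:
        raise ValidationError("parametric_bootstrap requires standardized genotypes")
    if mode not in ("fixedV", "full"):
        raise ValidationError(f"mode must be 'fixedV' or 'full', got {mode!r}")
    if n_reps < 1:
        raise ValidationError("n_reps must be >= 1")
    n, m = g.n, g.m
    rng = np.random.default_rng(seed)
    if mode == "fixedV":
        model = build_covariance_model(k, vc, eig=eig)
        T = transform_genotypes(g, model).matrix
        chunk = int(min(n_reps, max(64, 2.5e7 // max(m, 1))))
        min_p = np.empty(n_reps)
        pooled = np.empty((n_reps, m)) if collect_pvalues else None
        for lo in range(0, n_reps, chunk):
            cs = min(chunk, n_reps - lo)
            Z = rng.standard_normal((cs, n))
            # T's columns are centered, so the intercept projection of z is
            # implicit and each score statistic is exactly N(0, 1)
            stats = Z @ T / np.sqrt(n)
            p = np.clip(2.0 * norm.sf(np.abs(stats)), np.finfo(float).tiny, 1.0)
            min_p[lo : lo + cs] = p.min(axis=1)
            if pooled is not None:
                pooled[lo : lo + cs] = p
        return ResamplingRun(
            "bootstrap-fixedV", n_reps, seed, min_p, m,
            pooled.ravel() if pooled is not None else None,
        )

    # full mode: refit variance components for every replicate
    cost = float(n_reps) * n * (n + m)
    if cost > max_cost:
        raise ValidationError(
            f"full-mode bootstrap cost ~{cost:.1e} flops exceeds budget {max_cost:.1e}; "
            "reduce n_reps or use mode='fixedV'"
        )
    lam, U = eig if eig is not None else eigendecompose(k)
    u1 = U.T @ np.ones(n)
    xrot = U.T @ g.dosages
    w0 = np.sqrt(vc.sigma_g2 * lam + vc.sigma_e2)
    min_p = np.empty(n_reps)
    pooled = np.empty((n_reps, m)) if collect_pvalues else None
    report_every = max(1, n_reps // 10)
    for r in range(n_reps):
        yrot = w0 * rng.standard_normal(n)  # y* ~ N(0, V) in the eigenbasis
        with warnings.catch_warnings():
            # boundary heritability estimates are routine across replicates
            warnings.simplefilter("ignore", UserWarning)
            vc_star = fit_rotated(
                yrot, u1, lam,
                method=vc.method if vc.method in ("REML", "ML") else "REML",
            )
        dstar = 1.0 / np.sqrt(vc_star.sigma_g2 * lam + vc_star.sigma_e2)
        stats = _rotated_stats(dstar, xrot, yrot, u1, n)
        p = _corr_margin_pvalues(stats, n)
        min_p[r] = p.min()
        if pooled is not None:
            pooled[r] = p
        if (r + 1) % report_every == 0:
            logger.info("full bootstrap: %d / %d replicates", r + 1, n_reps)
    return ResamplingRun(
        "bootstrap-full", n_reps, seed, min_p, m,
        pooled.ravel() if pooled is not None else None,
    )


def permutation_test(
    g: GenotypeMatrix,
    k: KinshipMatrix,
    y: PhenotypeVector,
    n_perm: int,
    seed: int,
    refit: bool = True,
    eig: tuple[np.ndarray, np.ndarray] | None = None,
) -> ResamplingRun:
    """Naive phenotype permutation under the mixed model (negative control).

    Each permutation shuffles y uniformly without replacement.  With
    ``refit=True`` the full pipeline is rerun per permutation: variance
    components refit and the statistic studentized by the realized phenotype
    norm (exact correlation margins).  With ``refit=False`` the covariance
    fitted to the *observed* phenotype is applied to the permuted data as
    the model prescribes -- score statistics with the whitened variance
    treated as known, normal margins.  The shuffle destroys the phenotype's
    dependence on the relatedness structure while the fixed transform still
    assumes it, so under genetic structure the ``refit=False`` p-values come
    out inflated; per-permutation refit instead rediscovers h2 ~ 0 on the
    shuffled data and largely (and misleadingly) self-calibrates.  Pooled
    p-values are always collected, since calibration is what this test is
    for.
    """
    if not g.standardized:
        raise ValidationError("permutation_test requires standardized genotypes")
    if n_perm < 100:
        raise ValidationError("n_perm must be >= 100")
    n, m = g.n, g.m
    lam, U = eig if eig is not None else eigendecompose(k)
    u1 = U.T @ np.ones(n)
    xrot = U.T @ g.dosages
    rng = np.random.default_rng(seed)
    if not refit:
        vc0 = fit_rotated(U.T @ y.values, u1, lam)
        dfix = 1.0 / np.sqrt(vc0.sigma_g2 * lam + vc0.sigma_e2)
    min_p = np.empty(n_perm)
    pooled = np.empty((n_perm, m))
    for r in range(n_perm):
        yp = rng.permutation(y.values)
        yrot = U.T @ yp
        if refit:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", UserWarning)
                vc_star = fit_rotated(yrot, u1, lam)
            dstar = 1.0 / np.sqrt(vc_star.sigma_g2 * lam + vc_star.sigma_e2)
            stats = _rotated_stats(dstar, xrot, yrot, u1, n)
            p = _corr_margin_pvalues(stats, n)
        else:
            stats = _rotated_score_stats(dfix, xrot, yrot, u1, n)
            p = np.clip(2.0 * norm.sf(np.abs(stats)), np.finfo(float).tiny, 1.0)
        min_p[r] = p.min()
        pooled[r] = p
    return ResamplingRun("permutation", n_perm, seed, min_p, m, pooled.ravel())


@dataclass
class QQReport:
    """Observed vs expected -log10 p quantiles (uniform plotting positions)."""

    expected: np.ndarray
    observed: np.ndarray


def qq_report(pvals: np.ndarray) -> QQReport:
    """Sorted -log10(p) against -log10((k - 0.5) / N)."""
    p = np.asarray(pvals, dtype=float).ravel()
    if p.size == 0:
        raise ValidationError("empty p-value array")
    if p.min() <= 0 or p.max() > 1:
        raise ValidationError("p-values must lie in (0, 1]")
    srt = np.sort(p)
    N = len(srt)
    expected = -np.log10((np.arange(1, N + 1) - 0.5) / N)[::-1]
    observed = -np.log10(srt)[::-1]
    return QQReport(expected=expected, observed=observed)
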