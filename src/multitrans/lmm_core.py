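"""Linear mixed model core: variance components, V^{-1/2}, association scan.

The phenotype model is y ~ N(mu 1, sigma_g^2 K + sigma_e^2 I).  Variance
components are fit by profiling the (restricted) likelihood over the ratio
delta = sigma_e^2 / sigma_g^2 after a single eigendecomposition of K, the
EMMA-style spectral trick: with K = U L U^T every objective evaluation is
O(n).  The optimum over log10(delta) in [-10, 10] is located on a 100-point
grid and refined by bounded Brent search to 1e-6.

Association statistics are z-scores in the whitened space: with
V^{-1/2} = U diag(1/sqrt(sigma_g^2 l_i + sigma_e^2)) U^T (the symmetric
inverse square root), both phenotype and genotypes are transformed by
V^{-1/2}, centered (the intercept is absorbed by projecting out the
transformed all-ones direction) and the phenotype scaled to unit variance;
then S_i = x_i^T y / ||x_i|| ~ N(0, 1) under the null.  Two-sided p-values
come from the standard normal, matching the multivariate-normal machinery
downstream; at small n they differ slightly from t-based tools.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.stats import norm

from .errors import NumericalError, ValidationError
from .genotype_io import GenotypeMatrix, PhenotypeVector
from .kinship import KinshipMatrix

_LOG10_DELTA_BOUNDS = (-10.0, 10.0)
_GRID_SIZE = 100


@dataclass
class VarianceComponents:
    """Genetic and residual variances; heritability = sg2 / (sg2 + se2)."""

    sigma_g2: float
    sigma_e2: float
    heritability: float
    loglik: float = np.nan
    method: str = "REML"

    def __post_init__(self) -> None:
        if self.sigma_g2 < 0 or self.sigma_e2 < 0:
            raise ValidationError("variance components must be non-negative")
        if self.sigma_g2 + self.sigma_e2 <= 0:
            raise ValidationError("total variance must be positive")
        if not 0 <= self.heritability <= 1:
            raise ValidationError("heritability must lie in [0, 1]")

    @classmethod
    def from_heritability(cls, h2: float, total: float = 1.0) -> "VarianceComponents":
        """Components with the given heritability and total variance."""
        return cls(h2 * total, (1.0 - h2) * total, h2, method="fixed")


def eigendecompose(k: KinshipMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Eigendecomposition of K with eigenvalues clipped at zero.

    Callers that fit many phenotypes against the same K should compute this
    once and pass it through the ``eig=`` arguments.
    """
    lam, U = np.linalg.eigh(k.values)
    return np.clip(lam, 0.0, None), U


def _profiled_negloglik(log10_delta, yr, xr, lam, n, method):
    """Negative profiled (restricted) log likelihood at delta = 10**log10_delta."""
    d = lam + 10.0 ** log10_delta
    xtx = np.sum(xr * xr / d)
    mu = np.sum(xr * yr / d) / xtx if xtx > 1e-12 else 0.0
    r = yr - mu * xr
    rss = np.sum(r * r / d)
    logdet = np.sum(np.log(d))
    if method == "ML":
        s2 = rss / n
        ll = -0.5 * (n * np.log(2 * np.pi * s2) + logdet + n)
    else:  # REML, one fixed effect (intercept)
        s2 = rss / (n - 1)
        ll = -0.5 * (
            (n - 1) * np.log(2 * np.pi * s2)
            + logdet
            + np.log(xtx)
            - np.log(n)
            + (n - 1)
        )
    return -ll


def fit_variance_components(
    y: PhenotypeVector,
    k: KinshipMatrix,
    method: str = "REML",
    eig: tuple[np.ndarray, np.ndarray] | None = None,
) -> VarianceComponents:
    """Fit sigma_g^2 and sigma_e^2 for an intercept-only mixed model."""
    vals = np.asarray(y.values, dtype=float)
    n = len(vals)
    if n != k.n:
        raise ValidationError(f"phenotype has {n} values but kinship is {k.n}x{k.n}")
    lam, U = eig if eig is not None else eigendecompose(k)
    return fit_rotated(U.T @ vals, U.T @ np.ones(n), lam, method)


def fit_rotated(
    yr: np.ndarray, xr: np.ndarray, lam: np.ndarray, method: str = "REML"
) -> VarianceComponents:
    """Fit variance components from eigenbasis-rotated phenotype and intercept.

    ``yr = U^T y``, ``xr = U^T 1`` and ``lam`` are K's eigenvalues; resampling
    loops that refit thousands of phenotypes against one K use this entry
    point to skip the per-call rotation bookkeeping.
    """
    method = method.upper()
    if method not in ("REML", "ML"):
        raise ValidationError(f"method must be REML or ML, got {method!r}")
    n = len(yr)
    # constant y in the original basis is exactly proportional to xr = U^T 1
    resid = yr - xr * (xr @ yr) / (xr @ xr)
    if np.linalg.norm(resid) <= 1e-10 * max(1.0, np.linalg.norm(yr)):
        raise ValidationError("phenotype has zero variance")
    if method == "ML":
        # K from column-standardized genotypes has K 1 = 0 exactly, so the
        # intercept direction carries zero genetic variance and the full ML
        # likelihood is unbounded (mu fits it perfectly while sigma_e -> 0).
        # Marginalizing that direction out of the objective is exact and
        # restores a well-posed optimum.
        j = int(np.argmax(np.abs(xr)))
        if xr[j] ** 2 > 0.999 * n and lam[j] <= 1e-10 * (1.0 + lam.max()):
            keep = np.ones(n, dtype=bool)
            keep[j] = False
            yr, xr, lam, n = yr[keep], xr[keep], lam[keep], n - 1
    lo, hi = _LOG10_DELTA_BOUNDS
    grid = np.linspace(lo, hi, _GRID_SIZE)
    objs = np.array([_profiled_negloglik(g, yr, xr, lam, n, method) for g in grid])
    j = int(np.argmin(objs))
    a = grid[max(j - 1, 0)]
    b = grid[min(j + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(
        _profiled_negloglik,
        bounds=(a, b),
        args=(yr, xr, lam, n, method),
        method="bounded",
        options={"xatol": 1e-6},
    )
    log10_delta = float(res.x) if res.fun <= objs[j] else float(grid[j])
    step = (hi - lo) / (_GRID_SIZE - 1)
    h2_opt = 1.0 / (1.0 + 10.0 ** log10_delta)
    if (
        log10_delta <= lo + step
        or log10_delta >= hi - step
        or h2_opt < 1e-3
        or h2_opt > 1 - 1e-3
    ):
        warnings.warn(
            f"variance-ratio optimum at bracket edge (log10 delta = {log10_delta:.2f}); "
            "heritability estimate is effectively 0 or 1",
            stacklevel=2,
        )
    delta = 10.0 ** log10_delta
    d = lam + delta
    xtx = np.sum(xr * xr / d)
    mu = np.sum(xr * yr / d) / xtx if xtx > 1e-12 else 0.0
    r = yr - mu * xr
    rss = np.sum(r * r / d)
    sg2 = rss / (n if method == "ML" else n - 1)
    se2 = delta * sg2
    h2 = float(np.clip(sg2 / (sg2 + se2), 0.0, 1.0))
    loglik = -_profiled_negloglik(log10_delta, yr, xr, lam, n, method)
    return VarianceComponents(float(sg2), float(se2), h2, float(loglik), method)


@dataclass
class CovarianceModel:
    """Fitted phenotype covariance V = sg2 K + se2 I and its matrix roots."""

    V: np.ndarray
    V_inv_sqrt: np.ndarray
    V_sqrt: np.ndarray
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    components: VarianceComponents

    @property
    def n(self) -> int:
        return self.V.shape[0]

    @property
    def tag(self) -> str:
        c = self.components
        return f"lmm(sg2={c.sigma_g2:.6g},se2={c.sigma_e2:.6g})"


def build_covariance_model(
    k: KinshipMatrix,
    vc: VarianceComponents,
    eig: tuple[np.ndarray, np.ndarray] | None = None,
) -> CovarianceModel:
    """Construct V and its symmetric square roots from K's eigensystem."""
    lam, U = eig if eig is not None else eigendecompose(k)
    w = vc.sigma_g2 * lam + vc.sigma_e2
    if np.any(w <= 1e-12):
        raise NumericalError(
            f"singular phenotype covariance: min(sg2*lambda + se2) = {w.min():.3e}"
        )
    V = (U * w) @ U.T
    Vis = (U / np.sqrt(w)) @ U.T
    Vsq = (U * np.sqrt(w)) @ U.T
    return CovarianceModel(
        V=(V + V.T) / 2,
        V_inv_sqrt=(Vis + Vis.T) / 2,
        V_sqrt=(Vsq + Vsq.T) / 2,
        eigenvalues=lam,
        eigenvectors=U,
        components=vc,
    )


@dataclass
class AssociationResult:
    """Per-marker effect estimates, z-scores and two-sided normal p-values."""

    marker_ids: np.ndarray
    beta: np.ndarray
    stat: np.ndarray
    pvalue: np.ndarray

    @property
    def m(self) -> int:
        return len(self.stat)


def _scan_statistics(ty: np.ndarray, tx: np.ndarray, marker_ids) -> AssociationResult:
    """z-scores of whitened phenotype against whitened genotype columns."""
    ty = ty - ty.mean()
    sd = ty.std()
    if sd <= 0:
        raise ValidationError("transformed phenotype has zero variance")
    ty = ty / sd
    txc = tx - tx.mean(axis=0)
    ss = np.einsum("ij,ij->j", txc, txc)
    degenerate = ss <= 1e-24
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} marker(s) degenerate after transformation; "
            "statistic set to 0, p-value to 1",
            stacklevel=3,
        )
        ss = np.where(degenerate, 1.0, ss)
    xy = txc.T @ ty
    beta = np.where(degenerate, 0.0, xy / ss)
    stat = np.where(degenerate, 0.0, xy / np.sqrt(ss))
    pvalue = np.clip(2.0 * norm.sf(np.abs(stat)), np.finfo(float).tiny, 1.0)
    return AssociationResult(np.asarray(marker_ids), beta, stat, pvalue)


def association_scan(
    y: PhenotypeVector,
    g: GenotypeMatrix,
    model: CovarianceModel | None = None,
) -> AssociationResult:
    """Score every marker against the phenotype under the fitted covariance.

    With ``model=None`` (or sigma_g^2 = 0) this reduces exactly to plain
    linear-model z-scores on standardized data.
    """
    if not g.standardized:
        raise ValidationError("association_scan requires standardized genotypes")
    if y.n != g.n:
        raise ValidationError(f"phenotype n={y.n} does not match genotypes n={g.n}")
    if model is None:
        ty, tx = y.values.copy(), g.dosages
    else:
        if model.n != g.n:
            raise ValidationError("covariance model dimension does not match genotypes")
        ty = model.V_inv_sqrt @ y.values
        tx = model.V_inv_sqrt @ g.dosages
    return _scan_statistics(ty, tx, g.marker_ids)
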