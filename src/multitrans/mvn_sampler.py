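"""Monte-Carlo sampling of null statistic vectors from MVN(0, Sigma^M).

The sliding-window sampler draws each statistic conditionally on its w
predecessors on the same chromosome, following the chain-rule factorization
f(S_1..S_m) = f(S_1) f(S_2|S_1) ... f(S_m | S_{m-w}..S_{m-1}) that holds
under the local linkage-disequilibrium assumption.  Chromosomes are sampled
independently.  Per replicate only the running max |S| is kept; the output
is the distribution of per-replicate minimum pointwise p-values,
min_p = 2 (1 - Phi(max_i |S_i|)), which is all the threshold search needs.

A dense-Cholesky sampler over the full correlation matrix is provided as
the exact reference for small m.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg
from scipy.stats import norm

from .errors import NumericalError, ValidationError
from .genotype_io import chromosome_blocks
from .transform_cov import BandedCovariance, band_to_dense

# replicate chunking keeps the (chunk, w) working buffer around ~200 MB
_CHUNK_DOUBLES = 2.5e7


@dataclass
class SamplerConfig:
    n_samples: int
    seed: int
    window: int = 1000
    ridge: float = 1e-8
    min_conditional_var: float = 1e-8

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValidationError("n_samples must be >= 1")
        if self.window < 1:
            raise ValidationError("window must be >= 1")


@dataclass
class NullMinPDistribution:
    """Per-replicate minimum pointwise p-values under the null."""

    min_p: np.ndarray
    m: int
    provenance: str
    _sorted: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.min_p = np.asarray(self.min_p, dtype=float)
        if self.min_p.size == 0:
            raise ValidationError("empty min-p sample")
        if self.min_p.min() <= 0 or self.min_p.max() > 1:
            raise ValidationError("min_p values must lie in (0, 1]")

    @property
    def n_samples(self) -> int:
        return len(self.min_p)

    @property
    def sorted_min_p(self) -> np.ndarray:
        if self._sorted is None:
            self._sorted = np.sort(self.min_p)
        return self._sorted


def _cholesky_with_ridge(sigma: np.ndarray, ridge: float, what: str):
    """Lower Cholesky factor, retrying with escalating diagonal ridges."""
    for bump in (0.0, ridge, ridge * 1e2, ridge * 1e4):
        try:
            a = sigma if bump == 0.0 else sigma + bump * np.eye(sigma.shape[0])
            return linalg.cholesky(a, lower=True)
        except linalg.LinAlgError:
            continue
    raise NumericalError(f"covariance block not PSD after ridge retries ({what})")


def _window_block(band: np.ndarray, bandw: int, win: np.ndarray) -> np.ndarray:
    """Correlation matrix of the window markers (global indices ``win``)."""
    k = len(win)
    sig = np.eye(k)
    for b in range(1, k):
        j = win[b]
        lags = j - win[:b]
        vals = np.where(lags <= bandw, band[j, np.minimum(lags, bandw) - 1], 0.0)
        sig[b, :b] = vals
        sig[:b, b] = vals
    return sig


def _conditional_coefficients(band: BandedCovariance, cfg: SamplerConfig):
    """Per-marker regression coefficients onto the w predecessors.

    Returns (w_eff, list of (cbuf, sd)) where ``cbuf`` is the coefficient
    vector scattered to ring-buffer column positions (None for the first
    marker of a chromosome) and ``sd`` the conditional standard deviation.
    """
    w_eff = min(band.window, cfg.window)
    bandw = band.window
    coeffs: list[tuple[np.ndarray | None, float]] = []
    for start, stop in chromosome_blocks(band.chromosomes):
        for i in range(start, stop):
            k = min(w_eff, i - start)
            if k == 0:
                coeffs.append((None, 1.0))
                continue
            win = np.arange(i - k, i)
            sig = _window_block(band.band, bandw, win)
            lags = i - win
            rho = np.where(lags <= bandw, band.band[i, np.minimum(lags, bandw) - 1], 0.0)
            # window blocks are rank-deficient whenever w >= n, so the solve is
            # always ridge-regularized; this only biases the conditional
            # variance upward (conservative) by O(ridge)
            eye = np.eye(k)
            c = None
            for bump in (cfg.ridge, cfg.ridge * 1e2, cfg.ridge * 1e4):
                try:
                    chol = linalg.cholesky(sig + bump * eye, lower=True)
                except linalg.LinAlgError:
                    continue
                c_try = linalg.cho_solve((chol, True), rho)
                var_try = 1.0 - float(rho @ c_try)
                if var_try >= -1e-3:
                    c, var = c_try, var_try
                    break
            if c is None:
                raise NumericalError(
                    f"covariance block not PSD after ridge retries "
                    f"(marker {band.marker_ids[i]})"
                )
            sd = math.sqrt(min(max(var, cfg.min_conditional_var), 1.0))
            cbuf = np.zeros(w_eff)
            cbuf[win % w_eff] = c
            coeffs.append((cbuf, sd))
    return w_eff, coeffs


def _minp_from_maxabs(maxabs: np.ndarray) -> np.ndarray:
    return np.clip(2.0 * norm.sf(maxabs), np.finfo(float).tiny, 1.0)


def sample_null_statistics(
    band: BandedCovariance, cfg: SamplerConfig
) -> NullMinPDistribution:
    """Sliding-window conditional Gaussian sampling of the null max statistic.

    All replicates advance marker by marker simultaneously; the effective
    window is min(band.window, cfg.window).  Bit-reproducible for a given
    (band, cfg) pair.
    """
    m = band.m
    w_eff, coeffs = _conditional_coefficients(band, cfg)
    s = cfg.n_samples
    chunk = int(min(s, max(1024, _CHUNK_DOUBLES // max(w_eff, 1))))
    rng = np.random.default_rng(cfg.seed)
    min_p = np.empty(s)
    blocks = chromosome_blocks(band.chromosomes)
    for lo in range(0, s, chunk):
        cs = min(chunk, s - lo)
        maxabs = np.zeros(cs)
        buffer = np.empty((cs, w_eff))
        for start, stop in blocks:
            buffer[:] = 0.0
            for i in range(start, stop):
                cbuf, sd = coeffs[i]
                z = rng.standard_normal(cs)
                if cbuf is None:
                    vals = z
                else:
                    vals = buffer @ cbuf
                    vals += sd * z
                np.maximum(maxabs, np.abs(vals), out=maxabs)
                buffer[:, i % w_eff] = vals
        min_p[lo : lo + cs] = _minp_from_maxabs(maxabs)
    return NullMinPDistribution(min_p, m, "multitrans")


def sample_exact_mvn(
    sigma: np.ndarray | BandedCovariance, cfg: SamplerConfig
) -> NullMinPDistribution:
    """Full-covariance Cholesky sampling; the oracle for the sliding window."""
    if isinstance(sigma, BandedCovariance):
        sigma = band_to_dense(sigma)
    sigma = np.asarray(sigma, dtype=float)
    m = sigma.shape[0]
    if sigma.ndim != 2 or sigma.shape[1] != m:
        raise ValidationError("correlation matrix must be square")
    if m > 5000:
        raise ValidationError("dense sampling limited to m <= 5000")
    if np.abs(np.diag(sigma) - 1.0).max() > 1e-6:
        warnings.warn("correlation matrix diagonal deviates from 1", stacklevel=2)
    L = _cholesky_with_ridge(sigma, cfg.ridge, "dense covariance")
    s = cfg.n_samples
    chunk = int(min(s, max(256, _CHUNK_DOUBLES // max(m, 1))))
    rng = np.random.default_rng(cfg.seed)
    min_p = np.empty(s)
    for lo in range(0, s, chunk):
        cs = min(chunk, s - lo)
        stats = rng.standard_normal((cs, m)) @ L.T
        min_p[lo : lo + cs] = _minp_from_maxabs(np.abs(stats).max(axis=1))
    return NullMinPDistribution(min_p, m, "exact-mvn")
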