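"""Covariance of null statistics: correlations of V^{-1/2}-transformed genotypes.

Under the mixed model the covariance between the null z-scores of two
markers equals the Pearson correlation of their genotype vectors after
whitening by V^{-1/2} (r^M_ij); with the identity transform it is the plain
genotype correlation r_ij, the covariance valid under the ordinary linear
model.  Only within-window, within-chromosome correlations are stored (a
banded m x w array); cross-chromosome statistics are treated as independent,
which under the local linkage-disequilibrium assumption is conservative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import NumericalError, ValidationError
from .genotype_io import GenotypeMatrix, chromosome_blocks
from .kinship import KinshipMatrix
from .lmm_core import CovarianceModel, VarianceComponents, build_covariance_model


@dataclass
class TransformedGenotypes:
    """V^{-1/2} X with each column re-centered and scaled to unit variance."""

    matrix: np.ndarray
    marker_ids: np.ndarray
    chromosomes: np.ndarray
    positions: np.ndarray
    transform_tag: str

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def m(self) -> int:
        return self.matrix.shape[1]


def transform_genotypes(
    g: GenotypeMatrix, model: CovarianceModel | None = None
) -> TransformedGenotypes:
    """Whiten genotype columns by V^{-1/2}; identity model gives the raw baseline."""
    if not g.standardized:
        raise ValidationError("transform_genotypes requires standardized genotypes")
    if model is None:
        T = g.dosages.copy()
        tag = "identity"
    else:
        if model.n != g.n:
            raise ValidationError(
                f"covariance model is {model.n}x{model.n} but genotypes have n={g.n}"
            )
        T = model.V_inv_sqrt @ g.dosages
        tag = model.tag
    T = T - T.mean(axis=0)
    sd = T.std(axis=0)
    zero = sd <= 1e-12
    if zero.any():
        j = int(np.where(zero)[0][0])
        raise NumericalError(
            f"marker {g.marker_ids[j]} has zero variance after transformation"
        )
    return TransformedGenotypes(
        T / sd, g.marker_ids, g.chromosomes, g.positions, tag
    )


@dataclass
class BandedCovariance:
    """Within-window correlations: band[i, d-1] = Cor(marker i, marker i-d).

    Entries crossing a chromosome boundary (or with no predecessor) are 0,
    i.e. independent.  Dense storage is m * w * 8 bytes.
    """

    window: int
    band: np.ndarray
    chromosomes: np.ndarray
    marker_ids: np.ndarray
    transform_tag: str

    @property
    def m(self) -> int:
        return self.band.shape[0]


def windowed_correlation(t: TransformedGenotypes, window: int) -> BandedCovariance:
    """Pearson correlations of each marker with its ``window`` predecessors."""
    if window < 1:
        raise ValidationError("window must be >= 1")
    n, m = t.matrix.shape
    band = np.zeros((m, window))
    for start, stop in chromosome_blocks(t.chromosomes):
        block = t.matrix[:, start:stop]
        length = stop - start
        for d in range(1, min(window, length - 1) + 1):
            # columns have mean 0 and variance 1 (denominator n)
            band[start + d : stop, d - 1] = np.einsum(
                "ij,ij->j", block[:, d:], block[:, : length - d]
            ) / n
    np.clip(band, -1.0, 1.0, out=band)
    return BandedCovariance(window, band, t.chromosomes, t.marker_ids, t.transform_tag)


def band_to_dense(b: BandedCovariance) -> np.ndarray:
    """Expand the band into the full m x m correlation matrix (small m only)."""
    m = b.m
    sigma = np.eye(m)
    for i in range(m):
        for d in range(1, min(b.window, i) + 1):
            v = b.band[i, d - 1]
            if v != 0.0:
                sigma[i, i - d] = sigma[i - d, i] = v
    return sigma


@dataclass
class CalibrationReport:
    """Empirical statistic covariance vs model correlations, per marker pair.

    ``diff_transformed`` = Cov_emp(S_i, S_j) - r^M_ij and ``diff_raw`` the
    same against the untransformed correlation r_ij, over all i < j.
    """

    diff_transformed: np.ndarray
    diff_raw: np.ndarray
    n_reps: int

    @property
    def mean_diff_transformed(self) -> float:
        return float(self.diff_transformed.mean())

    @property
    def mean_abs_transformed(self) -> float:
        return float(np.abs(self.diff_transformed).mean())

    @property
    def mean_diff_raw(self) -> float:
        return float(self.diff_raw.mean())

    @property
    def mean_abs_raw(self) -> float:
        return float(np.abs(self.diff_raw).mean())


def covariance_calibration_check(
    g: GenotypeMatrix,
    k: KinshipMatrix,
    vc: VarianceComponents,
    n_reps: int,
    seed: int,
) -> CalibrationReport:
    """Simulate null statistics under V-hat and compare their empirical
    covariance with the transformed and raw genotype correlations.

    Phenotypes are drawn from N(0, V); because statistics are computed in the
    whitened space this reduces to scoring transformed genotypes against
    standard-normal vectors.
    """
    if n_reps < 100:
        raise ValidationError("n_reps must be >= 100 (noise dominates below that)")
    if g.m > 500:
        raise ValidationError("calibration check builds dense m x m matrices; use m <= 500")
    model = build_covariance_model(k, vc)
    T = transform_genotypes(g, model).matrix
    X = g.dosages  # standardized
    n = g.n
    rng = np.random.default_rng(seed)
    Z = rng.standard_normal((n_reps, n))
    Z = Z - Z.mean(axis=1, keepdims=True)
    Z = Z / Z.std(axis=1, keepdims=True)
    S = Z @ T / np.sqrt(n)
    emp = np.cov(S, rowvar=False)
    r_m = T.T @ T / n
    r_raw = X.T @ X / n
    iu = np.triu_indices(g.m, 1)
    return CalibrationReport(
        diff_transformed=emp[iu] - r_m[iu],
        diff_raw=emp[iu] - r_raw[iu],
        n_reps=n_reps,
    )
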