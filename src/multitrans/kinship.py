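"""Genetic-relatedness (kinship) matrix estimation and I/O.

The estimator is the standardized-genotype cross product K = X X^T / m, the
usual genomic relationship matrix.  The downstream machinery works for any
symmetric PSD K, so user-supplied matrices are accepted verbatim (after a
symmetry check).  K's overall scale is absorbed by the refitted genetic
variance component, so dividing by m only affects the reported component
values, not thresholds.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass

import numpy as np

from .errors import InputError, ValidationError
from .genotype_io import GenotypeMatrix

_EIG_FLOOR = -1e-8


@dataclass
class KinshipMatrix:
    """Symmetric PSD n x n relatedness matrix."""

    values: np.ndarray
    individual_ids: np.ndarray = None  # type: ignore[assignment]
    n_markers_used: int | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValidationError("kinship matrix must be square")
        if self.individual_ids is None:
            self.individual_ids = np.array(
                [f"ind{i:04d}" for i in range(self.values.shape[0])], dtype=object
            )
        self.individual_ids = np.asarray(self.individual_ids, dtype=object)
        if len(self.individual_ids) != self.values.shape[0]:
            raise ValidationError("kinship ids do not match matrix dimension")
        asym = np.abs(self.values - self.values.T).max() if self.values.size else 0.0
        if asym > 1e-10:
            raise ValidationError(f"kinship matrix not symmetric (max asymmetry {asym:.2e})")
        if np.any(np.diag(self.values) <= 0):
            raise ValidationError("kinship diagonal must be positive")
        lam_min = float(np.linalg.eigvalsh(self.values)[0])
        if lam_min < _EIG_FLOOR:
            raise ValidationError(
                f"kinship matrix is not PSD (min eigenvalue {lam_min:.2e})"
            )

    @property
    def n(self) -> int:
        return self.values.shape[0]


def compute_kinship(g: GenotypeMatrix) -> KinshipMatrix:
    """K = X X^T / m on standardized genotypes (mean diagonal ~ 1)."""
    if not g.standardized:
        raise ValidationError("compute_kinship requires standardized genotypes; "
                              "call standardize() first")
    K = g.dosages @ g.dosages.T / g.m
    K = (K + K.T) / 2.0
    return KinshipMatrix(K, g.individual_ids, n_markers_used=g.m)


def load_kinship(path: str | os.PathLike, individual_ids=None) -> KinshipMatrix:
    """Read a whitespace-delimited square matrix; symmetrize with a warning."""
    if not os.path.exists(path):
        raise InputError(f"kinship file not found: {path}")
    try:
        K = np.loadtxt(path)
    except ValueError as exc:
        raise InputError(f"{path}: could not parse square matrix: {exc}") from exc
    K = np.atleast_2d(K)
    if K.shape[0] != K.shape[1]:
        raise ValidationError(f"{path}: matrix is {K.shape[0]}x{K.shape[1]}, not square")
    asym = np.abs(K - K.T).max()
    if asym > 1e-6:
        warnings.warn(
            f"{path}: asymmetry {asym:.2e} exceeds 1e-6; symmetrizing as (K+K^T)/2",
            stacklevel=2,
        )
    K = (K + K.T) / 2.0
    return KinshipMatrix(K, individual_ids)


def save_kinship(k: KinshipMatrix, path: str | os.PathLike) -> None:
    np.savetxt(path, k.values, fmt="%.12g")


@dataclass
class KinshipSummary:
    """Histogram of the n(n-1)/2 upper-triangle relatedness values."""

    counts: np.ndarray
    bin_edges: np.ndarray
    minimum: float
    median: float
    maximum: float


def kinship_heatmap_summary(k: KinshipMatrix, bins: int = 50) -> KinshipSummary:
    """Binned off-diagonal relatedness values plus min/median/max."""
    if k.n < 2:
        raise ValidationError("need at least 2 individuals to summarize relatedness")
    off = k.values[np.triu_indices(k.n, 1)]
    counts, edges = np.histogram(off, bins=bins)
    return KinshipSummary(
        counts=counts,
        bin_edges=edges,
        minimum=float(off.min()),
        median=float(np.median(off)),
        maximum=float(off.max()),
    )
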