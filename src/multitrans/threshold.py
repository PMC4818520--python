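"""Per-marker thresholds and family-wise error rates from null min-p samples.

The per-marker threshold u at level alpha is the empirical alpha-quantile of
the per-replicate minimum pointwise p-value: the Monte-Carlo realization of
the outside-rectangle probability search.  The lower order statistic is
used, a conservative tie-break.  Bonferroni (alpha/m) and Sidak
(1-(1-alpha)^(1/m)) are provided as independence-based references.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import binomtest

from .errors import ValidationError
from .mvn_sampler import NullMinPDistribution


@dataclass
class ThresholdResult:
    alpha: float
    per_marker_threshold: float
    mc_se: float
    n_samples: int
    m: int
    method: str


def per_marker_threshold(d: NullMinPDistribution, alpha: float = 0.05) -> ThresholdResult:
    """Empirical alpha-quantile of the null min-p distribution.

    The Monte-Carlo standard error is read off the order statistics at
    +/- sqrt(s alpha (1-alpha)) ranks, i.e. the binomial rank uncertainty
    mapped through the empirical quantile function.
    """
    if not 0 < alpha < 1:
        raise ValidationError("alpha must be in (0, 1)")
    s = d.n_samples
    if s * alpha < 10:
        raise ValidationError(
            f"insufficient samples: need s*alpha >= 10, got {s}*{alpha} = {s * alpha:.1f}"
        )
    srt = d.sorted_min_p
    k = math.ceil(alpha * s)
    u = float(srt[k - 1])
    if srt[0] == srt[-1]:
        warnings.warn("degenerate min-p distribution (all values equal)", stacklevel=2)
    dk = max(1, math.ceil(math.sqrt(s * alpha * (1 - alpha))))
    lo = float(srt[max(0, k - 1 - dk)])
    hi = float(srt[min(s - 1, k - 1 + dk)])
    return ThresholdResult(alpha, u, (hi - lo) / 2.0, s, d.m, d.provenance)


@dataclass
class FamilyWiseError:
    """Estimated family-wise error rate with an exact binomial 95 % CI."""

    estimate: float
    ci_low: float
    ci_high: float
    n_samples: int


def family_wise_error(d: NullMinPDistribution, u: float) -> FamilyWiseError:
    """Fraction of null replicates whose minimum p-value falls below u."""
    if not 0 < u <= 1:
        raise ValidationError("pointwise threshold u must be in (0, 1]")
    s = d.n_samples
    hits = int(np.count_nonzero(d.min_p <= u))
    ci = binomtest(hits, s).proportion_ci(confidence_level=0.95, method="exact")
    return FamilyWiseError(hits / s, float(ci.low), float(ci.high), s)


def bonferroni(alpha: float, m: int) -> float:
    """Independence-based per-marker threshold alpha / m."""
    if m < 1:
        raise ValidationError("m must be >= 1")
    if not 0 < alpha < 1:
        raise ValidationError("alpha must be in (0, 1)")
    return alpha / m


def sidak(alpha: float, m: int) -> float:
    """Exact independence correction 1 - (1 - alpha)^(1/m)."""
    if m < 1:
        raise ValidationError("m must be >= 1")
    if not 0 < alpha < 1:
        raise ValidationError("alpha must be in (0, 1)")
    return 1.0 - (1.0 - alpha) ** (1.0 / m)


def threshold_curve(
    d: NullMinPDistribution, alphas: np.ndarray | None = None
) -> list[ThresholdResult]:
    """Thresholds over a grid of significance levels (default 0.1 %-10 %)."""
    if alphas is None:
        alphas = np.geomspace(0.001, 0.10, 21)
    return [per_marker_threshold(d, float(a)) for a in alphas]
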