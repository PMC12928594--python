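"""Single-group moment and correlation estimators with analytic sampling
variances.

These are the building blocks for the two-group contrasts: the small-sample-
adjusted sample skewness (the adjusted Fisher–Pearson coefficient, often
written G1), the small-sample excess kurtosis (G2, zero in expectation under
normality), Pearson's r, and Fisher's variance-stabilising z-transform.

The analytic sampling variances

    var(sk) = 6 n (n-1) / [(n-2)(n+1)(n+3)]
    var(ku) = 24 n (n-1)^2 / [(n-3)(n-2)(n+3)(n+5)]
    var(Zr) = 1 / (n-3)

are exact under normality (sk, ku) or bivariate normality (Zr); for skewed or
heavy-tailed data the jackknife alternatives in :mod:`deltamoments.resampling`
are the recommended variance estimators.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np

from .errors import InvalidInputError, MomentDomainError, UndefinedStatisticError

__all__ = [
    "GroupSample",
    "MomentEstimate",
    "CorrelationEstimate",
    "sample_skewness",
    "skewness_sampling_variance",
    "sample_excess_kurtosis",
    "kurtosis_sampling_variance",
    "pearson_correlation",
    "fisher_z",
    "fisher_z_inverse",
    "fisher_z_variance",
    "skewness_estimate",
    "kurtosis_estimate",
    "correlation_estimate",
    "RECOMMENDED_MIN_N",
]

logger = logging.getLogger(__name__)

#: Below this per-group n, skewness/kurtosis contrasts are logged as fragile
#: (small samples make third/fourth moments extreme); it is a warning, not an
#: error, so simulation studies can still explore n = 10.
RECOMMENDED_MIN_N = 50


@dataclass(frozen=True)
class GroupSample:
    """Raw observations for one group: one trait, optionally a paired second.

    ``values`` (and ``second_values`` when present) must be free of missing
    entries; drop and count missing rows upstream.
    """

    values: np.ndarray
    second_values: Optional[np.ndarray] = None
    label: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1:
            raise InvalidInputError("values must be a 1-d sequence")
        if not np.all(np.isfinite(v)):
            raise InvalidInputError(
                f"group {self.label!r}: values contain non-finite entries; "
                "drop missing rows before constructing a GroupSample"
            )
        object.__setattr__(self, "values", v)
        if self.second_values is not None:
            w = np.asarray(self.second_values, dtype=float)
            if w.shape != v.shape:
                raise InvalidInputError(
                    f"group {self.label!r}: second_values length {w.size} "
                    f"!= values length {v.size}"
                )
            if not np.all(np.isfinite(w)):
                raise InvalidInputError(
                    f"group {self.label!r}: second_values contain non-finite entries"
                )
            object.__setattr__(self, "second_values", w)

    @property
    def n(self) -> int:
        return int(self.values.size)

    @property
    def paired(self) -> bool:
        return self.second_values is not None


@dataclass(frozen=True)
class MomentEstimate:
    """A skewness or excess-kurtosis point estimate with sampling variance."""

    statistic_kind: Literal["skewness", "excess_kurtosis"]
    estimate: float
    sampling_variance: float
    n: int
    method: Literal["analytic", "jackknife"] = "analytic"

    def __post_init__(self) -> None:
        if self.sampling_variance < 0:
            raise InvalidInputError("sampling_variance must be >= 0")


@dataclass(frozen=True)
class CorrelationEstimate:
    """Pearson r with its Fisher transform and the z-scale sampling variance."""

    r: float
    zr: float
    sampling_variance: float
    n: int
    method: Literal["analytic", "jackknife"] = "analytic"


def _check_sample(x: Sequence[float], min_n: int, what: str) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise InvalidInputError(f"{what}: input must be 1-d")
    if x.size < min_n:
        raise InvalidInputError(
            f"{what}: needs at least {min_n} observations, got {x.size}"
        )
    if not np.all(np.isfinite(x)):
        raise InvalidInputError(f"{what}: non-finite values in input")
    return x


def _central_moments(x: np.ndarray, upto: int) -> tuple[float, ...]:
    # center on the mean once; moments are location-invariant so this also
    # improves conditioning for data with large offsets
    d = x - x.mean()
    return tuple(float(np.mean(d**k)) for k in range(2, upto + 1))


def sample_skewness(x: Sequence[float]) -> float:
    """Small-sample-adjusted sample skewness.

    G1 = m3 / m2^(3/2) * sqrt(n(n-1)) / (n-2), with m2, m3 the divisor-n
    central moments. Requires n >= 3 and a non-degenerate sample.
    """
    x = _check_sample(x, 3, "sample_skewness")
    n = x.size
    m2, m3 = _central_moments(x, 3)
    if m2 == 0.0:
        raise UndefinedStatisticError(
            "sample_skewness: all values identical (zero variance)"
        )
    g1 = m3 / m2**1.5
    return g1 * math.sqrt(n * (n - 1)) / (n - 2)


def skewness_sampling_variance(n: int) -> float:
    """Analytic (normal-theory) sampling variance of the sample skewness."""
    if n < 3:
        raise InvalidInputError(f"skewness_sampling_variance: n >= 3 required, got {n}")
    n = int(n)
    return 6.0 * n * (n - 1) / ((n - 2) * (n + 1) * (n + 3))


def sample_excess_kurtosis(x: Sequence[float]) -> float:
    """Small-sample excess kurtosis (G2); zero in expectation under normality.

    G2 = (n-1)/[(n-2)(n-3)] * [(n+1) g2 + 6] with g2 = m4/m2^2 - 3.
    Equivalently the non-excess kurtosis of the normal recovers 3 when 3 is
    added back. Requires n >= 4 and a non-degenerate sample.
    """
    x = _check_sample(x, 4, "sample_excess_kurtosis")
    n = x.size
    m2, _, m4 = _central_moments(x, 4)
    if m2 == 0.0:
        raise UndefinedStatisticError(
            "sample_excess_kurtosis: all values identical (zero variance)"
        )
    g2 = m4 / m2**2 - 3.0
    return (n - 1) / ((n - 2) * (n - 3)) * ((n + 1) * g2 + 6.0)


def kurtosis_sampling_variance(n: int) -> float:
    """Analytic (normal-theory) sampling variance of the excess kurtosis."""
    if n < 4:
        raise InvalidInputError(f"kurtosis_sampling_variance: n >= 4 required, got {n}")
    n = int(n)
    return 24.0 * n * (n - 1) ** 2 / ((n - 3) * (n - 2) * (n + 3) * (n + 5))


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation of two paired sequences."""
    x = _check_sample(x, 4, "pearson_correlation")
    y = _check_sample(y, 4, "pearson_correlation")
    if x.size != y.size:
        raise InvalidInputError(
            f"pearson_correlation: length mismatch ({x.size} vs {y.size})"
        )
    dx = x - x.mean()
    dy = y - y.mean()
    sxx = float(dx @ dx)
    syy = float(dy @ dy)
    if sxx == 0.0 or syy == 0.0:
        raise UndefinedStatisticError("pearson_correlation: constant input sequence")
    r = float(dx @ dy) / math.sqrt(sxx * syy)
    # guard against rounding past the closed interval
    return min(1.0, max(-1.0, r))


def fisher_z(r: float) -> float:
    """Fisher's variance-stabilising transform z = atanh(r) = ln((1+r)/(1-r))/2."""
    if not -1.0 < r < 1.0:
        raise MomentDomainError(
            f"fisher_z: |r| must be < 1 (got r = {r}); the transform is infinite"
        )
    return math.atanh(r)


def fisher_z_inverse(z: float) -> float:
    """Back-transform from the z scale to a correlation, r = tanh(z)."""
    return math.tanh(z)


def fisher_z_variance(n: int) -> float:
    """Sampling variance of Fisher's z under bivariate normality: 1/(n-3)."""
    if n <= 3:
        raise InvalidInputError(f"fisher_z_variance: n >= 4 required, got {n}")
    return 1.0 / (int(n) - 3)


def _warn_small_n(n: int, what: str, label: str = "") -> None:
    if n < RECOMMENDED_MIN_N:
        logger.warning(
            "%s computed on n = %d%s; recommended minimum per group is %d — "
            "higher moments become extreme in small samples",
            what,
            n,
            f" (group {label!r})" if label else "",
            RECOMMENDED_MIN_N,
        )


def skewness_estimate(g: GroupSample) -> MomentEstimate:
    """Analytic skewness estimate with its normal-theory sampling variance."""
    _warn_small_n(g.n, "skewness", g.label)
    return MomentEstimate(
        statistic_kind="skewness",
        estimate=sample_skewness(g.values),
        sampling_variance=skewness_sampling_variance(g.n),
        n=g.n,
        method="analytic",
    )


def kurtosis_estimate(g: GroupSample) -> MomentEstimate:
    """Analytic excess-kurtosis estimate with its normal-theory variance."""
    _warn_small_n(g.n, "excess kurtosis", g.label)
    return MomentEstimate(
        statistic_kind="excess_kurtosis",
        estimate=sample_excess_kurtosis(g.values),
        sampling_variance=kurtosis_sampling_variance(g.n),
        n=g.n,
        method="analytic",
    )


def correlation_estimate(g: GroupSample) -> CorrelationEstimate:
    """Pearson r, Fisher z and the analytic z-scale variance for a paired sample."""
    if not g.paired:
        raise InvalidInputError(
            f"correlation_estimate: group {g.label!r} has no second trait"
        )
    r = pearson_correlation(g.values, g.second_values)
    return CorrelationEstimate(
        r=r,
        zr=fisher_z(r),
        sampling_variance=fisher_z_variance(g.n),
        n=g.n,
        method="analytic",
    )
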