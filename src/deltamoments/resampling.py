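"""Leave-one-out (delete-1) jackknife variance and bias correction.

For a plug-in statistic theta computed on a sample of size n, let theta_(i)
be the statistic on the sample with observation i removed and theta_(.) the
mean of the leave-one-out values. The Tukey jackknife variance is

    var_jack = (n-1)/n * sum_i (theta_(i) - theta_(.))^2

and the bias-corrected point estimate is

    theta_bc = n * theta - (n-1) * theta_(.)

The generic :func:`jackknife` recomputes the statistic naively on every
subsample (O(n^2) for O(n) statistics) and is the reference implementation;
:func:`jackknife_moment` and :func:`jackknife_correlation` are exact O(n)
power-sum fast paths for the moment statistics and Fisher's z, pinned to the
naive path in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Literal, Sequence

import numpy as np

from .core_moments import fisher_z
from .errors import InvalidInputError, MomentDomainError, UndefinedStatisticError

__all__ = [
    "JackknifeResult",
    "jackknife",
    "jackknife_moment",
    "jackknife_correlation",
    "pooled_jackknife_contrast",
]

#: |skewness of the leave-one-out estimates| above which the result is
#: flagged: a strongly asymmetric jackknife distribution signals that the
#: Wald interval built from this variance may cover poorly (the known failure
#: mode of kurtosis contrasts).
PSEUDOVALUE_SKEW_THRESHOLD = 2.0


@dataclass(frozen=True)
class JackknifeResult:
    plug_in: float
    bias_corrected: float
    variance: float
    n: int
    pseudovalue_skew_flag: bool = False


def _finalize(plug_in: float, loo: np.ndarray) -> JackknifeResult:
    n = loo.size
    loo_mean = float(loo.mean())
    variance = float((n - 1) / n * np.sum((loo - loo_mean) ** 2))
    bias_corrected = n * plug_in - (n - 1) * loo_mean
    flag = False
    if n >= 3:
        d = loo - loo_mean
        m2 = float(np.mean(d**2))
        if m2 > 0:
            g1 = float(np.mean(d**3)) / m2**1.5
            flag = abs(g1) > PSEUDOVALUE_SKEW_THRESHOLD
    return JackknifeResult(
        plug_in=float(plug_in),
        bias_corrected=float(bias_corrected),
        variance=variance,
        n=n,
        pseudovalue_skew_flag=flag,
    )


def jackknife(statistic: Callable[[np.ndarray], float], x: Sequence[float]) -> JackknifeResult:
    """Delete-1 jackknife of an arbitrary statistic (naive recomputation)."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise InvalidInputError("jackknife: need a 1-d sample with n >= 2")
    n = x.size
    plug_in = float(statistic(x))
    loo = np.empty(n)
    for i in range(n):
        sub = np.delete(x, i)
        try:
            loo[i] = statistic(sub)
        except Exception as exc:  # annotate which subsample failed
            raise UndefinedStatisticError(
                f"jackknife: statistic undefined on leave-one-out subsample "
                f"i={i}: {exc}"
            ) from exc
    return _finalize(plug_in, loo)


def _loo_central_moments(x: np.ndarray, upto: int) -> tuple[np.ndarray, ...]:
    """Central moments (divisor n-1 observations) of every delete-1 subsample.

    Computed from full-sample power sums; x should be pre-centered for
    conditioning (moments are location-invariant).
    """
    n = x.size
    m = n - 1
    pows = [x**k for k in range(1, upto + 1)]
    S = [float(p.sum()) for p in pows]
    s = [S[k] - pows[k] for k in range(upto)]  # s[k-1] = sum of x^k without i
    mu = s[0] / m
    out = []
    if upto >= 2:
        out.append(s[1] / m - mu**2)
    if upto >= 3:
        out.append(s[2] / m - 3 * mu * s[1] / m + 2 * mu**3)
    if upto >= 4:
        out.append(s[3] / m - 4 * mu * s[2] / m + 6 * mu**2 * s[1] / m - 3 * mu**4)
    return tuple(out)


def jackknife_moment(
    x: Sequence[float], kind: Literal["skewness", "excess_kurtosis"]
) -> JackknifeResult:
    """Exact vectorised delete-1 jackknife of G1 skewness or G2 excess kurtosis."""
    x = np.asarray(x, dtype=float)
    min_n = 4 if kind == "skewness" else 5  # statistic must exist on subsamples
    if x.ndim != 1 or x.size < min_n:
        raise InvalidInputError(
            f"jackknife_moment({kind}): need n >= {min_n}, got {x.size}"
        )
    xc = x - x.mean()
    n = x.size
    m = n - 1
    if kind == "skewness":
        from .core_moments import sample_skewness

        plug_in = sample_skewness(x)
        m2, m3 = _loo_central_moments(xc, 3)
        if np.any(m2 <= 0):
            bad = int(np.argmax(m2 <= 0))
            raise UndefinedStatisticError(
                f"jackknife_moment: zero variance on leave-one-out subsample i={bad}"
            )
        loo = m3 / m2**1.5 * np.sqrt(m * (m - 1)) / (m - 2)
    else:
        from .core_moments import sample_excess_kurtosis

        plug_in = sample_excess_kurtosis(x)
        m2, _, m4 = _loo_central_moments(xc, 4)
        if np.any(m2 <= 0):
            bad = int(np.argmax(m2 <= 0))
            raise UndefinedStatisticError(
                f"jackknife_moment: zero variance on leave-one-out subsample i={bad}"
            )
        g2 = m4 / m2**2 - 3.0
        loo = (m - 1) / ((m - 2) * (m - 3)) * ((m + 1) * g2 + 6.0)
    return _finalize(plug_in, loo)


def jackknife_correlation(x: Sequence[float], y: Sequence[float]) -> JackknifeResult:
    """Leave-one-pair-out jackknife of Fisher's z (transform per subsample)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InvalidInputError("jackknife_correlation: paired 1-d sequences required")
    n = x.size
    if n < 5:
        raise InvalidInputError(f"jackknife_correlation: need n >= 5, got {n}")
    xc = x - x.mean()
    yc = y - y.mean()
    Sx, Sy = xc.sum(), yc.sum()
    Sxx, Syy, Sxy = float(xc @ xc), float(yc @ yc), float(xc @ yc)
    m = n - 1
    sx = Sx - xc
    sy = Sy - yc
    sxx = Sxx - xc**2
    syy = Syy - yc**2
    sxy = Sxy - xc * yc
    cov = sxy - sx * sy / m
    vx = sxx - sx**2 / m
    vy = syy - sy**2 / m
    denom = vx * vy
    if np.any(denom <= 0):
        bad = int(np.argmax(denom <= 0))
        raise UndefinedStatisticError(
            f"jackknife_correlation: constant trait on leave-one-out subsample i={bad}"
        )
    r_loo = cov / np.sqrt(denom)
    if np.any(np.abs(r_loo) >= 1.0):
        bad = int(np.argmax(np.abs(r_loo) >= 1.0))
        raise MomentDomainError(
            f"jackknife_correlation: |r| = 1 on leave-one-out subsample i={bad}"
        )
    from .core_moments import pearson_correlation

    plug_in = fisher_z(pearson_correlation(x, y))
    return _finalize(plug_in, np.arctanh(r_loo))


def pooled_jackknife_contrast(
    j1: JackknifeResult,
    j2: JackknifeResult,
    point_method: Literal["plug_in", "jackknife_bias_corrected"] = "plug_in",
) -> tuple[float, float]:
    """Two-group contrast from per-group jackknives: points differenced,
    variances summed (independent groups)."""
    if point_method == "plug_in":
        est = j1.plug_in - j2.plug_in
    elif point_method == "jackknife_bias_corrected":
        est = j1.bias_corrected - j2.bias_corrected
    else:
        raise InvalidInputError(f"unknown point_method {point_method!r}")
    return est, j1.variance + j2.variance
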