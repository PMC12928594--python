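"""Random sampling from the Pearson distribution system by target moments.

The Pearson system covers every (skewness, kurtosis) pair above the
feasibility boundary beta2 > beta1 + 1 (beta1 = skewness^2, beta2 the
non-excess kurtosis, normal = 3). A target is specified by its first four
moments; the type is selected by the classical kappa criterion on
(beta1, beta2) and each type is sampled through its standard distributional
form, then relocated affinely to the requested mean and variance:

    normal          beta1 = 0, beta2 = 3
    II   symmetric beta        beta1 = 0, beta2 < 3
    VII  scaled Student t      beta1 = 0, beta2 > 3
    I    beta(p, q)            kappa < 0
    III  gamma                 2*beta2 - 3*beta1 - 6 = 0
    IV   [1+x^2]^-m exp(-v atan x)   0 < kappa < 1 (numeric CDF inversion)
    V    inverse gamma         kappa = 1
    VI   beta prime            kappa > 1

Type I/III/V parameters are closed-form in (beta1, beta2); VI is solved
numerically; IV has no elementary quantile and is inverted on a grid in the
angle variable theta = atan((x - lam)/a), where the density is proportional
to cos(theta)^(2m-2) * exp(-v*theta) on (-pi/2, pi/2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import optimize

from .errors import ConvergenceError, InvalidInputError, MomentDomainError

__all__ = [
    "MomentTarget",
    "classify_pearson_type",
    "sample_pearson",
    "sample_bivariate_normal",
    "spawn_rng",
]

PearsonType = Literal["normal", "I", "II", "III", "IV", "V", "VI", "VII"]

_TOL = 1e-10


@dataclass(frozen=True)
class MomentTarget:
    """Target first four moments; kurtosis is on the non-excess scale."""

    mean: float
    variance: float
    skewness: float
    kurtosis_non_excess: float

    def __post_init__(self) -> None:
        if self.variance <= 0:
            raise MomentDomainError(f"variance must be > 0 (got {self.variance})")
        b1 = self.skewness**2
        if self.kurtosis_non_excess <= b1 + 1 + _TOL:
            raise MomentDomainError(
                f"infeasible moment pair: kurtosis {self.kurtosis_non_excess} must "
                f"exceed skewness^2 + 1 = {b1 + 1} (Pearson feasibility boundary)"
            )

    @property
    def excess_kurtosis(self) -> float:
        return self.kurtosis_non_excess - 3.0


def classify_pearson_type(skewness: float, kurtosis_non_excess: float) -> PearsonType:
    """Pearson type from the kappa criterion on (beta1, beta2)."""
    b1 = skewness**2
    b2 = kurtosis_non_excess
    if b2 <= b1 + 1 + _TOL:
        raise MomentDomainError(
            f"infeasible pair (skewness={skewness}, kurtosis={b2}): requires "
            f"kurtosis > skewness^2 + 1"
        )
    if b1 < _TOL:
        if abs(b2 - 3.0) < _TOL:
            return "normal"
        return "II" if b2 < 3.0 else "VII"
    denom = 2.0 * b2 - 3.0 * b1 - 6.0
    if abs(denom) < _TOL:
        return "III"
    kappa = b1 * (b2 + 3.0) ** 2 / (4.0 * (4.0 * b2 - 3.0 * b1) * denom)
    if kappa < 0.0:
        return "I"
    if abs(kappa - 1.0) < _TOL:
        return "V"
    if kappa < 1.0:
        return "IV"
    return "VI"


def _standardize(z: np.ndarray, mean: float, var: float) -> np.ndarray:
    return (z - mean) / math.sqrt(var)


def _sample_type_I(n: int, g1: float, b2: float, rng: np.random.Generator) -> np.ndarray:
    # beta(p, q): p + q = r, q - p = d solved in closed form from (beta1, beta2)
    b1 = g1**2
    r = 6.0 * (b2 - b1 - 1.0) / (6.0 + 3.0 * b1 - 2.0 * b2)
    d2 = b1 * (r + 2.0) ** 2 * r**2 / (16.0 * (r + 1.0) + b1 * (r + 2.0) ** 2)
    d = math.copysign(math.sqrt(d2), g1)  # q > p gives positive skew
    p = (r - d) / 2.0
    q = (r + d) / 2.0
    if p <= 0 or q <= 0:
        raise MomentDomainError(
            f"Type I parameters non-positive (p={p:.4g}, q={q:.4g}) for "
            f"skewness={g1}, kurtosis={b2}"
        )
    z = rng.beta(p, q, size=n)
    mean = p / (p + q)
    var = p * q / ((p + q) ** 2 * (p + q + 1.0))
    return _standardize(z, mean, var)


def _sample_type_II(n: int, b2: float, rng: np.random.Generator) -> np.ndarray:
    a = (6.0 / (3.0 - b2) - 3.0) / 2.0
    if a <= 0:
        raise MomentDomainError(f"Type II shape non-positive for kurtosis={b2}")
    z = rng.beta(a, a, size=n)
    return _standardize(z, 0.5, 1.0 / (4.0 * (2.0 * a + 1.0)))


def _sample_type_III(n: int, g1: float, rng: np.random.Generator) -> np.ndarray:
    k = 4.0 / g1**2
    z = (rng.gamma(k, size=n) - k) / math.sqrt(k)
    return z if g1 > 0 else -z


def _sample_type_V(n: int, g1: float, b2: float, rng: np.random.Generator) -> np.ndarray:
    ag1 = abs(g1)
    alpha = 3.0 + (8.0 + 4.0 * math.sqrt(ag1**2 + 4.0)) / ag1**2
    if alpha <= 4.0:
        raise MomentDomainError("Type V shape must exceed 4 for finite kurtosis")
    implied_b2 = 3.0 + (30.0 * alpha - 66.0) / ((alpha - 3.0) * (alpha - 4.0))
    if abs(implied_b2 - b2) > 1e-6:
        raise MomentDomainError(
            f"(skewness={g1}, kurtosis={b2}) is off the Type V curve "
            f"(implied kurtosis {implied_b2:.6f})"
        )
    z = 1.0 / rng.gamma(alpha, size=n)
    mean = 1.0 / (alpha - 1.0)
    var = 1.0 / ((alpha - 1.0) ** 2 * (alpha - 2.0))
    z = _standardize(z, mean, var)
    return z if g1 > 0 else -z


def _betaprime_moments(alpha: float, beta: float) -> tuple[float, float, float, float]:
    """(mean, var, skewness, non-excess kurtosis) of beta-prime; needs beta > 4."""
    raw = [1.0]
    for k in range(1, 5):
        raw.append(raw[-1] * (alpha + k - 1.0) / (beta - k))
    mean = raw[1]
    m2 = raw[2] - mean**2
    m3 = raw[3] - 3 * mean * raw[2] + 2 * mean**3
    m4 = raw[4] - 4 * mean * raw[3] + 6 * mean**2 * raw[2] - 3 * mean**4
    return mean, m2, m3 / m2**1.5, m4 / m2**2


def _sample_type_VI(n: int, g1: float, b2: float, rng: np.random.Generator) -> np.ndarray:
    ag1 = abs(g1)

    def resid(logp: np.ndarray) -> np.ndarray:
        alpha = math.exp(logp[0])
        beta = 4.0 + math.exp(logp[1])
        _, _, sk, ku = _betaprime_moments(alpha, beta)
        return np.array([sk - ag1, ku - b2])

    sol = None
    for start in ([math.log(5.0), math.log(6.0)], [0.0, math.log(2.0)], [2.0, 2.0]):
        res = optimize.root(resid, np.array(start), method="hybr")
        if res.success and np.max(np.abs(res.fun)) < 1e-9:
            sol = res.x
            break
    if sol is None:
        raise ConvergenceError(
            f"Type VI parameter solve failed for skewness={g1}, kurtosis={b2}"
        )
    alpha = math.exp(sol[0])
    beta = 4.0 + math.exp(sol[1])
    y = rng.beta(alpha, beta, size=n)
    z = y / (1.0 - y)
    mean, var, _, _ = _betaprime_moments(alpha, beta)
    z = _standardize(z, mean, var)
    return z if g1 > 0 else -z


def _sample_type_VII(n: int, b2: float, rng: np.random.Generator) -> np.ndarray:
    nu = 4.0 + 6.0 / (b2 - 3.0)
    return rng.standard_t(nu, size=n) * math.sqrt((nu - 2.0) / nu)


#: grid resolution for the Type IV angle-space CDF; the cos^(2m-2) e^(-v t)
#: integrand is smooth on (-pi/2, pi/2) so Simpson on this grid resolves the
#: CDF far below the 1e-9 probability tolerance
_TYPE_IV_GRID = 40001


def _sample_type_IV(n: int, g1: float, b2: float, rng: np.random.Generator) -> np.ndarray:
    b1 = g1**2
    r = 6.0 * (b2 - b1 - 1.0) / (2.0 * b2 - 3.0 * b1 - 6.0)
    disc = 16.0 * (r - 1.0) - b1 * (r - 2.0) ** 2
    if r <= 2.0 or disc <= 0.0:
        raise MomentDomainError(
            f"Type IV parameterisation undefined for skewness={g1}, kurtosis={b2}"
        )
    m = (r + 2.0) / 2.0
    nu = -r * (r - 2.0) * math.sqrt(b1) / math.sqrt(disc)
    if g1 < 0:
        nu = -nu
    # scale/location for zero mean, unit variance
    a = r * math.sqrt((r - 1.0) / (r**2 + nu**2))
    lam = a * nu / r
    theta = np.linspace(-math.pi / 2.0, math.pi / 2.0, _TYPE_IV_GRID)
    with np.errstate(over="ignore"):
        log_f = (2.0 * m - 2.0) * np.log(np.cos(theta).clip(min=0.0) + 1e-300) - nu * theta
    f = np.exp(log_f - log_f.max())
    from scipy.integrate import cumulative_simpson

    cdf = cumulative_simpson(f, x=theta, initial=0.0)
    total = cdf[-1]
    if not np.isfinite(total) or total <= 0:
        raise ConvergenceError("Type IV CDF normalisation failed")
    cdf /= total
    cdf = np.maximum.accumulate(cdf)
    u = rng.random(n)
    t = np.interp(u, cdf, theta)
    x = lam + a * np.tan(t)
    return x


def sample_pearson(n: int, target: MomentTarget, rng: np.random.Generator) -> np.ndarray:
    """Draw n iid values whose population moments equal ``target``."""
    if n < 1:
        raise InvalidInputError(f"sample_pearson: n >= 1 required, got {n}")
    g1 = target.skewness
    b2 = target.kurtosis_non_excess
    ptype = classify_pearson_type(g1, b2)
    if ptype == "normal":
        z = rng.standard_normal(n)
    elif ptype == "I":
        z = _sample_type_I(n, g1, b2, rng)
    elif ptype == "II":
        z = _sample_type_II(n, b2, rng)
    elif ptype == "III":
        z = _sample_type_III(n, g1, rng)
    elif ptype == "IV":
        z = _sample_type_IV(n, g1, b2, rng)
    elif ptype == "V":
        z = _sample_type_V(n, g1, b2, rng)
    elif ptype == "VI":
        z = _sample_type_VI(n, g1, b2, rng)
    else:
        z = _sample_type_VII(n, b2, rng)
    return target.mean + math.sqrt(target.variance) * z


def sample_bivariate_normal(
    n: int, r: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """n draws from a bivariate normal with standard-normal marginals and
    population correlation r (Cholesky construction)."""
    if not -1.0 <= r <= 1.0:
        raise InvalidInputError(f"sample_bivariate_normal: |r| <= 1 required, got {r}")
    if n < 1:
        raise InvalidInputError(f"sample_bivariate_normal: n >= 1 required, got {n}")
    z1 = rng.standard_normal(n)
    z2 = rng.standard_normal(n)
    y = r * z1 + math.sqrt(max(0.0, 1.0 - r * r)) * z2
    return z1, y


def spawn_rng(root_seed: int, *keys: int | str) -> np.random.Generator:
    """Independent, reproducible stream identified by (root_seed, *keys).

    String keys are hashed stably (CRC32) so scenario ids can key streams;
    the stream is a pure function of its arguments.
    """
    import zlib

    ints = [int(root_seed) & 0x7FFFFFFF]
    for k in keys:
        if isinstance(k, str):
            ints.append(zlib.crc32(k.encode("utf-8")))
        else:
            ints.append(int(k) & 0xFFFFFFFF)
    return np.random.default_rng(np.random.SeedSequence(ints))
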