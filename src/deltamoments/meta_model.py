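"""Random-effects meta-analysis with additive crossed variance components.

Model: y_i = mu + sum_f u_{f, level_f(i)} + e_i, with e_i ~ N(0, v_i) for
known per-effect sampling variances v_i and independent normal random
effects u_f with variance tau2_f per factor f. With a single factor whose
levels are the effect ids, this is the standard random-effects model.

Two weighting schemes:

* ``inverse_variance`` — REML estimation of the tau2 components, GLS pooled
  mean and Wald interval. The default for dsk and dZr.
* ``sample_size`` — weights proportional to the effective sample size
  ntilde = n1*n2/(n1+n2). Used when the sampling variances themselves are
  untrustworthy (the dku case: its analytic variance assumes normality and
  its jackknife variance yields skewed sampling distributions). tau2 comes
  from a method-of-moments identity on the weighted residual sum of squares
  and the pooled SE from the weighted residual variance (sandwich form), so
  neither depends on trusting the v_i as weights.

Heterogeneity is reported as I^2 per component on the percent scale:

    I2_f = tau2_f / (sum_g tau2_g + s2_typ) * 100

where s2_typ = (k-1) sum(w) / [ (sum w)^2 - sum(w^2) ], w = 1/v_i, is the
typical within-study sampling variance; components sum to the total.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
from scipy import optimize, stats

from .effect_sizes import EffectSize
from .errors import ConvergenceError, InvalidInputError

__all__ = [
    "MetaInput",
    "MetaResult",
    "random_effects_meta",
    "i_squared",
    "typical_sampling_variance",
]


@dataclass(frozen=True)
class MetaInput:
    """Effects to pool plus the random-factor level labels per effect.

    ``factors`` maps a factor name (e.g. "phenotyping_center") to the
    per-effect level labels, aligned with ``effects``. When empty, a single
    "effect_id" factor with one level per effect is assumed (standard
    random-effects heterogeneity).
    """

    effects: Sequence[EffectSize]
    factors: dict[str, Sequence[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        k = len(self.effects)
        if k < 1:
            raise InvalidInputError("MetaInput: at least one effect required")
        kinds = {e.effect_kind for e in self.effects}
        if len(kinds) > 1:
            raise InvalidInputError(
                f"MetaInput: effects must share one kind, got {sorted(kinds)}"
            )
        for name, levels in self.factors.items():
            if len(levels) != k:
                raise InvalidInputError(
                    f"MetaInput: factor {name!r} has {len(levels)} labels for {k} effects"
                )

    @classmethod
    def from_effects(cls, effects: Sequence[EffectSize], factor_names: Sequence[str] = ()) -> "MetaInput":
        """Pull factor levels out of the effects' stratum tags."""
        factors = {}
        for name in factor_names:
            levels = []
            for e in effects:
                tags = e.stratum_labels or {}
                if name not in tags:
                    raise InvalidInputError(
                        f"MetaInput: effect missing stratum tag {name!r}"
                    )
                levels.append(tags[name])
            factors[name] = levels
        return cls(effects=effects, factors=factors)


@dataclass(frozen=True)
class MetaResult:
    pooled_estimate: float
    pooled_se: float
    ci: tuple[float, float]
    tau2_components: dict[str, float]
    i2_total: float
    i2_components: dict[str, float]
    k: int
    weighting: Literal["inverse_variance", "sample_size"]
    level: float = 0.95
    note: str = ""

    @property
    def tau2_total(self) -> float:
        return sum(self.tau2_components.values())


def typical_sampling_variance(v: np.ndarray) -> float:
    """Higgins' typical within-study variance s2_typ from the v_i."""
    w = 1.0 / v
    sw = w.sum()
    return float((v.size - 1) * sw / (sw**2 - (w**2).sum()))


def _design(factors: dict[str, Sequence[str]], k: int) -> dict[str, np.ndarray]:
    """Indicator matrices Z_f (k x levels) per factor."""
    out = {}
    for name, labels in factors.items():
        levels = sorted(set(map(str, labels)))
        Z = np.zeros((k, len(levels)))
        idx = {lv: j for j, lv in enumerate(levels)}
        for i, lab in enumerate(labels):
            Z[i, idx[str(lab)]] = 1.0
        out[name] = Z
    return out


def _neg2_reml(tau2: np.ndarray, y: np.ndarray, v: np.ndarray, Zs: list[np.ndarray]) -> float:
    k = y.size
    V = np.diag(v.copy())
    for t2, Z in zip(tau2, Zs):
        V += t2 * (Z @ Z.T)
    try:
        L = np.linalg.cholesky(V)
    except np.linalg.LinAlgError:
        return np.inf
    logdetV = 2.0 * np.sum(np.log(np.diag(L)))
    Vinv_y = np.linalg.solve(V, y)
    Vinv_1 = np.linalg.solve(V, np.ones(k))
    xvx = float(np.ones(k) @ Vinv_1)
    mu = float(np.ones(k) @ Vinv_y) / xvx
    resid = y - mu
    quad = float(resid @ np.linalg.solve(V, resid))
    return logdetV + math.log(xvx) + quad


def _fit_reml(
    y: np.ndarray, v: np.ndarray, factors: dict[str, Sequence[str]]
) -> tuple[dict[str, float], float, float]:
    """REML variance components; returns (tau2 per factor, mu, se(mu))."""
    names = list(factors)
    Zmats = _design(factors, y.size)
    Zs = [Zmats[n] for n in names]
    scale = max(float(np.var(y)), float(np.mean(v)), 1e-8)
    obj = lambda t2: _neg2_reml(t2, y, v, Zs)
    best = None
    for start_frac in (0.5, 0.05, 1.5):
        x0 = np.full(len(names), start_frac * scale)
        res = optimize.minimize(
            obj,
            x0,
            method="L-BFGS-B",
            bounds=[(0.0, None)] * len(names),
            options={"maxiter": 500},
        )
        if res.success and (best is None or res.fun < best.fun - 1e-10):
            best = res
    if best is None:
        raise ConvergenceError(
            "REML did not converge from any starting point; variance components "
            "may be unidentifiable for this factor structure"
        )
    tau2 = {n: float(t) for n, t in zip(names, best.x)}
    V = np.diag(v.copy())
    for n, Z in zip(names, Zs):
        V += tau2[n] * (Z @ Z.T)
    Vinv_1 = np.linalg.solve(V, np.ones(y.size))
    xvx = float(np.ones(y.size) @ Vinv_1)
    mu = float(Vinv_1 @ y) / xvx
    se = math.sqrt(1.0 / xvx)
    return tau2, mu, se


def _fit_sample_size(
    y: np.ndarray, v: np.ndarray, ntilde: np.ndarray
) -> tuple[float, float, float]:
    """n-weighted pooled mean, sandwich SE, and generalized-MoM tau2.

    tau2 solves E[Q_w] = sum(w_i (v_i + tau2)) - sum(w_i^2 (v_i + tau2))/W
    for Q_w = sum w_i (y_i - ybar_w)^2, the DerSimonian-Laird identity with
    arbitrary fixed weights.
    """
    w = ntilde / ntilde.sum()
    mu = float(w @ y)
    k = y.size
    resid = y - mu
    se = math.sqrt(float(np.sum(w**2 * resid**2)) * k / max(k - 1, 1))
    W = w.sum()  # = 1
    Q = float(np.sum(w * resid**2))
    c = float(np.sum(w) - np.sum(w**2) / W)
    a = float(np.sum(w * v) - np.sum(w**2 * v) / W)
    tau2 = max(0.0, (Q - a) / c) if c > 0 else 0.0
    return mu, se, tau2


def i_squared(
    tau2_components: dict[str, float], s2_typical: float
) -> tuple[float, dict[str, float]]:
    """Per-component and total I^2 (%) from variance components."""
    total_tau2 = sum(tau2_components.values())
    denom = total_tau2 + s2_typical
    if denom <= 0:
        return 0.0, {n: 0.0 for n in tau2_components}
    comps = {n: 100.0 * t / denom for n, t in tau2_components.items()}
    return sum(comps.values()), comps


def random_effects_meta(
    data: MetaInput | Sequence[EffectSize],
    weighting: Optional[Literal["inverse_variance", "sample_size"]] = None,
    level: float = 0.95,
) -> MetaResult:
    """Pool effect sizes under a random-effects model.

    ``weighting`` defaults to inverse-variance, except for ``delta_ku``
    effects where sample-size weighting is the default (its sampling
    variances are unreliable).
    """
    if not isinstance(data, MetaInput):
        data = MetaInput(effects=list(data))
    if not 0.0 < level < 1.0:
        raise InvalidInputError(f"level must be in (0, 1), got {level}")
    effects = list(data.effects)
    kind = effects[0].effect_kind
    if weighting is None:
        weighting = "sample_size" if kind == "delta_ku" else "inverse_variance"
    y = np.array([e.estimate for e in effects])
    v = np.array([e.sampling_variance for e in effects])
    if np.any(v <= 0):
        raise InvalidInputError("all sampling variances must be > 0 for pooling")
    k = y.size
    zq = stats.norm.ppf(0.5 + level / 2.0)

    if k == 1:
        e = effects[0]
        se = math.sqrt(e.sampling_variance)
        return MetaResult(
            pooled_estimate=e.estimate,
            pooled_se=se,
            ci=(e.estimate - zq * se, e.estimate + zq * se),
            tau2_components={"effect_id": 0.0},
            i2_total=0.0,
            i2_components={"effect_id": 0.0},
            k=1,
            weighting=weighting,
            level=level,
            note="single effect: pooled estimate is the effect itself, tau2 = 0",
        )

    factors = dict(data.factors)
    if not factors:
        factors = {"effect_id": [str(i) for i in range(k)]}
    s2_typ = typical_sampling_variance(v)

    if weighting == "inverse_variance":
        tau2, mu, se = _fit_reml(y, v, factors)
    elif weighting == "sample_size":
        ntilde = np.array([e.effective_n for e in effects])
        mu, se, t2 = _fit_sample_size(y, v, ntilde)
        tau2 = {"total": t2}
    else:
        raise InvalidInputError(f"unknown weighting {weighting!r}")

    i2_total, i2_comps = i_squared(tau2, s2_typ)
    return MetaResult(
        pooled_estimate=mu,
        pooled_se=se,
        ci=(mu - zq * se, mu + zq * se),
        tau2_components=tau2,
        i2_total=i2_total,
        i2_components=i2_comps,
        k=k,
        weighting=weighting,
        level=level,
    )
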