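"""Monte-Carlo performance evaluation of the contrast estimators.

Builds scenario grids (two-group moment targets or correlation targets
crossed with per-group sample sizes), runs seeded replicates, and summarises
estimator performance with the standard simulation-study metrics:

    bias          mean(theta_hat) - theta
    rel_var_bias  [mean(v_hat) - Var_MC(theta_hat)] / Var_MC(theta_hat)
    coverage      fraction of nominal Wald intervals containing theta

each with its Monte-Carlo standard error. Four estimator pairings are
evaluated per replicate: {analytic, jackknife bias-corrected} points crossed
with {analytic, jackknife} variances.

Default grids: the skewness family crosses ordered pairs from
sk in {-1, -0.5, 0, 0.5, 1} (kurtosis fixed at 3) with equal/unequal group
variances and equal/unequal group means (100 scenarios), at each of 12
sample sizes n in {10, 20, ..., 100, 150, 500} (1,200 cells); the kurtosis
family likewise with ku in {2.5, 3, 4, 5, 6} at skewness 0; the correlation
family crosses ordered pairs from r in {-0.8, -0.4, -0.2, 0, 0.2, 0.4, 0.6,
0.8} (64 scenarios, 768 cells) under bivariate-normal sampling with
standard-normal marginals.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_moments import (
    fisher_z,
    fisher_z_variance,
    kurtosis_sampling_variance,
    skewness_sampling_variance,
)
from .errors import ConfigError, DeltaMomentsError, InvalidInputError
from .meta_model import MetaInput, random_effects_meta
from .effect_sizes import EffectSize
from .pearson_system import (
    MomentTarget,
    sample_bivariate_normal,
    sample_pearson,
    spawn_rng,
)
from .resampling import jackknife_correlation, jackknife_moment

__all__ = [
    "Scenario",
    "ReplicateResult",
    "PerformanceSummary",
    "DEFAULT_GRIDS",
    "build_scenarios",
    "run_scenario",
    "summarize_performance",
    "run_study",
    "run_meta_performance",
    "PAIRINGS",
]

logger = logging.getLogger(__name__)

Family = Literal["skew_family", "kurt_family", "zr_family"]

#: (point estimator, variance estimator) pairings evaluated per replicate
PAIRINGS = [
    ("analytic", "analytic"),
    ("analytic", "jackknife"),
    ("jackknife_bc", "analytic"),
    ("jackknife_bc", "jackknife"),
]

DEFAULT_GRIDS = {
    "skew_values": [-1.0, -0.5, 0.0, 0.5, 1.0],
    "kurt_values": [2.5, 3.0, 4.0, 5.0, 6.0],
    "r_values": [-0.8, -0.4, -0.2, 0.0, 0.2, 0.4, 0.6, 0.8],
    "n_values": [10, 20, 30, 40, 50, 60, 70, 80, 90, 100, 150, 500],
    "variance_conditions": ["equal", "unequal"],  # unequal: group 2 variance doubled
    "mean_conditions": ["equal", "unequal"],  # unequal: group 2 mean 5 vs 0
}

_CONFIG_KEYS = {
    "families",
    "skew_values",
    "kurt_values",
    "r_values",
    "n_values",
    "variance_conditions",
    "mean_conditions",
    "reps",
    "nominal_level",
    "seed",
}


@dataclass(frozen=True)
class Scenario:
    """One grid cell: a family, per-group targets, and a per-group n."""

    family: Family
    group1: MomentTarget | float  # MomentTarget for moment families, r for zr
    group2: MomentTarget | float
    n_per_group: int
    scenario_id: str

    @property
    def true_effect(self) -> float:
        """The population contrast implied by the targets.

        On the excess scale for kurtosis (the non-excess offsets cancel in
        the difference), and on the Fisher-z scale for correlations.
        """
        if self.family == "zr_family":
            return math.atanh(self.group1) - math.atanh(self.group2)
        if self.family == "skew_family":
            return self.group1.skewness - self.group2.skewness
        return self.group1.kurtosis_non_excess - self.group2.kurtosis_non_excess


@dataclass(frozen=True)
class ReplicateResult:
    scenario_id: str
    replicate_id: int
    estimate_analytic: float = math.nan
    estimate_jackknife_bc: float = math.nan
    variance_analytic: float = math.nan
    variance_jackknife: float = math.nan
    error: str = ""  # reason code; empty when the replicate succeeded

    @property
    def ok(self) -> bool:
        return not self.error


@dataclass(frozen=True)
class PerformanceSummary:
    scenario_id: str
    estimator_pairing: str
    n_reps_effective: int
    bias: float
    bias_mcse: float
    rel_var_bias: float
    rel_var_bias_mcse: float
    coverage: float
    coverage_mcse: float


def _validate_config(config: dict) -> dict:
    unknown = set(config) - _CONFIG_KEYS
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    cfg = {**DEFAULT_GRIDS, "families": ["skew_family", "kurt_family", "zr_family"]}
    cfg.update(config)
    for fam in cfg["families"]:
        if fam not in ("skew_family", "kurt_family", "zr_family"):
            raise ConfigError(f"unknown family {fam!r} in config key 'families'")
    for key in ("n_values",):
        if not cfg[key] or any(int(n) < 4 for n in cfg[key]):
            raise ConfigError(f"config key {key!r} must list integers >= 4")
    for key in ("variance_conditions", "mean_conditions"):
        bad = set(cfg[key]) - {"equal", "unequal"}
        if bad:
            raise ConfigError(f"config key {key!r} has invalid entries {sorted(bad)}")
    return cfg


def _moment_pair(
    family: Family, v1: float, v2: float, cond_var: str, cond_mean: str
) -> tuple[MomentTarget, MomentTarget]:
    mean2 = 5.0 if cond_mean == "unequal" else 0.0
    var2 = 2.0 if cond_var == "unequal" else 1.0
    if family == "skew_family":
        t1 = MomentTarget(0.0, 1.0, v1, 3.0)
        t2 = MomentTarget(mean2, var2, v2, 3.0)
    else:
        t1 = MomentTarget(0.0, 1.0, 0.0, v1)
        t2 = MomentTarget(mean2, var2, 0.0, v2)
    return t1, t2


def build_scenarios(config: Optional[dict] = None) -> list[Scenario]:
    """Deterministic, sorted enumeration of the configured grid cells."""
    cfg = _validate_config(config or {})
    scenarios: list[Scenario] = []
    for family in cfg["families"]:
        if family == "zr_family":
            for n in cfg["n_values"]:
                for r1 in cfg["r_values"]:
                    for r2 in cfg["r_values"]:
                        sid = f"zr|r1={r1:g},r2={r2:g}|n={n}"
                        scenarios.append(
                            Scenario("zr_family", float(r1), float(r2), int(n), sid)
                        )
        else:
            values = cfg["skew_values" if family == "skew_family" else "kurt_values"]
            tag = "sk" if family == "skew_family" else "ku"
            for n in cfg["n_values"]:
                for v1 in values:
                    for v2 in values:
                        for cv in cfg["variance_conditions"]:
                            for cm in cfg["mean_conditions"]:
                                sid = (
                                    f"{tag}|{tag}1={v1:g},{tag}2={v2:g}"
                                    f"|var={cv}|mean={cm}|n={n}"
                                )
                                t1, t2 = _moment_pair(family, v1, v2, cv, cm)
                                scenarios.append(
                                    Scenario(family, t1, t2, int(n), sid)
                                )
    return scenarios


def _replicate_moment(
    s: Scenario, rep: int, rng: np.random.Generator
) -> ReplicateResult:
    kind = "skewness" if s.family == "skew_family" else "excess_kurtosis"
    avar_fn = (
        skewness_sampling_variance
        if s.family == "skew_family"
        else kurtosis_sampling_variance
    )
    x1 = sample_pearson(s.n_per_group, s.group1, rng)
    x2 = sample_pearson(s.n_per_group, s.group2, rng)
    try:
        j1 = jackknife_moment(x1, kind)
        j2 = jackknife_moment(x2, kind)
    except DeltaMomentsError as exc:
        return ReplicateResult(s.scenario_id, rep, error=type(exc).__name__)
    return ReplicateResult(
        scenario_id=s.scenario_id,
        replicate_id=rep,
        estimate_analytic=j1.plug_in - j2.plug_in,
        estimate_jackknife_bc=j1.bias_corrected - j2.bias_corrected,
        variance_analytic=avar_fn(s.n_per_group) * 2.0,
        variance_jackknife=j1.variance + j2.variance,
    )


def _replicate_zr(s: Scenario, rep: int, rng: np.random.Generator) -> ReplicateResult:
    x1, y1 = sample_bivariate_normal(s.n_per_group, s.group1, rng)
    x2, y2 = sample_bivariate_normal(s.n_per_group, s.group2, rng)
    try:
        j1 = jackknife_correlation(x1, y1)
        j2 = jackknife_correlation(x2, y2)
    except DeltaMomentsError as exc:
        return ReplicateResult(s.scenario_id, rep, error=type(exc).__name__)
    return ReplicateResult(
        scenario_id=s.scenario_id,
        replicate_id=rep,
        estimate_analytic=j1.plug_in - j2.plug_in,
        estimate_jackknife_bc=j1.bias_corrected - j2.bias_corrected,
        variance_analytic=fisher_z_variance(s.n_per_group) * 2.0,
        variance_jackknife=j1.variance + j2.variance,
    )


def run_scenario(s: Scenario, reps: int, root_seed: int) -> list[ReplicateResult]:
    """Run ``reps`` seeded replicates of one scenario.

    The stream for replicate j is a pure function of (root_seed,
    scenario_id, j), so results are reproducible and resumable.
    """
    if reps < 1:
        raise InvalidInputError(f"reps >= 1 required, got {reps}")
    fn = _replicate_zr if s.family == "zr_family" else _replicate_moment
    out = []
    for j in range(reps):
        rng = spawn_rng(root_seed, s.scenario_id, j)
        out.append(fn(s, j, rng))
    n_fail = sum(1 for r in out if not r.ok)
    if n_fail:
        logger.warning("scenario %s: %d/%d replicates failed", s.scenario_id, n_fail, reps)
    if n_fail > reps / 2:
        raise DeltaMomentsError(
            f"scenario {s.scenario_id}: more than half of replicates failed "
            f"({n_fail}/{reps})"
        )
    return out


def summarize_performance(
    results: Sequence[ReplicateResult],
    truth: float,
    nominal_level: float = 0.95,
) -> list[PerformanceSummary]:
    """Per-pairing bias / relative variance bias / coverage with MCSEs."""
    ok = [r for r in results if r.ok]
    if len(ok) < 2:
        raise InvalidInputError("summarize_performance: need >= 2 effective replicates")
    R = len(ok)
    sid = ok[0].scenario_id
    zq = stats.norm.ppf(0.5 + nominal_level / 2.0)
    points = {
        "analytic": np.array([r.estimate_analytic for r in ok]),
        "jackknife_bc": np.array([r.estimate_jackknife_bc for r in ok]),
    }
    variances = {
        "analytic": np.array([r.variance_analytic for r in ok]),
        "jackknife": np.array([r.variance_jackknife for r in ok]),
    }
    out = []
    for pm, vm in PAIRINGS:
        est = points[pm]
        v = variances[vm]
        var_mc = float(np.var(est, ddof=1))
        bias = float(est.mean()) - truth
        bias_mcse = math.sqrt(var_mc / R)
        if var_mc > 0:
            rel = float(v.mean()) / var_mc - 1.0
            # delta-method MCSE: variation of mean(v_hat) plus the empirical
            # variance's own MC noise (~ sqrt(2/(R-1)) relative under normality)
            rel_mcse = (float(v.mean()) / var_mc) * math.sqrt(
                float(np.var(v, ddof=1)) / (R * float(v.mean()) ** 2) + 2.0 / (R - 1)
            )
        else:
            rel, rel_mcse = math.nan, math.nan
        half = zq * np.sqrt(v)
        hits = np.abs(est - truth) <= half
        cov = float(hits.mean())
        out.append(
            PerformanceSummary(
                scenario_id=sid,
                estimator_pairing=f"{pm}+{vm}",
                n_reps_effective=R,
                bias=bias,
                bias_mcse=bias_mcse,
                rel_var_bias=rel,
                rel_var_bias_mcse=rel_mcse,
                coverage=cov,
                coverage_mcse=math.sqrt(cov * (1.0 - cov) / R),
            )
        )
    return out


_CACHE_COLUMNS = [
    "scenario_id", "family", "n_per_group", "true_effect", "estimator_pairing",
    "n_reps_effective", "bias", "bias_mcse", "rel_var_bias", "rel_var_bias_mcse",
    "coverage", "coverage_mcse",
]


def _cache_key(config: dict, root_seed: int, reps: int, scenario_id: str) -> str:
    payload = json.dumps(
        {"config": config, "seed": root_seed, "reps": reps, "scenario": scenario_id},
        sort_keys=True, default=str,
    )
    return hashlib.sha1(payload.encode()).hexdigest()[:16]


def run_study(
    config: Optional[dict] = None,
    root_seed: int = 0,
    reps: int = 2500,
    nominal_level: float = 0.95,
    cache_dir: Optional[str] = None,
    out_csv: Optional[str] = None,
) -> pd.DataFrame:
    """Run every configured scenario and return a tidy performance table.

    One row per (scenario, estimator pairing). With ``cache_dir`` set,
    per-scenario results are cached keyed on (config, seed, reps,
    scenario id); a cached file with the wrong schema is a hard error.
    """
    from pathlib import Path

    cfg = _validate_config(config or {})
    scenarios = build_scenarios(config or {})
    logger.info("running %d scenario cells x %d reps", len(scenarios), reps)
    frames = []
    for s in scenarios:
        cache_path = None
        if cache_dir is not None:
            key = _cache_key(cfg, root_seed, reps, s.scenario_id)
            cache_path = Path(cache_dir) / f"scenario_{key}.csv"
            if cache_path.exists():
                cached = pd.read_csv(cache_path)
                if list(cached.columns) != _CACHE_COLUMNS:
                    raise ConfigError(
                        f"cache schema mismatch in {cache_path}; delete the cache "
                        "directory and re-run"
                    )
                frames.append(cached)
                continue
        results = run_scenario(s, reps, root_seed)
        rows = []
        for p in summarize_performance(results, s.true_effect, nominal_level):
            rows.append(
                {
                    "scenario_id": s.scenario_id,
                    "family": s.family,
                    "n_per_group": s.n_per_group,
                    "true_effect": s.true_effect,
                    "estimator_pairing": p.estimator_pairing,
                    "n_reps_effective": p.n_reps_effective,
                    "bias": p.bias,
                    "bias_mcse": p.bias_mcse,
                    "rel_var_bias": p.rel_var_bias,
                    "rel_var_bias_mcse": p.rel_var_bias_mcse,
                    "coverage": p.coverage,
                    "coverage_mcse": p.coverage_mcse,
                }
            )
        frame = pd.DataFrame(rows, columns=_CACHE_COLUMNS)
        if cache_path is not None:
            cache_path.parent.mkdir(parents=True, exist_ok=True)
            frame.to_csv(cache_path, index=False)
        frames.append(frame)
    table = pd.concat(frames, ignore_index=True)
    if out_csv is not None:
        table.to_csv(out_csv, index=False)
    return table


_META_CONFIG_KEYS = {
    "effect", "k", "n", "mu", "tau2", "meta_reps", "weighting", "base_r2",
    "base_target2",
}


def run_meta_performance(
    config: dict,
    root_seed: int = 0,
) -> pd.DataFrame:
    """Evaluate pooled-estimate bias/coverage and tau2 recovery.

    Each meta-replicate simulates ``k`` two-group studies whose true
    per-study effect is mu + N(0, tau2), realised by shifting group 1's
    target on the effect scale against a fixed group 2; per-study effects
    use the recommended estimator pairing and are pooled with
    :func:`deltamoments.meta_model.random_effects_meta`.
    """
    unknown = set(config) - _META_CONFIG_KEYS
    if unknown:
        raise ConfigError(f"unknown meta-performance config keys: {sorted(unknown)}")
    effect = config.get("effect", "delta_zr")
    if effect not in ("delta_sk", "delta_ku", "delta_zr"):
        raise ConfigError(f"unknown effect {effect!r}")
    k = int(config.get("k", 20))
    n = int(config.get("n", 100))
    mu = float(config.get("mu", 0.0))
    tau2 = float(config.get("tau2", 0.0))
    meta_reps = int(config.get("meta_reps", 200))
    weighting = config.get("weighting")
    level = 0.95

    from .effect_sizes import delta_kurtosis, delta_skewness, delta_zr as dzr_fn
    from .core_moments import GroupSample

    pooled_est = np.empty(meta_reps)
    pooled_hit = np.empty(meta_reps, dtype=bool)
    tau2_hat = np.empty(meta_reps)
    for m in range(meta_reps):
        effects = []
        for i in range(k):
            rng = spawn_rng(root_seed, f"meta-{effect}", m, i)
            theta_i = mu + math.sqrt(tau2) * rng.standard_normal()
            if effect == "delta_zr":
                r2 = float(config.get("base_r2", 0.0))
                r1 = math.tanh(theta_i + math.atanh(r2))
                x1, y1 = sample_bivariate_normal(n, r1, rng)
                x2, y2 = sample_bivariate_normal(n, r2, rng)
                e = dzr_fn(
                    GroupSample(x1, y1, "g1"), GroupSample(x2, y2, "g2"),
                )
            else:
                if effect == "delta_sk":
                    sk2, ku2 = 0.0, 3.0
                    sk1 = max(-1.3, min(1.3, sk2 + theta_i))
                    t1 = MomentTarget(0.0, 1.0, sk1, ku2)
                    t2 = MomentTarget(0.0, 1.0, sk2, ku2)
                    fn = delta_skewness
                else:
                    sk, ku2 = 0.0, 3.0
                    ku1 = max(1.2, ku2 + theta_i)
                    t1 = MomentTarget(0.0, 1.0, sk, ku1)
                    t2 = MomentTarget(0.0, 1.0, sk, ku2)
                    fn = delta_kurtosis
                x1 = sample_pearson(n, t1, rng)
                x2 = sample_pearson(n, t2, rng)
                e = fn(GroupSample(x1, label="g1"), GroupSample(x2, label="g2"))
            effects.append(e)
        res = random_effects_meta(MetaInput(effects=effects), weighting=weighting, level=level)
        pooled_est[m] = res.pooled_estimate
        pooled_hit[m] = res.ci[0] <= mu <= res.ci[1]
        tau2_hat[m] = res.tau2_total
    cov = float(pooled_hit.mean())
    return pd.DataFrame(
        [
            {
                "effect": effect,
                "k": k,
                "n": n,
                "mu": mu,
                "tau2": tau2,
                "meta_reps": meta_reps,
                "pooled_bias": float(pooled_est.mean()) - mu,
                "pooled_bias_mcse": float(pooled_est.std(ddof=1)) / math.sqrt(meta_reps),
                "pooled_coverage": cov,
                "pooled_coverage_mcse": math.sqrt(cov * (1 - cov) / meta_reps),
                "tau2_hat_mean": float(tau2_hat.mean()),
                "tau2_hat_mcse": float(tau2_hat.std(ddof=1)) / math.sqrt(meta_reps),
            }
        ]
    )
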