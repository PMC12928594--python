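"""Tabular I/O, per-stratum effect computation, and a synthetic fixture
generator emulating a multi-center, two-sex phenotyping dataset.

Input is long (tidy) format: one row per individual with a group column,
one or two trait columns, and optional stratum columns (e.g. phenotyping
center, strain). Effects are computed separately per stratum, matching how
such datasets are meta-analysed (one effect size per center x strain cell,
pooled downstream with the strata as random factors).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core_moments import GroupSample, RECOMMENDED_MIN_N
from .effect_sizes import (
    DependenceSpec,
    EffectSize,
    delta_kurtosis,
    delta_skewness,
    delta_zr,
    effects_to_frame,
    ln_rr,
    ln_vr,
)
from .errors import ConfigError, DeltaMomentsError, InvalidInputError
from .pearson_system import MomentTarget, sample_pearson, spawn_rng

__all__ = [
    "StudyTable",
    "read_study_table",
    "compute_effects",
    "generate_fixture",
    "DEFAULT_FIXTURE_CONFIG",
]

logger = logging.getLogger(__name__)


@dataclass
class StudyTable:
    """Parsed long-format individual data with exactly two groups."""

    data: pd.DataFrame
    group_col: str
    trait_cols: list[str]
    stratum_cols: list[str]
    group_labels: tuple[str, str]
    n_dropped: int = 0

    def strata(self) -> list[dict[str, str]]:
        """Distinct stratum combinations, sorted for determinism."""
        if not self.stratum_cols:
            return [{}]
        combos = (
            self.data[self.stratum_cols]
            .drop_duplicates()
            .sort_values(self.stratum_cols)
        )
        return [dict(zip(self.stratum_cols, map(str, row))) for row in combos.itertuples(index=False)]

    def group_samples(
        self, stratum: dict[str, str], paired: bool
    ) -> tuple[GroupSample, GroupSample]:
        sub = self.data
        for col, val in stratum.items():
            sub = sub[sub[col].astype(str) == val]
        out = []
        for lab in self.group_labels:
            rows = sub[sub[self.group_col].astype(str) == lab]
            if paired:
                if len(self.trait_cols) < 2:
                    raise InvalidInputError(
                        "paired effect requested but only one trait column mapped"
                    )
                out.append(
                    GroupSample(
                        rows[self.trait_cols[0]].to_numpy(float),
                        rows[self.trait_cols[1]].to_numpy(float),
                        label=lab,
                    )
                )
            else:
                out.append(
                    GroupSample(rows[self.trait_cols[0]].to_numpy(float), label=lab)
                )
        return out[0], out[1]


def read_study_table(
    path: str | Path,
    group_col: str,
    trait_cols: Sequence[str],
    stratum_cols: Sequence[str] = (),
    group_order: Optional[Sequence[str]] = None,
    sep: str = ",",
) -> StudyTable:
    """Read a delimited long-format table and validate the column mapping.

    Rows with unparseable or missing trait values are dropped and counted
    (``n_dropped``); more or fewer than two distinct group labels is an
    error. ``group_order`` fixes which label is group 1 (the sign
    convention: positive effects mean group 1 exceeds group 2); by default
    labels are taken in sorted order.
    """
    df = pd.read_csv(path, sep=sep)
    needed = [group_col, *trait_cols, *stratum_cols]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ConfigError(f"missing columns in {path}: {missing}")
    for c in trait_cols:
        df[c] = pd.to_numeric(df[c], errors="coerce")
    before = len(df)
    df = df.dropna(subset=list(trait_cols)).reset_index(drop=True)
    n_dropped = before - len(df)
    if n_dropped:
        logger.info("dropped %d rows with missing/unparseable trait values", n_dropped)
    labels = sorted(df[group_col].astype(str).unique())
    if len(labels) != 2:
        raise InvalidInputError(
            f"expected exactly 2 group labels in column {group_col!r}, "
            f"found {len(labels)}: {labels}"
        )
    if group_order is not None:
        go = [str(g) for g in group_order]
        if sorted(go) != labels:
            raise InvalidInputError(
                f"group_order {go} does not match labels present {labels}"
            )
        labels = go
    return StudyTable(
        data=df,
        group_col=group_col,
        trait_cols=list(trait_cols),
        stratum_cols=list(stratum_cols),
        group_labels=(labels[0], labels[1]),
        n_dropped=n_dropped,
    )


_KIND_ALIASES = {
    "dsk": "delta_sk",
    "dku": "delta_ku",
    "dzr": "delta_zr",
    "lnrr": "lnRR",
    "lnvr": "lnVR",
}


def compute_effects(
    table: StudyTable,
    kinds: Sequence[str],
    dep: DependenceSpec = DependenceSpec(),
    swap_groups: bool = False,
) -> pd.DataFrame:
    """One effect-size row per stratum x kind; failures become NA rows with
    a reason code rather than aborting the whole table."""
    kinds = [_KIND_ALIASES.get(k, k) for k in kinds]
    valid = {"delta_sk", "delta_ku", "delta_zr", "lnRR", "lnVR"}
    bad = set(kinds) - valid
    if bad:
        raise ConfigError(f"unknown effect kinds: {sorted(bad)}")
    rows = []
    for stratum in table.strata():
        for kind in kinds:
            paired = kind == "delta_zr"
            try:
                g1, g2 = table.group_samples(stratum, paired)
                if swap_groups:
                    g1, g2 = g2, g1
                if kind in ("delta_sk", "delta_ku") and (
                    g1.n < RECOMMENDED_MIN_N or g2.n < RECOMMENDED_MIN_N
                ):
                    logger.warning(
                        "%s in stratum %s: group n (%d, %d) below recommended %d",
                        kind, stratum or "(all)", g1.n, g2.n, RECOMMENDED_MIN_N,
                    )
                fn = {
                    "delta_sk": delta_skewness,
                    "delta_ku": delta_kurtosis,
                    "delta_zr": delta_zr,
                    "lnRR": ln_rr,
                    "lnVR": ln_vr,
                }[kind]
                e = fn(g1, g2, dep) if kind.startswith("delta") else fn(g1, g2)
                rows.append(
                    {
                        **{
                            "effect_kind": e.effect_kind,
                            "estimate": e.estimate,
                            "sampling_variance": e.sampling_variance,
                            "n1": e.n1,
                            "n2": e.n2,
                            "point_method": e.point_method,
                            "variance_method": e.variance_method,
                        },
                        **stratum,
                        "error": "",
                    }
                )
            except DeltaMomentsError as exc:
                logger.warning("%s in stratum %s failed: %s", kind, stratum, exc)
                rows.append(
                    {
                        "effect_kind": kind,
                        "estimate": math.nan,
                        "sampling_variance": math.nan,
                        "n1": pd.NA,
                        "n2": pd.NA,
                        "point_method": "",
                        "variance_method": "",
                        **stratum,
                        "error": type(exc).__name__,
                    }
                )
    if not rows:
        raise InvalidInputError("no strata found in study table")
    return pd.DataFrame(rows)


#: emulates a two-sex, multi-center phenotyping design: strata are
#: center x strain cells; two traits with sex-specific shape and
#: within-sex cross-trait correlations; group 1 = male (so positive effects
#: mean the male estimate exceeds the female one)
DEFAULT_FIXTURE_CONFIG = {
    "strata": [
        {"center": "C1", "strain": "S1"},
        {"center": "C1", "strain": "S2"},
        {"center": "C2", "strain": "S1"},
        {"center": "C2", "strain": "S2"},
    ],
    "n_per_group": 200,
    "groups": {
        "male": {
            "trait1": {"mean": 30.0, "variance": 16.0, "skewness": 0.5, "kurtosis": 3.5},
            "trait2": {"mean": 10.0, "variance": 4.0, "skewness": 0.0, "kurtosis": 3.0},
            "r": 0.4,
        },
        "female": {
            "trait1": {"mean": 25.0, "variance": 9.0, "skewness": 0.3, "kurtosis": 3.2},
            "trait2": {"mean": 9.0, "variance": 3.0, "skewness": 0.0, "kurtosis": 3.0},
            "r": 0.6,
        },
    },
}


def _gaussian_copula_pair(
    n: int, t1: MomentTarget, t2: MomentTarget, r: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Two traits with the given marginal moments and (approximate)
    cross-trait correlation, via a Gaussian copula over Pearson marginals.

    The rank-based coupling preserves each marginal's four moments exactly in
    population; the linear correlation of the transformed pair differs from
    the normal-score correlation only at second order for the mild shapes
    used here.
    """
    z1 = rng.standard_normal(n)
    z2 = r * z1 + math.sqrt(max(0.0, 1.0 - r * r)) * rng.standard_normal(n)
    x1 = np.sort(sample_pearson(n, t1, rng))[np.argsort(np.argsort(z1))]
    x2 = np.sort(sample_pearson(n, t2, rng))[np.argsort(np.argsort(z2))]
    return x1, x2


def generate_fixture(
    config: Optional[dict] = None,
    seed: int = 0,
    out_csv: Optional[str | Path] = None,
    out_truth_json: Optional[str | Path] = None,
) -> tuple[pd.DataFrame, dict]:
    """Deterministic synthetic study table with known population effects.

    Returns the long-format table and a ground-truth dict of the configured
    population contrasts (group 1 = "male" minus group 2 = "female") per
    stratum, so the effect -> meta pipeline can be tested end to end.
    """
    cfg = {**DEFAULT_FIXTURE_CONFIG, **(config or {})}
    groups = cfg["groups"]
    if len(groups) != 2:
        raise ConfigError("fixture config needs exactly two groups")
    g1_name, g2_name = list(groups)
    rows = []
    for stratum in cfg["strata"]:
        for gname, spec in groups.items():
            t1 = MomentTarget(
                spec["trait1"]["mean"], spec["trait1"]["variance"],
                spec["trait1"]["skewness"], spec["trait1"]["kurtosis"],
            )
            t2 = MomentTarget(
                spec["trait2"]["mean"], spec["trait2"]["variance"],
                spec["trait2"]["skewness"], spec["trait2"]["kurtosis"],
            )
            rng = spawn_rng(seed, "fixture", json.dumps(stratum, sort_keys=True), gname)
            x1, x2 = _gaussian_copula_pair(
                cfg["n_per_group"], t1, t2, spec["r"], rng
            )
            for a, b in zip(x1, x2):
                rows.append({**stratum, "group": gname, "trait1": a, "trait2": b})
    df = pd.DataFrame(rows)
    s1, s2 = groups[g1_name], groups[g2_name]
    truth = {
        "group1": g1_name,
        "group2": g2_name,
        "delta_sk_trait1": s1["trait1"]["skewness"] - s2["trait1"]["skewness"],
        "delta_ku_trait1": s1["trait1"]["kurtosis"] - s2["trait1"]["kurtosis"],
        "delta_zr": math.atanh(s1["r"]) - math.atanh(s2["r"]),
        "lnRR_trait1": math.log(s1["trait1"]["mean"] / s2["trait1"]["mean"]),
        "lnVR_trait1": 0.5 * math.log(s1["trait1"]["variance"] / s2["trait1"]["variance"]),
    }
    if out_csv is not None:
        df.to_csv(out_csv, index=False)
    if out_truth_json is not None:
        Path(out_truth_json).write_text(json.dumps(truth, indent=2))
    return df, truth
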