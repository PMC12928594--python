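# deltamoments

Effect-size statistics for comparing the *shape* of trait distributions
between two groups — differences in skewness, kurtosis, and within-group
correlation — with the sampling variances needed to meta-analyse them.

Most comparative and biomedical syntheses contrast group means (and,
increasingly, variability). But two groups — say, male and female mice —
can differ in the asymmetry of a trait distribution, in the heaviness of
its tails, or in how strongly two traits correlate within each group, even
when means and variances are similar. This package provides the three
contrast statistics that make such differences meta-analysable:

- **Δsk** = sk₁ − sk₂, the difference in small-sample-adjusted sample
  skewness (G1), with analytic sampling variance
  s²_sk = 6n(n−1)/[(n−2)(n+1)(n+3)] per group;
- **Δku** = ku₁ − ku₂, the difference in small-sample excess kurtosis
  (G2; a normal population has expected value 0, i.e. kurtosis 3 on the
  non-excess scale), with s²_ku = 24n(n−1)²/[(n−3)(n−2)(n+3)(n+5)];
- **ΔZr** = Zr₁ − Zr₂, the difference in Fisher-transformed within-group
  Pearson correlations, Zr = atanh(r), with s²_Zr = 1/(n−3).

Each contrast's variance is v₁ + v₂ − 2ρ√(v₁v₂) (ρ = 0 for independent
groups). Because the analytic moment variances assume normality, a delete-1
**jackknife** alternative (per-group variances, pooled) and a jackknife
bias-corrected point estimate are provided; the recommended pairing is
analytic points with jackknife variances for Δsk/Δku, and the fully
analytic pair for ΔZr. The companions lnRR (log response ratio) and lnVR
(log variance ratio) are included so a full mean / variability / shape /
correlation profile can be computed from one table.

Also included:

- a **Pearson-system sampler** (`sample_pearson`) drawing from the
  distribution type implied by any feasible (mean, variance, skewness,
  kurtosis) target — the generator behind the simulation study;
- a **Monte-Carlo harness** (`sim_engine`) that enumerates the scenario
  grids (64 correlation scenarios per sample size, 768 cells; 100 moment
  scenarios per sample size, 1,200 cells per family), runs seeded
  replicates, and reports bias, relative variance bias, coverage and
  Monte-Carlo standard errors per estimator pairing;
- a **random-effects meta-analysis** layer (`meta_model`) with REML
  estimation of additive crossed variance components (e.g. effect ID ×
  center × strain), per-component I², and a sample-size-weighted path for
  Δku, whose sampling variances are not trustworthy enough for
  inverse-variance weighting;
- a CLI (`deltamoments effect | simulate | meta | fixture`) and a synthetic
  fixture generator emulating a multi-center two-sex phenotyping dataset
  with known population effects.

## Worked example

```python
import deltamoments as dm

# synthetic two-sex study: 4 center x strain strata, n = 200 per sex,
# females configured with the stronger trait1-trait2 correlation
df, truth = dm.generate_fixture(seed=11)
df.to_csv("fixture.csv", index=False)

st = dm.read_study_table(
    "fixture.csv", group_col="group", trait_cols=["trait1", "trait2"],
    stratum_cols=["center", "strain"], group_order=["male", "female"],
)
effects = dm.compute_effects(st, ["dzr"])          # one dZr per stratum
from deltamoments.effect_sizes import frame_to_effects
from deltamoments.meta_model import MetaInput, random_effects_meta

res = random_effects_meta(MetaInput.from_effects(
    frame_to_effects(effects.drop(columns=["error"])), ["center", "strain"],
))
print(truth["delta_zr"], res.pooled_estimate, res.ci)
```

prints

```
-0.26949825036634345 -0.1697831042734353 (-0.26977627093876094, -0.06978993760810963)
```

The configured truth is ΔZr = atanh(0.4) − atanh(0.6) ≈ −0.269 (males have
the weaker correlation, and the male-minus-female sign convention makes the
effect negative); the pooled estimate from this seed's four strata is
−0.170 with 95% CI (−0.270, −0.070) — covering the truth, and correctly
signed. Averaged over many seeds the per-stratum estimates are unbiased
(mean −0.2703 across 120 strata).

The same pipeline from a shell:

```sh
deltamoments fixture --seed 11 --out fixture.csv
deltamoments effect fixture.csv --type dzr --stratum-cols center,strain \
    --group-order male,female --out effects.csv
deltamoments meta effects.csv --random-factors center,strain --forest forest.png
deltamoments simulate --families zr --dry-run   # prints: 768 scenario cells ...
```

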