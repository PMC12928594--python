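# Methods

## Estimators

**Single-group moments.** Sample skewness is the adjusted Fisher–Pearson
coefficient G1 = m₃/m₂^{3/2} · √(n(n−1))/(n−2), and sample excess kurtosis
is G2 = (n−1)/[(n−2)(n−3)] · [(n+1)(m₄/m₂² − 3) + 6], with m_k the
divisor-n central moments. Both are the standard small-sample-corrected
estimators: G1 and G2 are unbiased under normality, and G2 has expectation
0 for normal populations at every n (equivalently, kurtosis 3 on the
non-excess scale) — the property the test suite checks on 10⁶ simulated
draws. Their normal-theory sampling variances are

    var(G1) = 6n(n−1) / [(n−2)(n+1)(n+3)]
    var(G2) = 24n(n−1)² / [(n−3)(n−2)(n+3)(n+5)]

Fisher's z = atanh(r) has variance 1/(n−3) under bivariate normality.
Inputs with zero variance, |r| = 1, or too few observations raise typed
errors (`UndefinedStatisticError`, `MomentDomainError`,
`InvalidInputError`) rather than returning NaN, so pipelines can count
exclusions. Minimum n is a hard precondition (3 for skewness, 4 for
kurtosis and r); per-group n < 50 for Δsk/Δku triggers a logged warning
only, because simulation at n = 10 must remain possible — higher moments
become extreme in small samples, which is why 50 per group is the
recommended floor for real analyses.

**Contrasts.** Δsk, Δku, ΔZr are group-1-minus-group-2 differences with
variance v₁ + v₂ − 2ρ√(v₁v₂). The ρ terms (one per statistic, default 0)
express sampling dependence between groups; the package never estimates
them from data — they are caller-supplied, relevant for paired or
longitudinal designs. Kurtosis contrasts are on the excess scale; for
targets specified on the non-excess scale the offsets cancel in the
difference. lnRR and lnVR use their standard published forms:
lnRR = ln(x̄₁/x̄₂) with variance s₁²/(n₁x̄₁²) + s₂²/(n₂x̄₂²);
lnVR = ln(s₁/s₂) + ½[1/(n₁−1) − 1/(n₂−1)] with variance
½[1/(n₁−1) + 1/(n₂−1)].

**Jackknife.** Delete-1 only. Variance (n−1)/n·Σ(θ₍ᵢ₎−θ̄₍·₎)², bias-corrected
point nθ̂ − (n−1)θ̄₍·₎; the two scaling conventions in the literature
(pseudovalue-based and direct) coincide for delete-1, verified by the
closed-form sample-mean identity (jackknife variance = s²/n exactly). Group
jackknives are computed separately and summed for contrasts; ρ is ignored
under jackknife variances since groups are resampled independently. The
generic implementation recomputes the statistic on each leave-one-out
subsample; exact O(n) power-sum fast paths exist for the moment statistics
and for leave-one-pair-out Fisher z (data are pre-centered before forming
power sums to avoid cancellation), and tests pin them to the naive path at
1e−10. A result is flagged when the leave-one-out estimates have |skewness|
> 2 — the diagnostic for the kurtosis-contrast coverage failure discussed
below.

**Default pairings.** Δsk and Δku default to analytic points with jackknife
variances; ΔZr to the fully analytic pair. Rationale (reproduced
directionally by the test suite): the analytic moment variances assume
normality and are substantially biased under skewed/heavy-tailed truths,
while the jackknife variance tracks the Monte-Carlo variance well for
n ≳ 50; for ΔZr the analytic 1/(n−3) is already excellent. Bias-corrected
jackknife points reduce small-sample mean-squared bias in aggregate
(clearly at n = 20–30; at n = 10 the correction itself is noisy and can
overshoot for extreme skewness), but the default keeps analytic points for
comparability and because the bias correction does not improve coverage.

## Pearson-system sampler

A moment target (μ, σ², γ₁, β₂) is feasible iff β₂ > γ₁² + 1. The type is
chosen by the κ criterion on (β₁ = γ₁², β₂): β₁ = 0 gives normal/II/VII;
2β₂ − 3β₁ − 6 = 0 gives III; otherwise κ = β₁(β₂+3)²/[4(4β₂−3β₁)(2β₂−3β₁−6)]
with κ < 0 → I, κ = 1 → V, 0 < κ < 1 → IV, κ > 1 → VI. Each type is
sampled via its standard distributional form and affinely relocated:

- **I**: beta(p, q) with p + q = r = 6(β₂−β₁−1)/(6+3β₁−2β₂) and
  q − p = sign(γ₁)·√[β₁(r+2)²r²/(16(r+1)+β₁(r+2)²)] (closed form);
- **II**: symmetric beta(a, a), a = (6/(3−β₂) − 3)/2;
- **III**: gamma with shape 4/γ₁² (mirrored for γ₁ < 0);
- **IV**: no elementary quantile; the density transformed by
  θ = atan((x−λ)/a) is cos^{2m−2}θ·e^{−νθ} on (−π/2, π/2), which is smooth
  and compact — the CDF is accumulated by Simpson's rule on a 40,001-point
  θ grid (probability error far below 1e−9) and inverted by interpolation;
- **V**: inverse-gamma, shape solved in closed form from γ₁, with a
  consistency check that (γ₁, β₂) lies on the Type V curve;
- **VI**: beta-prime, (α, β) solved numerically from the first four raw
  moments (log-parameterised root-find, multiple starts, explicit
  `ConvergenceError` on failure);
- **VII**: Student t scaled to unit variance, ν = 4 + 6/(β₂−3).

Moment recovery for every type is verified at 2×10⁵ draws in unit tests and
at 10⁶ draws for all default grid targets in the acceptance tests, within 4
Monte-Carlo standard errors (normal-theory SEs inflated for heavy-tailed
targets, since the SE of a sample kurtosis grows with the population's
higher moments). Only types normal/I/II/VII occur in the default grids;
III/IV/V/VI are exercised by dedicated tests.

Correlation scenarios use a bivariate normal with standard-normal marginals
via the Cholesky construction y = r·z₁ + √(1−r²)·z₂.

**Streams.** Every replicate's generator is spawned as a pure function of
(root seed, scenario id, replicate index) via `SeedSequence` (string keys
hashed by CRC32), so studies are bit-reproducible and resumable and no
stream is shared across scenarios.

## Simulation harness

Default grids: skewness family — ordered pairs from {−1, −0.5, 0, 0.5, 1}
at kurtosis 3; kurtosis family — ordered pairs from {2.5, 3, 4, 5, 6} at
skewness 0; each crossed with equal/unequal variance (σ₂² = 2 vs 1) and
equal/unequal mean (μ₂ = 5 vs 0), giving 100 scenarios per sample size and
1,200 cells over n ∈ {10, 20, …, 100, 150, 500}. Correlation family —
ordered pairs from {−0.8, −0.4, −0.2, 0, 0.2, 0.4, 0.6, 0.8}, 64 scenarios
per sample size, 768 cells. Mean/variance shifts are affine and do not
change shape, so they serve as invariance conditions. Equal group sizes
only in the default grids (the data model supports unequal n). Default
2,500 replicates per cell; the CLI exposes `--reps`.

Per replicate, four estimator pairings are evaluated: {analytic,
jackknife-bias-corrected} points × {analytic, jackknife} variances.
Metrics, per pairing: bias = mean(θ̂) − θ with MCSE √(Var_MC/R); relative
variance bias = mean(v̂)/Var_MC(θ̂) − 1, with a delta-method MCSE combining
the spread of v̂ and the ≈√(2/(R−1)) relative noise of the empirical
variance; coverage of symmetric Wald intervals (no t-quantile adjustment)
with MCSE √(c(1−c)/R). Replicates whose statistics are undefined are
excluded and counted (`n_reps_effective`), never re-drawn — re-drawing
would bias boundary scenarios; a scenario aborts if more than half its
replicates fail.

The meta-performance runner simulates k studies per meta-replicate with
per-study truths μ + N(0, τ²) realised by shifting group 1's target on the
effect scale (through tanh/atanh for correlations, with feasibility
clipping for moment targets), pools them, and reports pooled bias,
coverage, and τ² recovery. Its design (k, n, τ², weighting) is fully
config-driven since no single canonical layout exists for this evaluation.

## Meta-analysis

The inverse-variance path fits y_i = μ + Σ_f u_{f,level(i)} + e_i with
known e_i variances and additive crossed components τ²_f by REML
(L-BFGS-B on the −2 restricted log-likelihood, τ² bounded at 0, three
starting points, explicit `ConvergenceError` otherwise); pooling is GLS
with Wald intervals. With one factor at one level per effect this is the
standard random-effects model, and tests pin τ̂² to a dense
profile-likelihood grid search. Heterogeneity: I²_f = τ²_f/(Στ² + s̃²)·100
with s̃² the typical sampling variance (k−1)Σw/[(Σw)²−Σw²], w = 1/vᵢ;
components sum to the total by construction.

The sample-size path (default for Δku) weights by effective n
ñ = n₁n₂/(n₁+n₂). τ² solves the generalized DerSimonian–Laird identity
E[Q_w] = Σwᵢ(vᵢ+τ²) − Σwᵢ²(vᵢ+τ²)/Σw for the weighted residual sum of
squares (the analytic vᵢ enter only this correction, not the weights), and
the pooled SE is the sandwich form √(Σwᵢ²rᵢ²)·√(k/(k−1))/Σw, which does
not trust the vᵢ at all. Under n-weighting heterogeneity is reported as a
single total component — a method-of-moments estimator cannot partition
crossed factors. Knapp–Hartung adjustment is not applied, keeping the
interval construction consistent with the Wald intervals used in the
coverage metric.

## Fixture generator

`generate_fixture` emulates the structure of a multi-center two-sex
phenotyping dataset: strata = center × strain, two traits per individual,
sex-specific moment targets and within-sex cross-trait correlation, group
1 = male (positive effects mean the male estimate exceeds the female one).
Trait pairs couple Pearson-system marginals through a Gaussian copula
(rank-matching against correlated normal scores), which preserves each
marginal's four moments exactly and attenuates the linear correlation only
marginally for the mild shapes in the default config (measured ≈0.395 and
0.598 for targets 0.4 and 0.6). Defaults: 4 strata, n = 200 per sex per
stratum, female correlation 0.6 vs male 0.4, males with slightly larger,
more variable, more skewed trait 1 values.

What the generator does *not* emulate: measurement error, batch and
season effects within centers, unbalanced sexes, missingness mechanisms,
discrete or bounded traits. Passing end-to-end tests therefore show that
the pipeline recovers known population contrasts from cleanly generated
data, not that it is robust to the messiness of real phenotyping archives.

## Problem sizes in the test suite

Unit tests use reduced Monte-Carlo sizes (hundreds of replicates, 2×10⁵
draws for moment recovery) chosen so each check's Monte-Carlo error is
well inside its assertion tolerance; the acceptance tests run the headline
quantities at full size (10⁶ draws, 2,500 replicates, 500 replicates per
cell for the directional grid comparisons). The full 1,200/768-cell study
at 2,500 replicates is what `deltamoments simulate` runs by default and
takes a few CPU-hours; tests assert its enumeration, not its full
execution.

## Known limitations

- **Wald coverage for shape contrasts is not exactly nominal.** At n = 100
  with true Δsk = 1 (skewness ±0.5), the analytic-point + jackknife-variance
  interval covers at ≈93.3% (20,000-replicate measurement), not 95%: the
  jackknife variance is conservative on average (+9%) but anticorrelated
  with the estimate's error, making the standardized ratio heavy-tailed.
  Bias-correcting the point removes essentially all bias yet leaves
  coverage at ≈93.1%. Coverage is closer to nominal at null cells and for
  ΔZr (≈95.1% under the same design). Users wanting strict 95% coverage
  for non-null moment contrasts need larger n or interval methods outside
  this package's scope (e.g. bootstrap calibration).
- **Δku inference is fragile**, exactly as the simulations show: at large n
  and large true Δku the jackknife sampling distribution is strongly
  skewed (the `pseudovalue_skew_flag` diagnostic) and Wald coverage
  collapses (≈54% at n = 500, true Δku = 3.5). Hence the sample-size-
  weighted meta-analytic default for Δku.
- ρ (between-group sampling correlation) is exposed but there is no
  guidance or estimation for choosing nonzero values.
- The REML parameterisation assumes additive independent components;
  strongly confounded factor layouts (few levels, nested rather than
  crossed) can leave components unidentifiable — the optimiser then
  attributes variance arbitrarily among aliased components.
- Type IV Pearson sampling is grid-inversion based; extreme parameter
  corners (κ → 1) inherit interpolation error, though never in the default
  grids.
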