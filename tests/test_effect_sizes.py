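"""Two-group contrast construction, variances, intervals, and the CSV schema."""

import math

import numpy as np
import pytest

from deltamoments import (
    DependenceSpec,
    EffectSize,
    GroupSample,
    InvalidInputError,
    MomentDomainError,
    confidence_interval,
    delta_kurtosis,
    delta_skewness,
    delta_zr,
    effect_from_summaries,
    effects_to_frame,
    frame_to_effects,
    kurtosis_sampling_variance,
    ln_rr,
    ln_vr,
    skewness_sampling_variance,
)


@pytest.fixture
def two_groups(rng):
    g1 = GroupSample(rng.gamma(3.0, size=60), label="g1")
    g2 = GroupSample(rng.gamma(5.0, size=80), label="g2")
    return g1, g2


@pytest.fixture
def two_paired_groups(rng):
    def make(n, r, label):
        x = rng.standard_normal(n)
        y = r * x + math.sqrt(1 - r * r) * rng.standard_normal(n)
        return GroupSample(x, y, label=label)

    return make(60, 0.5, "g1"), make(80, 0.2, "g2")


class TestIdenticalGroups:
    def test_all_contrasts_zero(self, rng):
        x = rng.gamma(2.0, size=50)
        y = 0.3 * x + rng.standard_normal(50)
        g = GroupSample(x, y, label="g")
        for fn in (delta_skewness, delta_kurtosis, delta_zr):
            for vm in ("analytic", "jackknife"):
                e = fn(g, g, variance_method=vm)
                assert e.estimate == 0.0
        assert ln_rr(g, g).estimate == 0.0
        assert ln_vr(g, g).estimate == 0.0


class TestAntisymmetry:
    @pytest.mark.parametrize("point_method", ["analytic", "jackknife_bias_corrected"])
    def test_moment_contrasts(self, two_groups, point_method):
        g1, g2 = two_groups
        for fn in (delta_skewness, delta_kurtosis):
            a = fn(g1, g2, point_method=point_method)
            b = fn(g2, g1, point_method=point_method)
            assert a.estimate == pytest.approx(-b.estimate, rel=1e-12)
            assert a.sampling_variance == pytest.approx(b.sampling_variance, rel=1e-12)

    def test_correlation_contrast(self, two_paired_groups):
        g1, g2 = two_paired_groups
        for vm in ("analytic", "jackknife"):
            a = delta_zr(g1, g2, variance_method=vm)
            b = delta_zr(g2, g1, variance_method=vm)
            assert a.estimate == pytest.approx(-b.estimate, rel=1e-12)
            assert a.sampling_variance == pytest.approx(b.sampling_variance, rel=1e-12)


class TestAnalyticVariances:
    def test_delta_sk_variance_sums_group_terms(self, rng):
        g1 = GroupSample(rng.standard_normal(10), label="a")
        g2 = GroupSample(rng.standard_normal(10), label="b")
        e = delta_skewness(g1, g2, variance_method="analytic")
        assert e.sampling_variance == pytest.approx(2 * 540.0 / 1144.0, rel=1e-12)

    def test_delta_ku_variance_sums_group_terms(self, rng):
        g1 = GroupSample(rng.standard_normal(10), label="a")
        g2 = GroupSample(rng.standard_normal(10), label="b")
        e = delta_kurtosis(g1, g2, variance_method="analytic")
        assert e.sampling_variance == pytest.approx(
            2 * kurtosis_sampling_variance(10), rel=1e-12
        )

    def test_rho_term_reduces_variance(self, rng):
        g1 = GroupSample(rng.standard_normal(30), label="a")
        g2 = GroupSample(rng.standard_normal(30), label="b")
        dep = DependenceSpec(rho_sk=0.5)
        e0 = delta_skewness(g1, g2, variance_method="analytic")
        e5 = delta_skewness(g1, g2, dep, variance_method="analytic")
        v = skewness_sampling_variance(30)
        assert e5.sampling_variance == pytest.approx(2 * v - 2 * 0.5 * v, rel=1e-12)
        assert e5.sampling_variance < e0.sampling_variance

    def test_perfect_dependence_cancels_zr_variance(self):
        e = effect_from_summaries(
            "delta_zr", 50, 50, DependenceSpec(rho_zr=1.0), est1=0.5, est2=0.5
        )
        assert e.sampling_variance == pytest.approx(0.0, abs=1e-15)


class TestFromSummaries:
    def test_zr_hand_example(self):
        e = effect_from_summaries("delta_zr", 103, 53, est1=0.5, est2=0.3)
        assert e.estimate == pytest.approx(math.atanh(0.5) - math.atanh(0.3), rel=1e-12)
        assert e.sampling_variance == pytest.approx(0.01 + 0.02, rel=1e-12)

    def test_null_zr(self):
        e = effect_from_summaries("delta_zr", 50, 50, est1=0.5, est2=0.5)
        assert e.estimate == 0.0
        assert e.sampling_variance == pytest.approx(2.0 / 47.0, rel=1e-12)

    def test_sk_difference(self):
        e = effect_from_summaries("delta_sk", 100, 100, est1=1.0, est2=-1.0)
        assert e.estimate == pytest.approx(2.0)

    def test_agrees_with_raw_data_path(self, two_paired_groups):
        from deltamoments import pearson_correlation, sample_skewness

        g1, g2 = two_paired_groups
        raw = delta_zr(g1, g2, variance_method="analytic")
        summ = effect_from_summaries(
            "delta_zr", g1.n, g2.n,
            est1=pearson_correlation(g1.values, g1.second_values),
            est2=pearson_correlation(g2.values, g2.second_values),
        )
        assert summ.estimate == pytest.approx(raw.estimate, rel=1e-12)
        assert summ.sampling_variance == pytest.approx(raw.sampling_variance, rel=1e-12)

        raw = delta_skewness(g1, g2, variance_method="analytic")
        summ = effect_from_summaries(
            "delta_sk", g1.n, g2.n,
            est1=sample_skewness(g1.values), est2=sample_skewness(g2.values),
        )
        assert summ.estimate == pytest.approx(raw.estimate, rel=1e-12)
        assert summ.sampling_variance == pytest.approx(raw.sampling_variance, rel=1e-12)

    def test_missing_n_rejected(self):
        with pytest.raises(InvalidInputError):
            effect_from_summaries("delta_sk", None, 50, est1=1.0, est2=0.0)


class TestConfidenceInterval:
    def test_zero_variance_degenerates_to_point(self):
        e = EffectSize("delta_sk", 0.7, 0.0, 50, 50)
        assert confidence_interval(e) == (0.7, 0.7)

    def test_standard_normal_quantile(self):
        e = EffectSize("delta_sk", 0.0, 1.0, 50, 50)
        lo, hi = confidence_interval(e, 0.95)
        assert lo == pytest.approx(-1.959964, abs=1e-5)
        assert hi == pytest.approx(1.959964, abs=1e-5)

    def test_width_scales_with_sqrt_variance(self):
        e1 = EffectSize("delta_sk", 0.0, 1.0, 50, 50)
        e4 = EffectSize("delta_sk", 0.0, 4.0, 50, 50)
        w1 = np.diff(confidence_interval(e1))[0]
        w4 = np.diff(confidence_interval(e4))[0]
        assert w4 == pytest.approx(2 * w1, rel=1e-12)

    def test_level_domain(self):
        e = EffectSize("delta_sk", 0.0, 1.0, 50, 50)
        with pytest.raises(InvalidInputError):
            confidence_interval(e, 1.0)


class TestRatioEffects:
    def test_doubled_sd_gives_minus_log_two(self):
        e = effect_from_summaries("lnVR", 10_001, 10_001, sd1=1.0, sd2=2.0)
        assert e.estimate == pytest.approx(-math.log(2), abs=1e-3)

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(MomentDomainError):
            effect_from_summaries("lnRR", 50, 50, mean1=-1.0, mean2=2.0, sd1=1, sd2=1)
        with pytest.raises(MomentDomainError):
            effect_from_summaries("lnVR", 50, 50, sd1=0.0, sd2=1.0)

    def test_lnvr_variance_matches_simulation(self, rng):
        """The analytic lnVR variance 0.5*(1/(n1-1) + 1/(n2-1)) should match
        the Monte-Carlo variance of the estimator on normal data."""
        reps, n = 2000, 100
        vals = np.empty(reps)
        for i in range(reps):
            g1 = GroupSample(rng.standard_normal(n), label="a")
            g2 = GroupSample(rng.standard_normal(n), label="b")
            vals[i] = ln_vr(g1, g2).estimate
        analytic = 0.5 * (2.0 / (n - 1))
        assert vals.var(ddof=1) == pytest.approx(analytic, rel=0.15)


class TestTabularSchema:
    def test_round_trip(self, two_groups):
        g1, g2 = two_groups
        effects = [
            delta_skewness(g1, g2),
            delta_kurtosis(g1, g2),
            ln_vr(g1, g2),
        ]
        effects[0] = EffectSize(
            **{**effects[0].__dict__, "stratum_labels": {"center": "C1"}}
        )
        df = effects_to_frame(effects)
        assert list(df.columns[:7]) == [
            "effect_kind", "estimate", "sampling_variance", "n1", "n2",
            "point_method", "variance_method",
        ]
        back = frame_to_effects(df)
        for a, b in zip(effects, back):
            assert a.estimate == b.estimate
            assert a.sampling_variance == b.sampling_variance
            assert a.effect_kind == b.effect_kind
        assert back[0].stratum_labels == {"center": "C1"}

    def test_missing_columns_rejected(self):
        import pandas as pd

        with pytest.raises(InvalidInputError):
            frame_to_effects(pd.DataFrame({"estimate": [1.0]}))


class TestDependenceSpec:
    def test_range_validation(self):
        with pytest.raises(InvalidInputError):
            DependenceSpec(rho_sk=1.5)
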