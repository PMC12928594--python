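"""Study-table I/O, the fixture generator, and the CLI surface."""

import json
import math

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

from deltamoments import (
    ConfigError,
    InvalidInputError,
    compute_effects,
    generate_fixture,
    read_study_table,
)
from deltamoments.cli import main as cli_main
from deltamoments.effect_sizes import frame_to_effects
from deltamoments.meta_model import MetaInput, random_effects_meta


@pytest.fixture
def toy_csv(tmp_path):
    p = tmp_path / "toy.csv"
    pd.DataFrame({
        "group": ["a", "a", "b", "b"],
        "trait1": [1.0, 2.0, 3.0, 4.0],
    }).to_csv(p, index=False)
    return p


class TestReadStudyTable:
    def test_toy_table(self, toy_csv):
        st = read_study_table(toy_csv, "group", ["trait1"])
        assert st.group_labels == ("a", "b")
        g1, g2 = st.group_samples({}, paired=False)
        assert g1.n == 2 and g2.n == 2

    def test_third_group_error_names_labels(self, tmp_path):
        p = tmp_path / "three.csv"
        pd.DataFrame({
            "group": ["a", "b", "c"], "trait1": [1.0, 2.0, 3.0],
        }).to_csv(p, index=False)
        with pytest.raises(InvalidInputError) as err:
            read_study_table(p, "group", ["trait1"])
        for lab in ("a", "b", "c"):
            assert lab in str(err.value)

    def test_missing_column(self, toy_csv):
        with pytest.raises(ConfigError, match="trait9"):
            read_study_table(toy_csv, "group", ["trait9"])

    def test_unparseable_rows_dropped_and_counted(self, tmp_path):
        p = tmp_path / "messy.csv"
        pd.DataFrame({
            "group": ["a", "a", "a", "b", "b", "b"],
            "trait1": ["1.0", "oops", "2.0", "3.0", "", "4.0"],
        }).to_csv(p, index=False)
        st = read_study_table(p, "group", ["trait1"])
        assert st.n_dropped == 2
        assert len(st.data) == 4

    def test_round_trip(self, tmp_path, rng):
        df, _ = generate_fixture(seed=5)
        p = tmp_path / "fx.csv"
        df.to_csv(p, index=False)
        st = read_study_table(p, "group", ["trait1", "trait2"], ["center", "strain"])
        assert st.n_dropped == 0
        np.testing.assert_allclose(
            st.data["trait1"].to_numpy(), df["trait1"].to_numpy(), rtol=1e-12
        )

    def test_group_order_controls_sign_convention(self, tmp_path):
        df, _ = generate_fixture(seed=5)
        p = tmp_path / "fx.csv"
        df.to_csv(p, index=False)
        a = read_study_table(p, "group", ["trait1"], group_order=["male", "female"])
        b = read_study_table(p, "group", ["trait1"], group_order=["female", "male"])
        ea = compute_effects(a, ["lnrr"])
        eb = compute_effects(b, ["lnrr"])
        assert ea["estimate"].iloc[0] == pytest.approx(-eb["estimate"].iloc[0])


class TestFixtureGenerator:
    def test_deterministic(self):
        a, _ = generate_fixture(seed=9)
        b, _ = generate_fixture(seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_truth_dict_matches_config(self):
        _, truth = generate_fixture(seed=1)
        assert truth["group1"] == "male"
        assert truth["delta_zr"] == pytest.approx(math.atanh(0.4) - math.atanh(0.6))

    def test_identical_groups_give_null_truths_and_null_estimates(self, tmp_path):
        cfg = {
            "groups": {
                "male": {
                    "trait1": {"mean": 10, "variance": 4, "skewness": 0.3, "kurtosis": 3.2},
                    "trait2": {"mean": 5, "variance": 1, "skewness": 0.0, "kurtosis": 3.0},
                    "r": 0.5,
                },
                "female": {
                    "trait1": {"mean": 10, "variance": 4, "skewness": 0.3, "kurtosis": 3.2},
                    "trait2": {"mean": 5, "variance": 1, "skewness": 0.0, "kurtosis": 3.0},
                    "r": 0.5,
                },
            },
        }
        df, truth = generate_fixture(cfg, seed=21)
        assert truth["delta_zr"] == 0.0 and truth["delta_sk_trait1"] == 0.0
        p = tmp_path / "null.csv"
        df.to_csv(p, index=False)
        st = read_study_table(p, "group", ["trait1", "trait2"], ["center", "strain"],
                              group_order=["male", "female"])
        eff = compute_effects(st, ["dzr"])
        effs = frame_to_effects(eff.drop(columns=["error"]))
        res = random_effects_meta(MetaInput(effects=effs))
        assert res.ci[0] <= 0.0 <= res.ci[1]

    def test_pipeline_recovers_known_dzr_across_seeds(self, tmp_path):
        """End-to-end: fixture -> per-stratum effects -> pooled estimate
        covers the configured truth in nearly all seeded runs."""
        hits = 0
        runs = 12
        for seed in range(runs):
            df, truth = generate_fixture(seed=seed)
            p = tmp_path / f"fx{seed}.csv"
            df.to_csv(p, index=False)
            st = read_study_table(
                p, "group", ["trait1", "trait2"], ["center", "strain"],
                group_order=["male", "female"],
            )
            eff = compute_effects(st, ["dzr"])
            effs = frame_to_effects(eff.drop(columns=["error"]))
            res = random_effects_meta(MetaInput(effects=effs))
            if res.ci[0] <= truth["delta_zr"] <= res.ci[1]:
                hits += 1
        assert hits >= runs - 2


class TestCli:
    def test_fixture_effect_meta_pipeline(self, tmp_path):
        runner = CliRunner()
        fx = tmp_path / "fx.csv"
        eff = tmp_path / "eff.csv"
        meta = tmp_path / "meta.csv"
        r = runner.invoke(cli_main, ["fixture", "--seed", "3", "--out", str(fx)])
        assert r.exit_code == 0, r.output
        r = runner.invoke(cli_main, [
            "effect", str(fx), "--type", "dzr",
            "--stratum-cols", "center,strain",
            "--group-order", "male,female", "--out", str(eff),
        ])
        assert r.exit_code == 0, r.output
        table = pd.read_csv(eff)
        assert len(table) == 4 and table["estimate"].notna().all()
        r = runner.invoke(cli_main, [
            "meta", str(eff), "--random-factors", "center,strain",
            "--out", str(meta),
        ])
        assert r.exit_code == 0, r.output
        out = pd.read_csv(meta)
        assert out.loc[0, "k"] == 4
        assert out.loc[0, "weighting"] == "inverse_variance"

    def test_effect_swap_groups_negates(self, tmp_path):
        runner = CliRunner()
        fx = tmp_path / "fx.csv"
        runner.invoke(cli_main, ["fixture", "--seed", "3", "--out", str(fx)])
        outs = []
        for flag in ([], ["--swap-groups"]):
            out = tmp_path / f"eff{len(flag)}.csv"
            r = runner.invoke(cli_main, [
                "effect", str(fx), "--type", "dzr",
                "--stratum-cols", "center,strain",
                "--group-order", "male,female", "--out", str(out), *flag,
            ])
            assert r.exit_code == 0, r.output
            outs.append(pd.read_csv(out)["estimate"].to_numpy())
        np.testing.assert_allclose(outs[0], -outs[1], rtol=1e-12)

    def test_simulate_dry_run_counts(self):
        runner = CliRunner()
        r = runner.invoke(cli_main, ["simulate", "--families", "zr", "--dry-run"])
        assert r.exit_code == 0, r.output
        assert "768" in r.output
        r = runner.invoke(cli_main, ["simulate", "--families", "skew", "--dry-run"])
        assert r.exit_code == 0, r.output
        assert "1200" in r.output and "100" in r.output

    def test_simulate_smoke_run(self, tmp_path):
        runner = CliRunner()
        out = tmp_path / "perf.csv"
        cfgp = tmp_path / "cfg.yaml"
        cfgp.write_text(
            "families: [zr_family]\nr_values: [0.0, 0.4]\nn_values: [20]\n"
        )
        r = runner.invoke(cli_main, [
            "simulate", "--config", str(cfgp), "--reps", "10", "--out", str(out),
        ])
        assert r.exit_code == 0, r.output
        assert len(pd.read_csv(out)) == 16

    def test_meta_auto_n_weighting_for_dku(self, tmp_path):
        runner = CliRunner()
        eff = tmp_path / "eff.csv"
        pd.DataFrame({
            "effect_kind": ["delta_ku"] * 3,
            "estimate": [0.5, 0.7, 0.4],
            "sampling_variance": [0.2, 0.3, 0.25],
            "n1": [100, 120, 90],
            "n2": [100, 110, 95],
            "point_method": ["analytic"] * 3,
            "variance_method": ["jackknife"] * 3,
        }).to_csv(eff, index=False)
        out = tmp_path / "meta.csv"
        r = runner.invoke(cli_main, ["meta", str(eff), "--out", str(out)])
        assert r.exit_code == 0, r.output
        assert "sample-size weighting auto-selected" in r.output
        assert pd.read_csv(out).loc[0, "weighting"] == "sample_size"


class TestPlots:
    def test_panel_and_forest_plots_render(self, tmp_path, rng):
        from deltamoments import EffectSize, run_study
        from deltamoments.plots import plot_forest, plot_performance_panels

        table = run_study(
            {"families": ["zr_family"], "r_values": [0.0], "n_values": [20, 50]},
            root_seed=1, reps=10,
        )
        p1 = tmp_path / "panels.png"
        plot_performance_panels(table, p1)
        assert p1.stat().st_size > 0

        effs = [EffectSize("delta_zr", float(e), 0.02, 50, 50)
                for e in rng.normal(0.2, 0.1, size=5)]
        res = random_effects_meta(effs)
        p2 = tmp_path / "forest.png"
        plot_forest(effs, res, p2)
        assert p2.stat().st_size > 0
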