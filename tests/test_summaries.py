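"""Summary statistics, run outputs, configuration and CLI."""

import json

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

from redqueen import (
    ConfigError,
    ModelParams,
    diversity,
    load_config,
    mean_turnover_time,
    params_from_dict,
    run_simulation,
    trajectory_summary,
    weighted_allele_distributions,
    write_run_outputs,
)
from redqueen.cli import main


def make_ledger(rows):
    cols = ["allele_id", "birth_generation", "exit_generation",
            "initial_hotspots", "final_hotspots", "sojourn_time",
            "mean_frequency", "max_frequency", "fixed", "censored"]
    return pd.DataFrame(rows, columns=cols)


class TestDiversity:
    @pytest.mark.parametrize("freqs,expected", [
        ([1.0], 0.0),
        ([0.5, 0.5], 0.5),
        ([0.7, 0.2, 0.1], 0.46),
    ])
    def test_expected_heterozygosity(self, freqs, expected):
        assert diversity(freqs) == pytest.approx(expected)

    def test_unnormalized_rejected(self):
        with pytest.raises(ValueError):
            diversity([0.5, 0.6])


class TestWeightedDistributions:
    def test_single_allele_point_mass(self):
        ledger = make_ledger(
            [[1, 10, 110, 850, 120.0, 100, 0.8, 1.0, True, False]])
        dists = weighted_allele_distributions(ledger)
        assert dists.mean_turnover_time == 100.0
        init = dists.initial
        assert init["weight"].sum() == pytest.approx(1.0)
        row = init[(init["bin_start"] <= 850) & (init["bin_end"] >= 850)]
        assert row["weight"].iloc[0] == pytest.approx(1.0)

    def test_weights_proportional_to_sojourn_times_frequency(self):
        ledger = make_ledger([
            [1, 0, 100, 900, 100.0, 100, 0.9, 1.0, True, False],
            [2, 0, 100, 2_500, 200.0, 100, 0.1, 0.3, False, False]])
        dists = weighted_allele_distributions(ledger)
        w = dists.initial["weight"]
        assert w[w > 0].to_numpy() == pytest.approx([0.9, 0.1])
        assert dists.mean_turnover_time == pytest.approx(100.0)
        assert dists.mean_initial_hotspots == pytest.approx(
            0.9 * 900 + 0.1 * 2_500)

    def test_equal_weights_reduce_to_histogram(self):
        rows = [[i, 0, 50, n1, n1 / 2, 50, 0.5, 0.6, False, False]
                for i, n1 in enumerate([150, 250, 350, 450])]
        dists = weighted_allele_distributions(make_ledger(rows))
        w = dists.initial["weight"]
        assert w[w > 0].to_numpy() == pytest.approx([0.25] * 4)

    def test_final_distribution_uses_narrower_bins(self):
        ledger = make_ledger(
            [[1, 0, 100, 900, 120.0, 100, 0.9, 1.0, True, False]])
        dists = weighted_allele_distributions(ledger)
        assert (dists.initial["bin_end"] - dists.initial["bin_start"]
                + 1).iloc[0] == 100
        assert (dists.final["bin_end"] - dists.final["bin_start"]
                + 1).iloc[0] == 50

    def test_empty_ledger_rejected(self):
        with pytest.raises(ValueError):
            weighted_allele_distributions(make_ledger([]))

    def test_censored_alleles_excluded(self):
        ledger = make_ledger([
            [1, 0, 100, 900, 100.0, 100, 0.9, 1.0, True, False],
            [2, 50, np.nan, 2_000, 1_900.0, 60, 0.2, 0.4, False, True]])
        dists = weighted_allele_distributions(ledger)
        assert dists.mean_turnover_time == pytest.approx(100.0)


class TestTrajectorySummary:
    def test_constant_series(self):
        tr = pd.DataFrame({"generation": range(1, 11), "n1": 500.0,
                           "W": 0.7, "pi": 0.2})
        s = trajectory_summary(tr)
        assert s["W_mean"] == s["W_q25"] == s["W_q75"] == 0.7
        assert s["pi_q75"] - s["pi_q25"] == 0.0

    def test_quartiles_linear_interpolation(self):
        tr = pd.DataFrame({"generation": [1, 2, 3, 4], "n1": 0.0,
                           "W": [0.0, 0.0, 0.0, 1.0],
                           "pi": [0.0, 0.0, 0.0, 1.0]})
        s = trajectory_summary(tr)
        assert s["pi_mean"] == pytest.approx(0.25)
        assert s["pi_q25"] == pytest.approx(np.percentile([0, 0, 0, 1], 25))
        assert s["pi_q75"] == pytest.approx(np.percentile([0, 0, 0, 1], 75))

    def test_burn_in_discards_leading_generations(self):
        tr = pd.DataFrame({"generation": range(1, 101), "n1": 1.0,
                           "W": [0.0] * 50 + [1.0] * 50,
                           "pi": 0.0})
        assert trajectory_summary(tr, burn_in=50)["W_mean"] == 1.0


class TestConfigAndOutputs:
    def test_unknown_key_named_in_error(self):
        with pytest.raises(ConfigError, match="bogus_key"):
            params_from_dict({"bogus_key": 1})

    def test_out_of_range_value_named_in_error(self):
        with pytest.raises(ConfigError, match="B"):
            params_from_dict({"B": 1.5})

    def test_toml_round_trip(self, tmp_path):
        cfg = tmp_path / "run.toml"
        cfg.write_text("N = 250\nk1 = 5.0\nseed = 9\ngenerations = 100\n")
        p = load_config(cfg)
        assert (p.N, p.k1, p.seed, p.generations) == (250, 5.0, 9, 100)

    def test_manifest_reruns_to_identical_outputs(self, tmp_path):
        p = ModelParams(N=200, seed=17, generations=400)
        res = run_simulation(p)
        paths = write_run_outputs(res, tmp_path / "a")
        manifest = json.loads(paths["manifest"].read_text())
        p2 = params_from_dict(manifest["config"])
        res2 = run_simulation(p2)
        write_run_outputs(res2, tmp_path / "b")
        assert ((tmp_path / "a" / "trajectory.csv").read_bytes()
                == (tmp_path / "b" / "trajectory.csv").read_bytes())
        assert ((tmp_path / "a" / "ledger.csv").read_bytes()
                == (tmp_path / "b" / "ledger.csv").read_bytes())

    def test_turnover_requires_exited_alleles(self):
        ledger = make_ledger(
            [[0, 0, np.nan, 900, 800.0, 60, 1.0, 1.0, True, True]])
        with pytest.raises(ValueError):
            mean_turnover_time(ledger)


class TestCli:
    def test_run_writes_contracted_outputs(self, tmp_path):
        cfg = tmp_path / "cfg.toml"
        cfg.write_text("N = 200\ngenerations = 300\nseed = 4\n")
        out = tmp_path / "out"
        result = CliRunner().invoke(
            main, ["run", "--config", str(cfg), "--out", str(out)])
        assert result.exit_code == 0, result.output
        header = (out / "trajectory.csv").read_text().splitlines()[0]
        assert header == "generation,n1,W,pi"
        assert (out / "ledger.csv").exists()
        manifest = json.loads((out / "manifest.json").read_text())
        assert manifest["seed"] == 4

    def test_run_is_deterministic_given_seed(self, tmp_path):
        cfg = tmp_path / "cfg.toml"
        cfg.write_text("N = 200\ngenerations = 300\n")
        runner = CliRunner()
        for sub in ("a", "b"):
            r = runner.invoke(main, ["run", "--config", str(cfg), "--seed",
                                     "11", "--out", str(tmp_path / sub)])
            assert r.exit_code == 0, r.output
        assert ((tmp_path / "a" / "trajectory.csv").read_bytes()
                == (tmp_path / "b" / "trajectory.csv").read_bytes())

    def test_invalid_config_value_names_key(self, tmp_path):
        cfg = tmp_path / "cfg.toml"
        cfg.write_text("B = 1.5\n")
        result = CliRunner().invoke(main, ["run", "--config", str(cfg)])
        assert result.exit_code != 0
        assert "B" in result.output

    def test_landscape_and_summarize(self, tmp_path):
        runner = CliRunner()
        land = tmp_path / "landscape.csv"
        r = runner.invoke(main, ["landscape", "--k1", "50", "--grid-max",
                                 "1500", "--grid-step", "50",
                                 "--out", str(land)])
        assert r.exit_code == 0, r.output
        df = pd.read_csv(land)
        assert list(df.columns) == ["n1", "W_hom", "W_het"]
        assert ((df["W_hom"] >= 0) & (df["W_hom"] <= 1)).all()

        cfg = tmp_path / "cfg.toml"
        cfg.write_text("N = 300\ngenerations = 2000\nseed = 2\nk1 = 50.0\n")
        out = tmp_path / "run"
        r = runner.invoke(main, ["run", "--config", str(cfg),
                                 "--out", str(out)])
        assert r.exit_code == 0, r.output
        r = runner.invoke(main, ["summarize", "--run-dir", str(out)])
        assert r.exit_code == 0, r.output
        summary = json.loads((out / "summary.json").read_text())
        assert {"pi_mean", "W_mean", "pi_q25", "W_q75"} <= set(summary)

    def test_scenario_preset(self, tmp_path):
        r = CliRunner().invoke(
            main, ["run", "--scenario", "fig4-weak-smallN", "--generations",
                   "50", "--seed", "1", "--out", str(tmp_path / "s")])
        assert r.exit_code == 0, r.output
        manifest = json.loads((tmp_path / "s" / "manifest.json").read_text())
        assert manifest["config"]["N"] == 1_000
        assert manifest["config"]["k1"] == 50.0

    def test_unknown_scenario_rejected(self):
        r = CliRunner().invoke(main, ["run", "--scenario", "nope"])
        assert r.exit_code != 0
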