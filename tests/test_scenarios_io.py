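"""Scenario generation, config/trajectory serialization, and the CLI."""

import json

import numpy as np
import pytest
from click.testing import CliRunner

import hetdyn as hd
from hetdyn.cli import main as cli_main


class TestScenarioGeneration:
    def test_bit_identical_regeneration(self):
        a = hd.generate_scenario(1, n=4, law_family="logistic", rate_family="sinusoid")
        b = hd.generate_scenario(1, n=4, law_family="logistic", rate_family="sinusoid")
        assert np.array_equal(a.cfg.A, b.cfg.A)
        assert np.array_equal(a.cfg.x0, b.cfg.x0)
        assert a.cfg.law.params == b.cfg.law.params
        assert a.cfg.t_span == b.cfg.t_span
        assert a.provenance == b.provenance

    @pytest.mark.parametrize("seed", range(6))
    def test_every_draw_passes_validators(self, seed):
        sc = hd.generate_scenario(seed, n=2 + seed % 4, law_family=("logistic", "gompertz", "von_bertalanffy")[seed % 3])
        assert hd.validate_transition_matrix(sc.cfg.A).ok
        assert sc.cfg.x0.min() >= 0 and sc.cfg.N0 > 0
        assert sc.cfg.schedule.floor_guess > 0
        hd.stationary_distribution(sc.cfg.A)  # simple zero eigenvalue

    def test_gompertz_scenario_has_unit_h(self):
        sc = hd.generate_scenario(2, law_family="gompertz")
        grid = np.geomspace(0.1, 100.0, 20)
        assert np.all(np.asarray(sc.cfg.law.h(grid), float) == 1.0)

    @pytest.mark.parametrize("seed", range(4))
    def test_every_draw_is_theorem_applicable(self, seed):
        sc = hd.generate_scenario(
            10 + seed,
            n=2 + seed,
            law_family=("logistic", "von_bertalanffy")[seed % 2],
            rate_family=("constant", "piecewise")[seed % 2],
        )
        assert hd.check_theorem(sc.cfg).applicable


class TestConfigRoundTrip:
    def test_write_then_read_is_identity(self, tmp_path):
        sc = hd.generate_scenario(7, n=3, law_family="von_bertalanffy", rate_family="piecewise")
        path = tmp_path / "model.json"
        hd.write_config(sc.cfg, path)
        cfg = hd.read_config(path)
        assert hd.config_to_dict(cfg) == hd.config_to_dict(sc.cfg)
        assert np.array_equal(cfg.A, sc.cfg.A)
        assert np.array_equal(cfg.x0, sc.cfg.x0)

    def test_custom_expression_law_round_trip(self):
        doc = {
            "schema_version": 1,
            "law": {"name": "custom", "g": "1 - (N/3)^2", "h": "N^2", "C": 2.0, "N1": 1.5, "N2": 6.0},
            "rates": {"kind": "constant", "r": [1.0, 0.5]},
            "A": {"n": 2, "off_diagonal": [[0, 1, 2.0], [1, 0, 1.0]]},
            "x0": [0.5, 0.5],
            "t_span": [0.0, 40.0],
        }
        cfg = hd.config_from_dict(doc)
        # symbolic parsing yields analytic derivatives: residual at tight tolerance
        assert hd.verify_h_ode(cfg.law, np.geomspace(0.3, 30.0, 100)) <= 1e-8
        assert hd.config_to_dict(hd.config_from_dict(hd.config_to_dict(cfg))) == hd.config_to_dict(cfg)

    def test_negative_offdiagonal_rate_named(self):
        doc = {
            "schema_version": 1,
            "law": {"name": "logistic", "params": {"K": 1.0, "gamma": 1.0}},
            "rates": {"kind": "constant", "r": [1.0, 1.0]},
            "A": {"n": 2, "off_diagonal": [[0, 1, -2.0]]},
            "x0": [0.5, 0.5],
            "t_span": [0.0, 1.0],
        }
        with pytest.raises(hd.ConfigError, match=r"off_diagonal\[0\]"):
            hd.config_from_dict(doc)

    def test_unknown_keys_rejected(self, two_type_config):
        doc = hd.config_to_dict(two_type_config)
        doc["surprise"] = 1
        with pytest.raises(hd.ConfigError, match="surprise"):
            hd.config_from_dict(doc)

    def test_expression_rejects_unknown_symbols(self):
        with pytest.raises(hd.ConfigError, match="unknown symbols"):
            hd.parse_expression("N + t")


class TestTrajectoryRoundTrip:
    def test_tsv_round_trip_is_exact(self, tmp_path, two_type_config):
        traj = hd.simulate_full(two_type_config, grid=50)
        path = tmp_path / "traj.tsv"
        hd.write_trajectory(traj, path)
        back = hd.read_trajectory(path)
        assert np.array_equal(back.times, traj.times)
        assert np.array_equal(back.states, traj.states)
        assert np.array_equal(back.N, traj.N)
        assert back.system_tag == "full"


class TestCli:
    def run(self, *args):
        return CliRunner().invoke(cli_main, args)

    def test_gen_simulate_check_pipeline(self, tmp_path):
        model = tmp_path / "model.json"
        res = self.run("gen-scenario", "--seed", "5", "--n", "3", "--law", "logistic",
                       "--rates", "constant", "--out", str(model))
        assert res.exit_code == 0
        res = self.run("simulate", "--config", str(model), "--out", str(tmp_path / "traj.tsv"), "--grid", "200")
        assert res.exit_code == 0
        traj = hd.read_trajectory(tmp_path / "traj.tsv")
        assert traj.states.shape == (200, 3)
        res = self.run("check-theorem", "--config", str(model), "--out", str(tmp_path / "report.json"))
        assert res.exit_code == 0
        report = json.loads((tmp_path / "report.json").read_text())
        assert report["verdict"] == "applicable"

    def test_inapplicable_model_exits_2(self, tmp_path):
        doc = {
            "schema_version": 1,
            "law": {"name": "custom", "g": "(1-N)*(2-N)*(3-N)", "N1": 0.5, "N2": 6.0},
            "rates": {"kind": "constant", "r": [1.0, 1.0]},
            "A": {"n": 2, "off_diagonal": [[0, 1, 2.0], [1, 0, 1.0]]},
            "x0": [0.5, 0.5],
            "t_span": [0.0, 10.0],
        }
        model = tmp_path / "model.json"
        model.write_text(json.dumps(doc))
        res = self.run("check-theorem", "--config", str(model), "--out", str(tmp_path / "report.json"))
        assert res.exit_code == 2
        report = json.loads((tmp_path / "report.json").read_text())
        assert report["verdict"] == "inapplicable"
        assert "multiple_roots" in report["reasons"]

    def test_spectrum_output(self, tmp_path):
        model = tmp_path / "model.json"
        self.run("gen-scenario", "--seed", "3", "--out", str(model))
        res = self.run("spectrum", "--config", str(model), "--out", str(tmp_path / "spec.json"))
        assert res.exit_code == 0
        doc = json.loads((tmp_path / "spec.json").read_text())
        assert abs(doc["mu"]) <= 1e-9
        assert doc["p"] == doc["m"] + doc["q"] - 2
        assert doc["stationary_distribution"] is not None

    def test_rerun_reproduces_outputs(self, tmp_path):
        a, b = tmp_path / "a.json", tmp_path / "b.json"
        self.run("gen-scenario", "--seed", "9", "--out", str(a))
        self.run("gen-scenario", "--seed", "9", "--out", str(b))
        assert a.read_text() == b.read_text()
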