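"""Lyapunov decay, eta envelope, Yakubovich integral and the realized gap."""

import dataclasses
import math

import numpy as np
import pytest

import hetdyn as hd


@pytest.fixture
def floored_run(two_type_config):
    traj = hd.simulate_full(two_type_config)
    r_min, t_r = hd.declare_rate_floor(two_type_config.schedule, traj)
    return two_type_config, traj, r_min, t_r


class TestLyapunovTrace:
    def test_point_evaluation(self, logistic_unit):
        # V(N) = |1-N| / N at N = 0.5 is 1
        V = abs(float(logistic_unit.g(0.5))) / float(logistic_unit.h(0.5))
        assert V == pytest.approx(1.0)

    def test_constant_rates_give_pure_exponential(self, floored_run):
        cfg, traj, r_min, t_r = floored_run
        lt = hd.lyapunov_trace(traj, cfg, r_min, t_r)
        # uniform rates: rbar = 1 exactly, so V(t) = V(0) exp(-C t)
        V0 = lt.V[0]
        assert np.abs(lt.V - V0 * np.exp(-cfg.law.C * traj.times)).max() <= 1e-8 * V0

    def test_identity_with_varying_mean_rate(self, two_type_config):
        cfg = dataclasses.replace(
            two_type_config,
            schedule=hd.make_rate_schedule({"kind": "constant", "r": [1.5, 0.3]}),
        )
        traj = hd.simulate_full(cfg)
        r_min, t_r = hd.declare_rate_floor(cfg.schedule, traj)
        lt = hd.lyapunov_trace(traj, cfg, r_min, t_r)
        assert lt.identity_rel_error <= 1e-5
        assert lt.bound_excess <= 1e-7

    def test_start_at_equilibrium_gives_zero_V(self, two_type_config):
        cfg = dataclasses.replace(two_type_config, x0=np.array([0.6, 0.4]))  # N0 = K = N*
        traj = hd.simulate_full(cfg)
        lt = hd.lyapunov_trace(traj, cfg, 1.0, 0.0)
        assert np.abs(lt.V).max() <= 1e-8

    def test_decay_to_zero(self, floored_run):
        cfg, traj, r_min, t_r = floored_run
        lt = hd.lyapunov_trace(traj, cfg, r_min, t_r)
        assert lt.V[-1] <= 1e-6 * lt.V[0]


class TestEtaBound:
    def test_constant_when_no_threshold(self, floored_run):
        cfg, traj, r_min, t_r = floored_run
        region = hd.invariant_region(cfg)
        eta = hd.eta_bound(cfg, region, r_min, 0.0)
        from hetdyn.equivalence import companion_maxima

        Q1, Q2 = companion_maxima(cfg.law, region)
        assert eta.c == pytest.approx(cfg.schedule.r_max * Q1 * Q2)
        assert eta.lam == pytest.approx(cfg.law.C * r_min)

    def test_Q1_is_max_of_h_on_region(self, two_type_config):
        # logistic K=1, h=N monotone: max over [0.25, 4] is 4 (up to 1% inflation)
        from hetdyn.equivalence import companion_maxima

        region = hd.invariant_region(two_type_config)
        Q1, _ = companion_maxima(two_type_config.law, region)
        assert Q1 == pytest.approx(4.0, rel=0.02)

    def test_envelope_holds_along_trajectory(self, floored_run):
        cfg, traj, r_min, t_r = floored_run
        eta = hd.eta_bound(cfg, hd.invariant_region(cfg), r_min, t_r)
        assert hd.eta_violation(traj, cfg, eta) <= 1e-9

    def test_eps2_scales_both_sides(self, two_type_config):
        fast = dataclasses.replace(two_type_config, eps2=2.0)
        traj = hd.simulate_full(fast)
        r_min, t_r = hd.declare_rate_floor(fast.schedule, traj)
        eta = hd.eta_bound(fast, hd.invariant_region(fast), r_min, t_r)
        base_eta = hd.eta_bound(
            dataclasses.replace(fast, eps2=1.0), hd.invariant_region(fast), r_min, t_r
        )
        assert t_r == 0.0
        assert eta.c == pytest.approx(2.0 * base_eta.c)
        assert eta.lam == pytest.approx(2.0 * base_eta.lam)
        assert hd.eta_violation(traj, fast, eta) <= 1e-9

    def test_zero_floor_rejected(self, two_type_config):
        with pytest.raises(hd.RateFloorError):
            hd.eta_bound(two_type_config, hd.invariant_region(two_type_config), 0.0, 0.0)


class TestYakubovichIntegral:
    def test_unit_case(self):
        assert hd.yakubovich_integral(0, 1.0, 1.0).value == pytest.approx(1.0)

    def test_printed_example(self):
        # p=2, c=3, lam=2: 2! * 3 * 2**-3 = 0.75
        assert hd.yakubovich_integral(2, 3.0, 2.0).value == pytest.approx(0.75)

    def test_divergence_when_mu_reaches_lam(self):
        result = hd.yakubovich_integral(1, 1.0, 1.0, mu=1.0)
        assert not result.converges and math.isinf(result.value)

    def test_shifted_exponent(self):
        # mu in (0, lam): p! c (lam-mu)**-(p+1)
        assert hd.yakubovich_integral(1, 2.0, 3.0, mu=1.0).value == pytest.approx(2.0 / 4.0)

    @pytest.mark.parametrize("p", range(7))
    @pytest.mark.parametrize("lam", [0.1, 1.0, 10.0])
    def test_closed_form_matches_quadrature(self, p, lam):
        result = hd.yakubovich_integral(p, 1.7, lam, cross_check=True, check_rtol=1e-6)
        assert result.converges

    def test_bad_lam_rejected(self):
        with pytest.raises(ValueError):
            hd.yakubovich_integral(0, 1.0, 0.0)


class TestSolutionMatching:
    def test_rescaling(self, two_type_config):
        y0 = hd.match_linear_solution(two_type_config, N_star=1.0)
        assert y0 == pytest.approx(two_type_config.x0 / two_type_config.N0)

    def test_identity_on_simplex(self, two_type_config):
        cfg = dataclasses.replace(two_type_config, x0=np.array([0.6, 0.4]))
        assert hd.match_linear_solution(cfg, N_star=1.0) == pytest.approx(cfg.x0)

    def test_degenerate_matrix_rejected(self, two_type_config):
        cfg = dataclasses.replace(two_type_config, A=np.zeros((2, 2)))
        with pytest.raises(hd.DegenerateTransitionError):
            hd.match_linear_solution(cfg, N_star=1.0)


class TestGap:
    def test_same_start_on_simplex_gap_is_noise(self, two_type_config):
        cfg = dataclasses.replace(two_type_config, x0=np.array([0.6, 0.4]))
        traj = hd.simulate_full(cfg)
        linear = hd.simulate_linear(cfg.A, cfg.x0, traj.times)
        gap = hd.equivalence_gap(traj, linear)
        assert gap.gap.max() <= 1e-8

    def test_scalar_logistic_without_transitions(self):
        cfg = hd.ModelConfig(
            law=hd.make_growth_law("logistic", {"K": 1.0, "gamma": 1.0}),
            schedule=hd.make_rate_schedule({"kind": "constant", "r": [1.0]}),
            A=np.zeros((1, 1)),
            x0=np.array([0.1]),
            t_span=(0.0, 40.0),
        )
        traj = hd.simulate_full(cfg)
        linear = hd.simulate_linear(cfg.A, np.array([1.0]), traj.times)  # y stays at K
        gap = hd.equivalence_gap(traj, linear)
        assert gap.gap_tail_max <= 1e-9
        assert gap.gap[0] == pytest.approx(0.9)

    def test_grid_mismatch_rejected(self, two_type_config):
        traj = hd.simulate_full(two_type_config)
        other = hd.simulate_linear(two_type_config.A, two_type_config.x0, traj.times[:-1])
        with pytest.raises(ValueError, match="time grid"):
            hd.equivalence_gap(traj, other)


class TestCheckTheorem:
    def test_applicable_scenario(self, two_type_config):
        report = hd.check_theorem(two_type_config)
        assert report.applicable
        assert all(report.conditions.values())
        assert report.N_star == pytest.approx(1.0)
        assert report.p == 0
        assert report.gap_tail_ratio <= 1e-5
        assert report.gap.decay_rate < 0

    def test_multi_root_inapplicable_without_crash(self, two_type_config):
        law = hd.make_growth_law(
            "custom",
            g=lambda N: (1 - np.asarray(N, float)) * (2 - np.asarray(N, float)) * (3 - np.asarray(N, float)),
            N1=0.5,
            N2=6.0,
        )
        report = hd.check_theorem(dataclasses.replace(two_type_config, law=law))
        assert report.verdict == "inapplicable"
        assert "multiple_roots" in report.reasons

    def test_zero_rates_inapplicable(self, two_type_config):
        cfg = dataclasses.replace(
            two_type_config,
            schedule=hd.make_rate_schedule({"kind": "constant", "r": [0.0, 0.0]}),
        )
        report = hd.check_theorem(cfg)
        assert report.verdict == "inapplicable"
        assert report.reasons == ["rate_floor"]
        assert not report.conditions["rate_floor_positive"]

    def test_wrong_companion_pair_flagged(self, two_type_config):
        law = hd.make_growth_law(
            "custom",
            g=lambda N: 1.0 - np.asarray(N, float),
            h=lambda N: np.ones_like(np.asarray(N, float)),
            C=1.0,
            N1=0.5,
            N2=2.0,
        )
        report = hd.check_theorem(dataclasses.replace(two_type_config, law=law))
        assert "h_invalid" in report.reasons

    def test_threshold_time_pipeline(self, two_type_config):
        sched = hd.make_rate_schedule({"kind": "piecewise", "breaks": [[0.0, [0.0, 0.0]], [1.0, [1.0, 1.0]]]})
        report = hd.check_theorem(dataclasses.replace(two_type_config, schedule=sched))
        assert report.applicable
        assert report.t_r == 1.0
        assert report.lyapunov.bound_excess <= 1e-7

    def test_limit_composition_matches_stationary_distribution(self, two_type_config):
        report = hd.check_theorem(two_type_config)
        assert report.composition_gap_full <= 1e-5
        assert report.composition_gap_linear <= 1e-5


class TestTimescale:
    def test_neutral_scaling_equals_baseline(self, two_type_config):
        base = hd.check_theorem(two_type_config)
        rows = hd.timescale_experiment(two_type_config, eps1_list=[1.0], eps2_list=[1.0])
        rep = rows[0]["report"]
        assert rep.applicable
        assert rep.gap.gap_tail_max == pytest.approx(base.gap.gap_tail_max, abs=1e-12)

    @pytest.mark.parametrize("eps1,eps2", [(100.0, 1.0), (1.0, 100.0), (0.01, 1.0)])
    def test_extreme_timescales_stay_applicable(self, two_type_config, eps1, eps2):
        rows = hd.timescale_experiment(two_type_config, eps1_list=[eps1], eps2_list=[eps2])
        rep = rows[0]["report"]
        assert rep.applicable
        assert rep.gap_tail_ratio <= 1e-5
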