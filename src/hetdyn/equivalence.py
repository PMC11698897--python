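"""Numerical execution of the asymptotic-equivalence machinery.

The claim being verified: the full system dx/dt = eps2*g(N)R(t)x + eps1*Ax
and its linear part dy/dt = eps1*Ay are asymptotically equivalent — every
solution of one is matched by a solution of the other with vanishing
1-norm difference — whenever

1. a companion pair (h, C) exists for g (so the Lyapunov-like function
   V(N) = |g(N)|/h(N) obeys dV/dt = -eps2*C*V*rbar),
2. the transition matrix is conservative (spectrum in the closed left
   half-plane with 0 an eigenvalue),
3. g has a single root N* on the invariant size window, and
4. the mean rate rbar has an eventual positive floor r_min after t_r.

Under these, V decays like V(0)exp(eps2*C*r_min*t_r)exp(-eps2*C*r_min*t),
the nonlinear term is bounded by eta(t)|x| with eta(t) = c*exp(-lam*t),
c = eps2*r_max*Q1*Q2*exp(lam*t_r), lam = eps2*C*r_min (Q1, Q2 the maxima
of h and V on the size window), and the Yakubovich integral

    integral_0^inf t**p * exp(mu*t) * eta(t) dt,   p = m + q - 2,

converges with closed form p! * c * lam**-(p+1) at mu = 0.  The pipeline
in :func:`check_theorem` evaluates each condition, simulates both systems,
and measures the actual gap |x(t) - y(t)|.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from scipy.integrate import quad

from .growth_laws import count_roots, find_equilibrium, verify_h_ode
from .rates import RateFloorError, declare_rate_floor
from .simulator import (
    InvariantRegion,
    ModelConfig,
    Trajectory,
    invariant_region,
    simulate_full,
    simulate_linear,
)
from .transitions import (
    DegenerateTransitionError,
    spectral_summary,
    stationary_distribution,
    validate_transition_matrix,
)

__all__ = [
    "LyapunovTrace",
    "EtaBound",
    "GapReport",
    "YakubovichIntegral",
    "EquivalenceReport",
    "companion_maxima",
    "lyapunov_trace",
    "eta_bound",
    "eta_violation",
    "yakubovich_integral",
    "match_linear_solution",
    "equivalence_gap",
    "recommended_horizon",
    "check_theorem",
    "timescale_experiment",
]

#: numerical allowance, relative to V(0), for the Lyapunov bound check; the
#: multiplicative tolerance alone is meaningless below solver resolution at
#: the trajectory tail (see docs/methods.md)
V_NOISE_FLOOR = 1e-7


@dataclasses.dataclass(frozen=True)
class LyapunovTrace:
    """V(N(t)) along a trajectory with its certified exponential envelope.

    ``identity_rel_error`` is max_t |V(t) - V(0)exp(-eps2*C*int rbar)|
    normalized by V(0) (the trace maximum).  ``bound_excess`` is the worst
    excess of V over the printed envelope, in the same normalization,
    after a (1 + 1e-6) multiplicative tolerance; values at or below the
    numerical floor mean the bound holds.
    """

    times: np.ndarray
    V: np.ndarray
    Q1: float
    Q2: float
    bound: np.ndarray
    identity_rel_error: float
    bound_excess: float


@dataclasses.dataclass(frozen=True)
class EtaBound:
    """Exponential envelope eta(t) = c * exp(-lam * t) for the nonlinear term."""

    c: float
    lam: float

    def __call__(self, t):
        return self.c * np.exp(-self.lam * np.asarray(t, float))


@dataclasses.dataclass(frozen=True)
class YakubovichIntegral:
    value: float
    converges: bool
    p: int
    c: float
    lam: float
    mu: float


@dataclasses.dataclass(frozen=True)
class GapReport:
    """Pointwise 1-norm gap between matched full and linear solutions."""

    times: np.ndarray
    gap: np.ndarray
    gap_tail_max: float
    decay_rate: float
    tail_fraction: float = 0.1


@dataclasses.dataclass
class EquivalenceReport:
    """Verdict of the full theorem check plus every measured diagnostic."""

    conditions: dict
    reasons: list
    verdict: str
    N_star: float | None = None
    r_min: float | None = None
    t_r: float | None = None
    p: int | None = None
    integral_value: float | None = None
    eta: EtaBound | None = None
    eta_excess: float | None = None
    lyapunov: LyapunovTrace | None = None
    gap: GapReport | None = None
    gap_tail_ratio: float | None = None
    composition_gap_full: float | None = None
    composition_gap_linear: float | None = None
    horizon: float | None = None
    trajectory: Trajectory | None = None
    linear_trajectory: Trajectory | None = None

    @property
    def applicable(self) -> bool:
        return self.verdict == "applicable"

    def to_dict(self) -> dict:
        """JSON-serializable summary (arrays and trajectories elided)."""
        return {
            "verdict": self.verdict,
            "reasons": list(self.reasons),
            "conditions": dict(self.conditions),
            "N_star": self.N_star,
            "r_min": self.r_min,
            "t_r": self.t_r,
            "p": self.p,
            "integral_value": self.integral_value,
            "eta_c": None if self.eta is None else self.eta.c,
            "eta_lam": None if self.eta is None else self.eta.lam,
            "eta_excess": self.eta_excess,
            "lyapunov_identity_rel_error": None if self.lyapunov is None else self.lyapunov.identity_rel_error,
            "lyapunov_bound_excess": None if self.lyapunov is None else self.lyapunov.bound_excess,
            "gap_tail_max": None if self.gap is None else self.gap.gap_tail_max,
            "gap_tail_ratio": self.gap_tail_ratio,
            "gap_decay_rate": None if self.gap is None else self.gap.decay_rate,
            "composition_gap_full": self.composition_gap_full,
            "composition_gap_linear": self.composition_gap_linear,
            "horizon": self.horizon,
        }


def companion_maxima(law, region: InvariantRegion, *, grid: int = 2048, inflate: float = 0.01):
    """Grid maxima Q1 = max h, Q2 = max V on [U1, U2], inflated by ``inflate``.

    The 1% inflation keeps the downstream envelope a true bound despite
    grid discretization (h and V are smooth 1-D functions on a compact
    interval, so the grid maximum undershoots by O(step**2) at most).
    """
    N = np.linspace(region.U1, region.U2, grid)
    h_vals = np.asarray(law.h(N), float)
    V_vals = np.abs(np.asarray(law.g(N), float)) / h_vals
    return float(h_vals.max() * (1 + inflate)), float(V_vals.max() * (1 + inflate))


def lyapunov_trace(traj: Trajectory, cfg: ModelConfig, r_min: float, t_r: float) -> LyapunovTrace:
    """Evaluate V along a trajectory and check its decay identity and bound.

    The identity V(t) = V(0) * exp(-eps2*C*int_0^t rbar ds) uses the
    integral of rbar carried by the solver as an augmented state (exact to
    solver tolerance).  The envelope is
    V(0) * exp(eps2*C*r_min*t_r) * exp(-eps2*C*r_min*t).
    """
    law = cfg.law
    if not law.has_companion:
        raise ValueError("Lyapunov trace requires a companion pair (h, C)")
    N = np.maximum(traj.N, 1e-300)
    V = np.abs(np.asarray(law.g(N), float)) / np.asarray(law.h(N), float)
    V0 = float(V[0])

    if traj.rbar_integral is not None:
        z = np.asarray(traj.rbar_integral, float)
    else:
        # fall back to trapezoid quadrature of the sampled mean rate
        rbar = np.array(
            [np.dot(cfg.schedule.r(t), x) / max(x.sum(), 1e-300) for t, x in zip(traj.times, traj.states)]
        )
        z = np.concatenate([[0.0], np.cumsum(0.5 * (rbar[1:] + rbar[:-1]) * np.diff(traj.times))])

    predicted = V0 * np.exp(-cfg.eps2 * law.C * z)
    scale = max(V0, 1e-300)
    identity_rel_error = float(np.abs(V - predicted).max() / scale)

    region = invariant_region(cfg)
    Q1, Q2 = companion_maxima(law, region)
    lam = cfg.eps2 * law.C * r_min
    bound = V0 * np.exp(lam * t_r) * np.exp(-lam * traj.times)
    bound_excess = float(((V - bound * (1 + 1e-6)) / scale).max())
    return LyapunovTrace(
        times=traj.times,
        V=V,
        Q1=Q1,
        Q2=Q2,
        bound=bound,
        identity_rel_error=identity_rel_error,
        bound_excess=bound_excess,
    )


def eta_bound(cfg: ModelConfig, region: InvariantRegion, r_min: float, t_r: float) -> EtaBound:
    """Envelope |nonlinear part| <= eta(t)|x| with eta(t) = c*exp(-lam*t).

    c = eps2 * r_max * Q1 * Q2 * exp(lam * t_r) and lam = eps2 * C * r_min.
    The overall eps2 factor scales both the measured nonlinear norm and the
    envelope; it never affects convergence of the Yakubovich integral.
    """
    if r_min <= 0:
        raise RateFloorError("eta bound requires a positive mean-rate floor")
    law = cfg.law
    if not law.has_companion:
        raise ValueError("eta bound requires a companion pair (h, C)")
    Q1, Q2 = companion_maxima(law, region)
    lam = cfg.eps2 * law.C * r_min
    c = cfg.eps2 * cfg.schedule.r_max * Q1 * Q2 * math.exp(lam * t_r)
    return EtaBound(c=c, lam=lam)


def eta_violation(traj: Trajectory, cfg: ModelConfig, eta: EtaBound) -> float:
    """Worst relative excess of |eps2*g(N)R(t)x|_1 over eta(t)|x|_1.

    Negative values mean the envelope holds with margin everywhere.
    """
    N = np.maximum(traj.N, 1e-300)
    gN = np.abs(np.asarray(cfg.law.g(N), float))
    flux = np.array([np.dot(cfg.schedule.r(t), x) for t, x in zip(traj.times, traj.states)])
    nonlinear = cfg.eps2 * gN * flux  # entries of g*R*x share the sign of g
    envelope = eta(traj.times) * traj.N
    scale = max(float(nonlinear.max()), 1e-300)
    return float(((nonlinear - envelope) / scale).max())


def yakubovich_integral(
    p: int,
    c: float,
    lam: float,
    mu: float = 0.0,
    *,
    cross_check: bool = False,
    check_rtol: float = 1e-6,
) -> YakubovichIntegral:
    """Closed form of integral_0^inf t**p exp(mu*t) * c*exp(-lam*t) dt.

    Converges iff mu < lam, to p! * c * (lam - mu)**-(p+1); reported as
    divergent otherwise.  With ``cross_check`` the closed form is validated
    against adaptive quadrature and a mismatch beyond ``check_rtol`` raises.
    """
    if p < 0:
        raise ValueError("p must be a non-negative integer")
    if lam <= 0:
        raise ValueError("lam must be positive")
    if mu >= lam:
        return YakubovichIntegral(value=math.inf, converges=False, p=p, c=c, lam=lam, mu=mu)
    value = c * math.factorial(p) * (lam - mu) ** (-(p + 1))
    if cross_check:
        numeric, _ = quad(
            lambda t: c * t**p * math.exp((mu - lam) * t),
            0.0,
            np.inf,
            epsabs=0.0,
            epsrel=1e-10,
            points=None,
            limit=200,
        )
        if abs(numeric - value) > check_rtol * abs(value):
            raise ArithmeticError(
                f"closed form {value} disagrees with quadrature {numeric} beyond rtol {check_rtol}"
            )
    return YakubovichIntegral(value=value, converges=True, p=p, c=c, lam=lam, mu=mu)


def match_linear_solution(cfg: ModelConfig, N_star: float) -> np.ndarray:
    """Initial state of the matched linear solution: y0 = (N*/N0) * x0.

    The equivalence definition is existential; the composition-preserving
    rescaling onto the carrying simplex (1-norm N*) makes both flows tend
    to N* * pi and keeps early-time gaps interpretable.  Requires a simple
    zero eigenvalue (raises :class:`DegenerateTransitionError` otherwise,
    in which case the limit composition is x0-dependent and no canonical
    match exists).
    """
    stationary_distribution(cfg.A)  # raises when the zero eigenvalue is degenerate
    return (float(N_star) / cfg.N0) * cfg.x0


def equivalence_gap(
    full: Trajectory,
    linear: Trajectory,
    *,
    atol: float = 1e-12,
    rtol: float = 1e-10,
    tail_fraction: float = 0.1,
) -> GapReport:
    """1-norm gap series |x(t) - y(t)| with tail maximum and decay-rate fit.

    The decay rate is the slope of a log-linear fit over the final half of
    the horizon, restricted to points with gap above the solver noise floor
    100*(atol + rtol*max N) so that noise is not fitted; when the final
    half is entirely at the floor the fit widens to every point above it,
    and is NaN when too few remain (gap already indistinguishable from 0).
    """
    if full.times.shape != linear.times.shape or not np.array_equal(full.times, linear.times):
        raise ValueError("full and linear trajectories must share the same time grid")
    gap = np.abs(full.states - linear.states).sum(axis=1)
    k_tail = max(1, int(math.ceil(tail_fraction * gap.size)))
    gap_tail_max = float(gap[-k_tail:].max())

    floor = 100.0 * (atol + rtol * float(full.N.max()))
    half = full.times >= full.times[full.times.size // 2]
    mask = half & (gap > floor)
    if mask.sum() < 3:
        mask = gap > floor
    if mask.sum() >= 3:
        slope = float(np.polyfit(full.times[mask], np.log(gap[mask]), 1)[0])
    else:
        slope = float("nan")
    return GapReport(times=full.times, gap=gap, gap_tail_max=gap_tail_max,
                     decay_rate=slope, tail_fraction=tail_fraction)


def recommended_horizon(cfg: ModelConfig, *, decades: float = 20.0, fallback: float = 50.0) -> float:
    """Horizon long enough for both decay channels to reach exp(-decades).

    The gap between the two systems decays through the nonlinear envelope
    (rate eps2*C*r_min_guess, using the schedule-only floor guess) and
    through linear mixing (rate eps1 * slowest nonzero spectral decay of
    A); the horizon covers the slower of the two.  ``fallback`` is used
    when neither rate is available/positive (e.g. zero rates or h missing),
    which only happens on runs headed for an inapplicable verdict.
    """
    candidates = []
    if cfg.law.C is not None and cfg.schedule.floor_guess > 0:
        candidates.append(decades / (cfg.eps2 * cfg.law.C * cfg.schedule.floor_guess))
    eigs = np.linalg.eigvals(cfg.A)
    decay_rates = sorted(-e.real for e in eigs if -e.real > 1e-9)
    if decay_rates:
        candidates.append(decades / (cfg.eps1 * decay_rates[0]))
    return max(candidates) if candidates else fallback


def check_theorem(
    cfg: ModelConfig,
    *,
    horizon: float | None = None,
    grid: int = 1000,
    rtol: float = 1e-10,
    atol: float = 1e-12,
    gap_tol: float = 1e-5,
    keep_trajectories: bool = False,
) -> EquivalenceReport:
    """Run the full verification pipeline and assemble a single verdict.

    Assumption failures (missing/invalid companion pair, multi-root g, no
    positive rate floor, degenerate zero eigenvalue) map to verdict
    ``inapplicable`` with a reason, never to a crash.  When every condition
    holds, both systems are simulated to the recommended horizon and the
    realized gap, Lyapunov decay, eta envelope and Yakubovich integral are
    all measured and reported.
    """
    conditions = {
        "h_exists": False,
        "prop1_holds": False,
        "unique_root": False,
        "rate_floor_positive": False,
    }
    reasons: list[str] = []
    report = EquivalenceReport(conditions=conditions, reasons=reasons, verdict="inapplicable")

    # condition 1: companion pair registered and solving the companion ODE
    law = cfg.law
    if not law.has_companion:
        reasons.append("h_missing")
    else:
        probe = np.geomspace(min(law.N1, cfg.N0) / 10.0, 10.0 * max(law.N2, cfg.N0), 256)
        residual = verify_h_ode(law, probe)
        tol = 1e-8 if law.gh_prime is not None else 1e-5
        if residual <= tol:
            conditions["h_exists"] = True
        else:
            reasons.append("h_invalid")

    # condition 2: conservative spectrum (left half-plane, zero eigenvalue)
    try:
        if not validate_transition_matrix(cfg.A).ok:
            raise ValueError("invalid transition matrix")
        summary = spectral_summary(cfg.A)
        conditions["prop1_holds"] = True
        report.p = summary.p
    except (ValueError, np.linalg.LinAlgError):
        summary = None
        reasons.append("spectral")

    # condition 3: a single size equilibrium
    n_roots = count_roots(law)
    if n_roots == 1:
        conditions["unique_root"] = True
        equilibrium = find_equilibrium(law)
        report.N_star = equilibrium.N_star
    elif n_roots == 0:
        reasons.append("no_root")
    else:
        reasons.append("multiple_roots")

    if reasons:
        return report

    # simulate the full system and certify the mean-rate floor (condition 4)
    T = horizon if horizon is not None else recommended_horizon(cfg)
    report.horizon = T
    run_cfg = dataclasses.replace(cfg, t_span=(0.0, T))
    traj = simulate_full(run_cfg, grid=grid, rtol=rtol, atol=atol)
    try:
        r_min, t_r = declare_rate_floor(cfg.schedule, traj)
        conditions["rate_floor_positive"] = True
        report.r_min, report.t_r = r_min, t_r
    except RateFloorError:
        reasons.append("rate_floor")
        return report

    region = invariant_region(run_cfg)
    report.lyapunov = lyapunov_trace(traj, run_cfg, r_min, t_r)
    eta = eta_bound(run_cfg, region, r_min, t_r)
    report.eta = eta
    report.eta_excess = eta_violation(traj, run_cfg, eta)
    report.integral_value = yakubovich_integral(summary.p, eta.c, eta.lam, 0.0).value

    try:
        y0 = match_linear_solution(run_cfg, report.N_star)
    except DegenerateTransitionError:
        reasons.append("nonsimple_zero_eigenvalue")
        return report
    linear = simulate_linear(cfg.A, y0, traj.times, eps1=cfg.eps1)
    report.gap = equivalence_gap(traj, linear, atol=atol)
    report.gap_tail_ratio = report.gap.gap_tail_max / report.N_star

    pi = stationary_distribution(cfg.A)
    report.composition_gap_full = float(np.abs(traj.states[-1] / traj.N[-1] - pi).sum())
    report.composition_gap_linear = float(np.abs(linear.states[-1] / linear.N[-1] - pi).sum())

    if keep_trajectories:
        report.trajectory = traj
        report.linear_trajectory = linear

    report.verdict = "applicable" if all(conditions.values()) else "inapplicable"
    return report


def timescale_experiment(cfg: ModelConfig, eps1_list=(0.01, 1.0, 100.0), eps2_list=(0.01, 1.0, 100.0), **kwargs):
    """Re-run the theorem check over a grid of time-scale factors.

    Horizons rescale automatically through :func:`recommended_horizon`, so
    the verdict should remain ``applicable`` for every (eps1, eps2) pair —
    the equivalence does not rest on a time-scale separation between the
    nonlinear and linear parts, nor on which one is faster.
    """
    results = []
    for e1 in eps1_list:
        for e2 in eps2_list:
            scaled = dataclasses.replace(cfg, eps1=float(e1), eps2=float(e2))
            results.append({"eps1": float(e1), "eps2": float(e2), "report": check_theorem(scaled, **kwargs)})
    return results
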