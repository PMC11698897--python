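"""Seeded synthetic scenario generation.

A scenario is a complete, valid :class:`~hetdyn.simulator.ModelConfig`
drawn deterministically from a single integer seed: a growth law with
random positive parameters, a random conservative transition matrix with a
simple zero eigenvalue and well-mixed switching, a positive rate schedule
and an initial state on a random ray of the simplex.  By construction
every scenario satisfies all four assumptions of the equivalence theorem,
so ``check_theorem`` must return verdict ``applicable`` on every draw —
the property suites lean on this.

Parameter ranges (methods note records the rationale): carrying scales
(K, equilibrium size N*) log-uniform over two decades [1, 100]; shape
exponent gamma log-uniform on [0.5, 2]; intrinsic rates log-uniform on
[0.2, 2] per type.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .equivalence import recommended_horizon
from .growth_laws import GrowthLaw, make_growth_law
from .rates import make_rate_schedule
from .simulator import ModelConfig
from .transitions import random_transition_matrix

__all__ = ["Scenario", "generate_scenario", "LAW_FAMILIES", "RATE_FAMILIES"]

LAW_FAMILIES = ("logistic", "gompertz", "von_bertalanffy")
RATE_FAMILIES = ("constant", "piecewise", "sinusoid")

#: reject transition matrices whose slowest nonzero spectral decay rate is
#: below this (poorly mixed switching would demand very long horizons)
MIN_SPECTRAL_GAP = 0.1


@dataclasses.dataclass(frozen=True)
class Scenario:
    """A seeded model configuration plus the draws that produced it."""

    seed: int
    cfg: ModelConfig
    provenance: dict


def _log_uniform(rng: np.random.Generator, lo: float, hi: float, size=None):
    return 10.0 ** rng.uniform(np.log10(lo), np.log10(hi), size=size)


def _draw_law(rng: np.random.Generator, family: str) -> GrowthLaw:
    gamma = float(_log_uniform(rng, 0.5, 2.0))
    if family in ("logistic", "gompertz"):
        K = float(_log_uniform(rng, 1.0, 100.0))
        return make_growth_law(family, {"K": K, "gamma": gamma})
    if family == "von_bertalanffy":
        n_star = float(_log_uniform(rng, 1.0, 100.0))
        w = float(_log_uniform(rng, 0.5, 2.0))
        v = w * n_star**gamma
        return make_growth_law(family, {"v": v, "w": w, "gamma": gamma})
    raise ValueError(f"unknown law family {family!r}; expected one of {LAW_FAMILIES}")


def _draw_schedule(rng: np.random.Generator, family: str, n: int):
    if family == "constant":
        return make_rate_schedule({"kind": "constant", "r": _log_uniform(rng, 0.2, 2.0, n).tolist()})
    if family == "piecewise":
        n_seg = int(rng.integers(2, 4))
        t_break = np.concatenate([[0.0], np.sort(_log_uniform(rng, 0.3, 3.0, n_seg - 1))])
        breaks = [[float(t), _log_uniform(rng, 0.2, 2.0, n).tolist()] for t in t_break]
        return make_rate_schedule({"kind": "piecewise", "breaks": breaks})
    if family == "sinusoid":
        offset = _log_uniform(rng, 0.5, 2.0, n)
        amplitude = offset * rng.uniform(0.1, 0.8, n)
        return make_rate_schedule(
            {
                "kind": "sinusoid",
                "offset": offset.tolist(),
                "amplitude": amplitude.tolist(),
                "period": float(_log_uniform(rng, 1.0, 10.0)),
            }
        )
    raise ValueError(f"unknown rate family {family!r}; expected one of {RATE_FAMILIES}")


def _draw_matrix(rng: np.random.Generator, n: int, density: float, max_tries: int = 100) -> np.ndarray:
    for _ in range(max_tries):
        A = random_transition_matrix(n, density=density, rate_scale=1.0, rng=rng)
        decay = sorted(-e.real for e in np.linalg.eigvals(A) if -e.real > 1e-9)
        if decay and decay[0] >= MIN_SPECTRAL_GAP:
            return A
    raise RuntimeError(f"no well-mixed transition matrix found in {max_tries} draws")


def generate_scenario(
    seed: int,
    n: int = 3,
    law_family: str = "logistic",
    rate_family: str = "constant",
    density: float = 0.8,
) -> Scenario:
    """Draw a deterministic, theorem-applicable scenario from a seed."""
    if n < 2:
        raise ValueError("scenario generation needs n >= 2 cell types")
    rng = np.random.default_rng(seed)
    law = _draw_law(rng, law_family)
    A = _draw_matrix(rng, n, density)
    schedule = _draw_schedule(rng, rate_family, n)

    weights = rng.dirichlet(np.ones(n))
    N0 = float(_log_uniform(rng, law.N1 / 2.0, 2.0 * law.N2))
    x0 = N0 * weights

    cfg = ModelConfig(law=law, schedule=schedule, A=A, x0=x0, t_span=(0.0, 1.0))
    cfg = dataclasses.replace(cfg, t_span=(0.0, recommended_horizon(cfg)))
    provenance = {
        "seed": int(seed),
        "n": int(n),
        "law_family": law_family,
        "rate_family": rate_family,
        "density": float(density),
        "law_params": dict(law.params),
        "N0": N0,
    }
    return Scenario(seed=int(seed), cfg=cfg, provenance=provenance)
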