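"""Growth-modulation laws g(N) and their companion pairs (h, C).

The population model couples a scalar growth-modulation function ``g`` of the
total population size ``N`` with linear type transitions.  ``g`` must be
positive below some size ``N1`` and negative above some size ``N2`` (growth
saturates).  The asymptotic-equivalence theorem additionally requires a
positive companion function ``h(N)`` and a positive constant ``C`` solving

    -C / (N * h(N)) = d/dN [ g(N) / h(N) ],     N > 0.

Three classical tumor-growth families satisfy this with closed-form (g, h, C):

==========================  =====================  ==========  =======
family                      g(N)                   h(N)        C
==========================  =====================  ==========  =======
generalized logistic        1 - (N/K)**gamma       N**gamma    gamma
generalized Gompertz        gamma * ln(K/N)        1           gamma
generalized von Bertalanffy v*N**-gamma - w        N**-gamma   w*gamma
==========================  =====================  ==========  =======

At the unique root ``N*`` of ``g`` the companion equation reduces to the
identity ``N* g'(N*) = -C``, which forces ``g'(N*) < 0`` and hence uniqueness
and stability of the size equilibrium.
"""

from __future__ import annotations

import dataclasses
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "GrowthLaw",
    "EquilibriumReport",
    "REGISTRY",
    "make_growth_law",
    "eval_g",
    "verify_h_ode",
    "find_equilibrium",
    "count_roots",
]

#: names of the built-in growth-law families
REGISTRY = ("logistic", "gompertz", "von_bertalanffy")

ScalarFunc = Callable[[np.ndarray], np.ndarray]


@dataclasses.dataclass(frozen=True)
class GrowthLaw:
    """A growth-modulation function with optional companion pair.

    Attributes
    ----------
    name : str
        Family name (``logistic``, ``gompertz``, ``von_bertalanffy`` or
        ``custom``).
    params : dict
        Strictly positive parameters of the family.
    g, g_prime : callable
        The modulation function and its derivative (vectorized over N > 0).
    h : callable or None
        Companion function, positive on N > 0, if known.
    C : float or None
        Companion constant, positive, if known.
    N1, N2 : float
        Sign-bracketing sizes: g > 0 on (0, N1), g < 0 on (N2, inf).
    gh_prime : callable or None
        Analytic derivative of g/h when available; ``verify_h_ode`` falls
        back to a central finite difference otherwise.
    exprs : dict or None
        Source expression strings for config-defined custom laws (used only
        for serialization round-trips).
    """

    name: str
    params: Mapping[str, float]
    g: ScalarFunc
    g_prime: ScalarFunc
    h: ScalarFunc | None
    C: float | None
    N1: float
    N2: float
    gh_prime: ScalarFunc | None = None
    exprs: Mapping[str, str] | None = None

    @property
    def has_companion(self) -> bool:
        """Whether the (h, C) pair needed by the theorem check is available."""
        return self.h is not None and self.C is not None

    def __post_init__(self):
        if not (0.0 < self.N1 < self.N2):
            raise ValueError(f"need 0 < N1 < N2, got N1={self.N1}, N2={self.N2}")
        for key, value in self.params.items():
            if not value > 0:
                raise ValueError(f"parameter {key!r} must be positive, got {value}")


@dataclasses.dataclass(frozen=True)
class EquilibriumReport:
    """Result of root-finding on g.

    ``slope_identity_residual`` is |N* g'(N*) + C| (NaN when the law has no
    companion constant).  ``unique`` is True when exactly one sign-change
    root was found on the search interval.
    """

    N_star: float
    slope: float
    slope_identity_residual: float
    n_roots_found: int
    unique: bool
    roots: tuple[float, ...] = ()


def _require_params(params: Mapping[str, float], names: Sequence[str], law: str) -> dict:
    out = {}
    for key in names:
        if key not in params:
            raise ValueError(f"{law} law requires parameter {key!r}")
        value = float(params[key])
        if not np.isfinite(value) or value <= 0:
            raise ValueError(f"{law} parameter {key!r} must be a positive real, got {value}")
        out[key] = value
    extra = set(params) - set(names)
    if extra:
        raise ValueError(f"unknown parameters for {law} law: {sorted(extra)}")
    return out


def make_growth_law(
    name: str,
    params: Mapping[str, float] | None = None,
    *,
    g: ScalarFunc | None = None,
    g_prime: ScalarFunc | None = None,
    h: ScalarFunc | None = None,
    C: float | None = None,
    N1: float | None = None,
    N2: float | None = None,
    exprs: Mapping[str, str] | None = None,
) -> GrowthLaw:
    """Build a :class:`GrowthLaw` from a registry family or custom callables.

    For ``custom`` laws the caller supplies ``g`` (and optionally ``g_prime``,
    the companion pair ``h``/``C``, and the sign brackets ``N1``/``N2``).
    Supplying only one of ``h`` and ``C`` is rejected: the companion equation
    constrains them jointly.
    """
    params = dict(params or {})

    if name == "logistic":
        p = _require_params(params, ("K", "gamma"), name)
        K, gam = p["K"], p["gamma"]
        return GrowthLaw(
            name=name,
            params=p,
            g=lambda N: 1.0 - (np.asarray(N, float) / K) ** gam,
            g_prime=lambda N: -(gam / K) * (np.asarray(N, float) / K) ** (gam - 1.0),
            h=lambda N: np.asarray(N, float) ** gam,
            C=gam,
            N1=K / 2.0,
            N2=2.0 * K,
            # g/h = N**-gamma - K**-gamma
            gh_prime=lambda N: -gam * np.asarray(N, float) ** (-gam - 1.0),
        )

    if name == "gompertz":
        p = _require_params(params, ("K", "gamma"), name)
        K, gam = p["K"], p["gamma"]
        return GrowthLaw(
            name=name,
            params=p,
            g=lambda N: gam * np.log(K / np.asarray(N, float)),
            g_prime=lambda N: -gam / np.asarray(N, float),
            h=lambda N: np.ones_like(np.asarray(N, float)),
            C=gam,
            N1=K / 2.0,
            N2=2.0 * K,
            gh_prime=lambda N: -gam / np.asarray(N, float),
        )

    if name == "von_bertalanffy":
        p = _require_params(params, ("v", "w", "gamma"), name)
        v, w, gam = p["v"], p["w"], p["gamma"]
        n_star = (w / v) ** (-1.0 / gam)  # root of v*N**-gamma - w
        return GrowthLaw(
            name=name,
            params=p,
            g=lambda N: v * np.asarray(N, float) ** (-gam) - w,
            g_prime=lambda N: -gam * v * np.asarray(N, float) ** (-gam - 1.0),
            h=lambda N: np.asarray(N, float) ** (-gam),
            C=w * gam,
            N1=n_star / 2.0,
            N2=2.0 * n_star,
            # g/h = v - w*N**gamma
            gh_prime=lambda N: -w * gam * np.asarray(N, float) ** (gam - 1.0),
        )

    if name == "custom":
        if g is None:
            raise ValueError("custom law requires a g callable")
        if (h is None) != (C is None):
            raise ValueError("custom law must supply both h and C, or neither")
        if C is not None and not C > 0:
            raise ValueError(f"companion constant C must be positive, got {C}")
        if N1 is None or N2 is None:
            raise ValueError("custom law requires N1 and N2 sign brackets")
        if g_prime is None:
            g_prime = _central_difference(g)
        return GrowthLaw(
            name=name,
            params={k: float(v) for k, v in params.items()},
            g=g,
            g_prime=g_prime,
            h=h,
            C=None if C is None else float(C),
            N1=float(N1),
            N2=float(N2),
            gh_prime=None,
            exprs=dict(exprs) if exprs else None,
        )

    raise ValueError(f"unknown growth law {name!r}; expected one of {REGISTRY + ('custom',)}")


def _central_difference(f: ScalarFunc, rel_step: float = 1e-6) -> ScalarFunc:
    def deriv(N):
        N = np.asarray(N, float)
        step = rel_step * np.maximum(np.abs(N), 1e-300)
        return (np.asarray(f(N + step), float) - np.asarray(f(N - step), float)) / (2.0 * step)

    return deriv


def eval_g(law: GrowthLaw, N) -> np.ndarray | float:
    """Evaluate g(N); rejects non-positive sizes."""
    arr = np.asarray(N, dtype=float)
    if np.any(arr <= 0):
        raise ValueError("population size N must be positive")
    out = law.g(arr)
    return float(out) if np.isscalar(N) or arr.ndim == 0 else np.asarray(out, float)


def verify_h_ode(law: GrowthLaw, grid) -> float:
    """Max residual of the companion equation -C/(N h) = d/dN (g/h) on a grid.

    Uses the analytic derivative of g/h when the law provides one, else a
    central finite difference with relative step 1e-6 (custom laws; the
    matching residual tolerance is then ~1e-5 rather than ~1e-8).
    """
    if not law.has_companion:
        raise ValueError(f"law {law.name!r} has no companion pair (h, C)")
    grid = np.asarray(grid, dtype=float)
    if np.any(grid <= 0):
        raise ValueError("grid points must be positive")
    if law.gh_prime is not None:
        d_ratio = np.asarray(law.gh_prime(grid), float)
    else:
        ratio = lambda N: np.asarray(law.g(N), float) / np.asarray(law.h(N), float)
        d_ratio = _central_difference(ratio)(grid)
    residual = np.abs(law.C / (grid * np.asarray(law.h(grid), float)) + d_ratio)
    return float(residual.max())


def _default_interval(law: GrowthLaw) -> tuple[float, float]:
    # g > 0 at N1/2 and g < 0 at 4*N2 by the sign conditions
    return law.N1 / 2.0, 4.0 * law.N2


def _scan_roots(law: GrowthLaw, lo: float, hi: float, scan_points: int):
    """Locate sign-change brackets (and exact grid zeros) of g on [lo, hi]."""
    grid = np.geomspace(lo, hi, scan_points)
    vals = np.asarray(law.g(grid), float)
    signs = np.sign(vals)

    roots: list[float] = []
    brackets: list[tuple[float, float]] = []

    nonzero_idx = np.flatnonzero(signs != 0)
    for a, b in zip(nonzero_idx[:-1], nonzero_idx[1:]):
        if signs[a] * signs[b] < 0:
            brackets.append((grid[a], grid[b]))

    # runs of exact zeros: a root regardless of flanking signs; when the
    # flanking signs are opposite the bracket above already covers it
    i = 0
    while i < len(signs):
        if signs[i] == 0:
            j = i
            while j + 1 < len(signs) and signs[j + 1] == 0:
                j += 1
            left = signs[i - 1] if i > 0 else 0
            right = signs[j + 1] if j + 1 < len(signs) else 0
            if left == 0 or right == 0 or left == right:
                roots.append(float(grid[(i + j) // 2]))
            i = j + 1
        else:
            i += 1

    for a, b in brackets:
        roots.append(float(brentq(lambda N: float(law.g(N)), a, b, xtol=1e-13 * a, rtol=1e-12)))
    return sorted(roots)


def count_roots(law: GrowthLaw, search_interval=None, scan_points: int = 1024) -> int:
    """Number of sign-change roots of g on the interval (scan-grid bracket count).

    The asymptotic-equivalence theorem requires a unique root; callers treat
    a count > 1 as "theorem inapplicable".
    """
    lo, hi = search_interval if search_interval is not None else _default_interval(law)
    if not (0 < lo < hi):
        raise ValueError("need 0 < lo < hi")
    if scan_points < 10:
        raise ValueError("scan_points must be >= 10")
    return len(_scan_roots(law, lo, hi, scan_points))


def find_equilibrium(law: GrowthLaw, search_interval=None, scan_points: int = 1024) -> EquilibriumReport:
    """Locate the size equilibria N* (roots of g) and check N* g'(N*) = -C.

    Scans a log-spaced grid, brackets sign changes and refines each with a
    bracketed scalar root-finder.  Raises if no root is found on the
    interval.
    """
    lo, hi = search_interval if search_interval is not None else _default_interval(law)
    if not (0 < lo < hi):
        raise ValueError("need 0 < lo < hi")
    roots = _scan_roots(law, lo, hi, scan_points)
    if not roots:
        raise ValueError(f"g has no sign change on [{lo}, {hi}]")
    n_star = roots[0]
    slope = float(law.g_prime(n_star))
    if law.C is not None:
        residual = abs(n_star * slope + law.C)
    else:
        residual = float("nan")
    return EquilibriumReport(
        N_star=n_star,
        slope=slope,
        slope_identity_residual=residual,
        n_roots_found=len(roots),
        unique=len(roots) == 1,
        roots=tuple(roots),
    )
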