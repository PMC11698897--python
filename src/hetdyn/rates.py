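"""Per-type intrinsic rate schedules r_i(t) and the abundance-weighted mean.

Each cell type i carries an intrinsic (birth minus death) rate r_i(t) >= 0.
The model assumptions constrain the abundance-weighted average

    rbar(t) = sum_i r_i(t) x_i(t) / sum_i x_i(t)

to be non-negative, integrable and eventually bounded below: there must be
a time t_r and a floor r_min > 0 with rbar(t) >= r_min for t >= t_r.  The
floor and threshold cannot be read off the schedule alone (rbar depends on
the trajectory through the weights), so they are certified along a
simulated trajectory by :func:`declare_rate_floor`.

Three schedule kinds are registered: ``constant``, ``piecewise`` (constant
between breakpoints) and ``sinusoid`` (positive offset plus sine).  r_max
is the supremum over time of the 1-norm of diag(r(t)), i.e. of max_i
r_i(t); for all three kinds the exact supremum is available.
"""

from __future__ import annotations

import dataclasses
from typing import Callable, Mapping

import numpy as np

__all__ = ["RateFloorError", "RateSchedule", "make_rate_schedule", "mean_rate", "declare_rate_floor"]


class RateFloorError(ValueError):
    """The mean rate has no positive eventual floor (model assumption fails)."""


@dataclasses.dataclass(frozen=True)
class RateSchedule:
    """Vector-valued rate schedule with its exact bounds.

    ``floor_guess`` is min_i inf_t r_i(t), a schedule-only lower bound on
    rbar used for horizon selection before any trajectory exists (it is 0
    whenever some type's rate vanishes somewhere, in which case the true
    floor must come from :func:`declare_rate_floor`).
    """

    n: int
    kind: str
    r: Callable[[float], np.ndarray]
    r_max: float
    floor_guess: float
    breakpoints: tuple[float, ...]
    spec: Mapping


def _as_rate_vector(values, n=None) -> np.ndarray:
    vec = np.asarray(values, dtype=float)
    if vec.ndim != 1 or vec.size == 0:
        raise ValueError("rate vector must be non-empty and one-dimensional")
    if n is not None and vec.size != n:
        raise ValueError(f"rate vector length {vec.size} != {n}")
    if np.any(vec < 0):
        raise ValueError(f"intrinsic rates must be non-negative, got {vec.tolist()}")
    if not np.all(np.isfinite(vec)):
        raise ValueError("intrinsic rates must be finite")
    return vec


def make_rate_schedule(spec: Mapping) -> RateSchedule:
    """Build a schedule from a declarative spec dict.

    Accepted forms::

        {"kind": "constant", "r": [1.0, 0.5]}
        {"kind": "constant", "b": [2.0, 1.0], "d": [1.0, 0.5]}   # r = b - d
        {"kind": "piecewise", "breaks": [[0.0, [0, 0]], [1.0, [1, 1]]]}
        {"kind": "sinusoid", "offset": [...], "amplitude": [...], "period": p}

    Negative rates (including b - d < 0 anywhere) are rejected.
    """
    if not spec:
        raise ValueError("empty rate-schedule spec")
    spec = dict(spec)
    kind = spec.get("kind")

    if kind == "constant":
        if "b" in spec or "d" in spec:
            b = np.asarray(spec["b"], dtype=float)
            d = np.asarray(spec["d"], dtype=float)
            if b.shape != d.shape:
                raise ValueError("b and d vectors must have equal length")
            vec = _as_rate_vector(b - d)
            spec = {"kind": "constant", "r": vec.tolist()}
        else:
            vec = _as_rate_vector(spec["r"])
        n = vec.size
        return RateSchedule(
            n=n,
            kind=kind,
            r=lambda t, _v=vec: _v,
            r_max=float(vec.max()),
            floor_guess=float(vec.min()),
            breakpoints=(),
            spec=spec,
        )

    if kind == "piecewise":
        breaks = spec.get("breaks")
        if not breaks:
            raise ValueError("piecewise schedule needs non-empty 'breaks'")
        t_breaks = np.array([float(t) for t, _ in breaks])
        if t_breaks[0] != 0.0:
            raise ValueError("first piecewise segment must start at t=0")
        if np.any(np.diff(t_breaks) <= 0):
            raise ValueError("piecewise break times must be strictly increasing")
        vecs = [_as_rate_vector(v) for _, v in breaks]
        n = vecs[0].size
        for v in vecs:
            if v.size != n:
                raise ValueError("all piecewise segments must have the same length")
        table = np.vstack(vecs)

        def r(t, _tb=t_breaks, _tab=table):
            idx = int(np.searchsorted(_tb, t, side="right")) - 1
            return _tab[max(idx, 0)]

        return RateSchedule(
            n=n,
            kind=kind,
            r=r,
            r_max=float(table.max()),
            floor_guess=float(table.min()),
            breakpoints=tuple(float(t) for t in t_breaks[1:]),
            spec={"kind": "piecewise", "breaks": [[float(t), v.tolist()] for t, v in zip(t_breaks, vecs)]},
        )

    if kind == "sinusoid":
        offset = _as_rate_vector(spec["offset"])
        amplitude = np.asarray(spec["amplitude"], dtype=float)
        if amplitude.shape != offset.shape:
            raise ValueError("offset and amplitude must have equal length")
        period = float(spec["period"])
        if period <= 0:
            raise ValueError("period must be positive")
        if np.any(offset - np.abs(amplitude) < 0):
            raise ValueError("sinusoid rates dip below zero: need offset >= |amplitude|")
        omega = 2.0 * np.pi / period
        n = offset.size
        return RateSchedule(
            n=n,
            kind=kind,
            r=lambda t, _o=offset, _a=amplitude, _w=omega: _o + _a * np.sin(_w * t),
            r_max=float((offset + np.abs(amplitude)).max()),
            floor_guess=float((offset - np.abs(amplitude)).min()),
            breakpoints=(),
            spec={
                "kind": "sinusoid",
                "offset": offset.tolist(),
                "amplitude": amplitude.tolist(),
                "period": period,
            },
        )

    raise ValueError(f"unknown rate-schedule kind {kind!r}")


def mean_rate(schedule: RateSchedule, x, t: float) -> float:
    """Abundance-weighted mean rate rbar(t) = sum r_i(t) x_i / sum x_i."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("abundances must be non-negative")
    total = x.sum()
    if total <= 0:
        raise ValueError("total abundance must be positive")
    return float(np.dot(schedule.r(t), x) / total)


def declare_rate_floor(
    schedule: RateSchedule,
    trajectory,
    *,
    zero_tol: float = 1e-12,
) -> tuple[float, float]:
    """Certify (r_min, t_r) along a simulated trajectory.

    t_r is the earliest time after the last vanishing of rbar; when the
    schedule has breakpoints the threshold snaps to the breakpoint in the
    bracketing grid interval (the jump, not the sample after it).  r_min is
    the infimum of rbar over grid times >= t_r.  Raises
    :class:`RateFloorError` when rbar still vanishes at the end of the
    horizon or the certified floor is not positive.
    """
    times = np.asarray(trajectory.times, dtype=float)
    states = np.asarray(trajectory.states, dtype=float)
    rbar = np.array([mean_rate(schedule, states[k], times[k]) for k in range(len(times))])

    zero = rbar <= zero_tol
    if not zero.any():
        t_r = 0.0
    else:
        i = int(np.flatnonzero(zero)[-1])
        if i >= len(times) - 1:
            raise RateFloorError("mean rate rbar still vanishes at the end of the horizon")
        candidates = [b for b in schedule.breakpoints if times[i] < b <= times[i + 1]]
        t_r = max(candidates) if candidates else float(times[i + 1])
    tail = rbar[times >= t_r - 1e-15]
    r_min = float(tail.min())
    if r_min <= 0:
        raise RateFloorError(f"certified mean-rate floor is not positive (r_min={r_min})")
    return r_min, t_r
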