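"""Config, trajectory and report serialization.

A model lives in a single JSON document::

    {
      "schema_version": 1,
      "law": {"name": "logistic", "params": {"K": 100.0, "gamma": 1.0}},
      "rates": {"kind": "constant", "r": [1.0, 0.5]},
      "A": {"n": 2, "off_diagonal": [[0, 1, 2.0], [1, 0, 1.0]]},
      "x0": [0.5, 0.5],
      "t_span": [0.0, 20.0],
      "eps1": 1.0,
      "eps2": 1.0
    }

Only off-diagonal transition rates are user-specified; diagonals are
derived so the conservation condition holds exactly.  Custom growth laws
supply expression strings in N (operators + - * / ^, functions ln/log,
exp, sqrt), parsed symbolically so that derivatives — including the
derivative of g/h needed by the companion-equation residual — are
analytic.  Unknown keys are rejected with the offending field path.

Trajectories are TSV (columns t, x_1..x_n, N, system_tag) at full float64
precision; reports are JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import sympy

from .growth_laws import GrowthLaw, make_growth_law
from .rates import make_rate_schedule
from .simulator import ModelConfig, Trajectory
from .transitions import transition_matrix

__all__ = [
    "ConfigError",
    "parse_expression",
    "read_config",
    "write_config",
    "config_to_dict",
    "config_from_dict",
    "write_trajectory",
    "read_trajectory",
    "write_report",
]

SCHEMA_VERSION = 1

_N = sympy.Symbol("N", positive=True)
_ALLOWED_LOCALS = {
    "N": _N,
    "ln": sympy.log,
    "log": sympy.log,
    "exp": sympy.exp,
    "sqrt": sympy.sqrt,
    "pi": sympy.pi,
}


class ConfigError(ValueError):
    """Schema violation; the message names the offending field path."""


def parse_expression(text: str):
    """Parse an arithmetic expression in N into (callable, sympy expr)."""
    try:
        expr = sympy.sympify(str(text).replace("^", "**"), locals=dict(_ALLOWED_LOCALS))
    except (sympy.SympifyError, SyntaxError, TypeError) as err:
        raise ConfigError(f"cannot parse expression {text!r}: {err}") from None
    free = expr.free_symbols - {_N}
    if free:
        raise ConfigError(f"expression {text!r} uses unknown symbols {sorted(map(str, free))}")
    func = sympy.lambdify(_N, expr, modules="numpy")
    return (lambda N, _f=func: np.asarray(_f(np.asarray(N, dtype=float)), dtype=float)), expr


def _law_from_dict(doc: dict) -> GrowthLaw:
    if not isinstance(doc, dict) or "name" not in doc:
        raise ConfigError("law: must be an object with a 'name' field")
    name = doc["name"]
    if name != "custom":
        unknown = set(doc) - {"name", "params"}
        if unknown:
            raise ConfigError(f"law: unknown keys {sorted(unknown)}")
        try:
            return make_growth_law(name, doc.get("params", {}))
        except ValueError as err:
            raise ConfigError(f"law: {err}") from None

    unknown = set(doc) - {"name", "g", "h", "C", "N1", "N2"}
    if unknown:
        raise ConfigError(f"law: unknown keys {sorted(unknown)}")
    if "g" not in doc:
        raise ConfigError("law: custom law requires a 'g' expression")
    g, g_expr = parse_expression(doc["g"])
    g_prime = sympy.lambdify(_N, sympy.diff(g_expr, _N), modules="numpy")
    h = h_expr = None
    if "h" in doc:
        h, h_expr = parse_expression(doc["h"])
    C = doc.get("C")
    if ("h" in doc) != (C is not None):
        raise ConfigError("law: custom law must supply both 'h' and 'C', or neither")
    try:
        law = make_growth_law(
            "custom",
            g=g,
            g_prime=lambda N, _f=g_prime: np.asarray(_f(np.asarray(N, dtype=float)), dtype=float),
            h=h,
            C=C,
            N1=doc.get("N1"),
            N2=doc.get("N2"),
            exprs={k: str(doc[k]) for k in ("g", "h") if k in doc},
        )
    except ValueError as err:
        raise ConfigError(f"law: {err}") from None
    if h_expr is not None:
        # analytic d/dN (g/h) via symbolic differentiation
        ratio_prime = sympy.lambdify(_N, sympy.diff(g_expr / h_expr, _N), modules="numpy")
        law = GrowthLaw(
            name=law.name, params=law.params, g=law.g, g_prime=law.g_prime,
            h=law.h, C=law.C, N1=law.N1, N2=law.N2,
            gh_prime=lambda N, _f=ratio_prime: np.asarray(_f(np.asarray(N, dtype=float)), dtype=float),
            exprs=law.exprs,
        )
    return law


def _law_to_dict(law: GrowthLaw) -> dict:
    if law.name != "custom":
        return {"name": law.name, "params": dict(law.params)}
    if not law.exprs or "g" not in law.exprs:
        raise ConfigError("law: custom laws built from callables cannot be serialized; supply expression strings")
    doc = {"name": "custom", "g": law.exprs["g"], "N1": law.N1, "N2": law.N2}
    if law.has_companion:
        doc["h"] = law.exprs["h"]
        doc["C"] = law.C
    return doc


def _matrix_from_dict(doc: dict) -> np.ndarray:
    if not isinstance(doc, dict):
        raise ConfigError("A: must be an object with 'n' and 'off_diagonal'")
    unknown = set(doc) - {"n", "off_diagonal"}
    if unknown:
        raise ConfigError(f"A: unknown keys {sorted(unknown)}")
    try:
        n = int(doc["n"])
    except (KeyError, TypeError, ValueError):
        raise ConfigError("A: missing or invalid 'n'") from None
    entries = doc.get("off_diagonal", [])
    for k, triple in enumerate(entries):
        if len(triple) != 3:
            raise ConfigError(f"A.off_diagonal[{k}]: expected [i, j, rate]")
        i, j, rate = triple
        if not (0 <= int(i) < n and 0 <= int(j) < n):
            raise ConfigError(f"A.off_diagonal[{k}]: index ({i},{j}) out of range for n={n}")
        if rate < 0:
            raise ConfigError(f"A.off_diagonal[{k}]: negative rate {rate} for entry ({i},{j})")
    try:
        return transition_matrix(n, entries)
    except ValueError as err:
        raise ConfigError(f"A: {err}") from None


def _matrix_to_dict(A: np.ndarray) -> dict:
    n = A.shape[0]
    off = [[i, j, float(A[i, j])] for j in range(n) for i in range(n) if i != j and A[i, j] != 0.0]
    return {"n": n, "off_diagonal": off}


def config_from_dict(doc: dict) -> ModelConfig:
    required = {"schema_version", "law", "rates", "A", "x0", "t_span"}
    allowed = required | {"eps1", "eps2"}
    if not isinstance(doc, dict):
        raise ConfigError("config: top level must be an object")
    unknown = set(doc) - allowed
    if unknown:
        raise ConfigError(f"config: unknown keys {sorted(unknown)}")
    missing = required - set(doc)
    if missing:
        raise ConfigError(f"config: missing keys {sorted(missing)}")
    if doc["schema_version"] != SCHEMA_VERSION:
        raise ConfigError(f"config.schema_version: expected {SCHEMA_VERSION}, got {doc['schema_version']}")
    law = _law_from_dict(doc["law"])
    try:
        schedule = make_rate_schedule(doc["rates"])
    except (ValueError, KeyError) as err:
        raise ConfigError(f"rates: {err}") from None
    A = _matrix_from_dict(doc["A"])
    try:
        return ModelConfig(
            law=law,
            schedule=schedule,
            A=A,
            x0=np.asarray(doc["x0"], dtype=float),
            t_span=(float(doc["t_span"][0]), float(doc["t_span"][1])),
            eps1=float(doc.get("eps1", 1.0)),
            eps2=float(doc.get("eps2", 1.0)),
        )
    except ValueError as err:
        raise ConfigError(f"config: {err}") from None


def config_to_dict(cfg: ModelConfig) -> dict:
    return {
        "schema_version": SCHEMA_VERSION,
        "law": _law_to_dict(cfg.law),
        "rates": dict(cfg.schedule.spec),
        "A": _matrix_to_dict(cfg.A),
        "x0": cfg.x0.tolist(),
        "t_span": [float(cfg.t_span[0]), float(cfg.t_span[1])],
        "eps1": cfg.eps1,
        "eps2": cfg.eps2,
    }


def read_config(path) -> ModelConfig:
    with open(path) as fh:
        return config_from_dict(json.load(fh))


def write_config(cfg: ModelConfig, path) -> None:
    Path(path).write_text(json.dumps(config_to_dict(cfg), indent=2) + "\n")


def write_trajectory(traj: Trajectory, path) -> None:
    n = traj.states.shape[1]
    frame = pd.DataFrame(
        {"t": traj.times}
        | {f"x_{i + 1}": traj.states[:, i] for i in range(n)}
        | {"N": traj.N, "system_tag": traj.system_tag}
    )
    frame.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_trajectory(path) -> Trajectory:
    frame = pd.read_csv(path, sep="\t", float_precision="round_trip")
    cols = [c for c in frame.columns if c.startswith("x_")]
    return Trajectory(
        times=frame["t"].to_numpy(),
        states=frame[cols].to_numpy(),
        N=frame["N"].to_numpy(),
        system_tag=str(frame["system_tag"].iloc[0]),
    )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and (obj != obj or obj in (float("inf"), float("-inf"))):
        return repr(obj)
    return obj


def write_report(report, path) -> None:
    doc = report.to_dict() if hasattr(report, "to_dict") else report
    Path(path).write_text(json.dumps(_jsonable(doc), indent=2) + "\n")
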