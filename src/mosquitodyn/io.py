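"""Configuration parsing and machine-readable reports.

Coefficient bundles are described in TOML: each coefficient is a table with
a ``kind`` of ``constant``, ``trapezoid``, ``monthly``, ``expression`` or
``sampled``; two- and four-stage bundles collect them under
``[coefficients.<name>]``.  A top-level ``[generator]`` table instead asks
for one of the seeded synthetic scenarios, which keeps written specs exactly
round-trippable.  Monthly climate-like tables are read from CSV with header
``month,value`` (12 rows).  Trajectories are written as CSV with a JSON
metadata sidecar.
"""

from __future__ import annotations

import csv
import json
import math
import tomllib
from pathlib import Path

import numpy as np

from .dynamics import Trajectory
from .periodic import (FourStageCoefficients, PeriodicFunction,
                       TwoStageCoefficients, constant, from_expression,
                       make_monthly_interpolant, make_trapezoid_profile)

__all__ = [
    "load_config",
    "coefficient_from_spec",
    "two_stage_from_config",
    "four_stage_from_config",
    "coefficients_from_config",
    "read_monthly_csv",
    "write_trajectory_csv",
    "write_report",
    "write_coefficient_toml",
]

_EXPR_NAMES = {name: getattr(np, name) for name in
               ("sin", "cos", "tan", "exp", "log", "sqrt", "abs", "minimum",
                "maximum", "clip", "where")}
_EXPR_NAMES.update({"pi": math.pi, "np": np})


def load_config(path) -> dict:
    with open(path, "rb") as fh:
        return tomllib.load(fh)


def coefficient_from_spec(spec: dict, period_T: float,
                          label: str = "") -> PeriodicFunction:
    """Build a single periodic coefficient from its TOML table."""
    kind = spec.get("kind")
    if kind == "constant":
        return constant(float(spec["value"]), period_T, label)
    if kind == "trapezoid":
        return make_trapezoid_profile(float(spec["plateau"]),
                                      float(spec["t1"]), float(spec["t2"]),
                                      float(spec["t4"]), float(spec["t5"]),
                                      period_T, label)
    if kind == "monthly":
        if "csv" in spec:
            values = read_monthly_csv(spec["csv"])
        else:
            values = spec["values"]
        return make_monthly_interpolant(values, period_T,
                                        spec.get("method", "pchip"), label)
    if kind == "expression":
        expr = spec["expr"]
        code = compile(expr, f"<coefficient {label}>", "eval")

        def ev(t, code=code):
            ns = dict(_EXPR_NAMES)
            ns["t"] = np.asarray(t, float)
            ns["T"] = period_T
            return np.asarray(eval(code, {"__builtins__": {}}, ns), float)

        return from_expression(ev, period_T, label)
    if kind == "sampled":
        times = np.asarray(spec["times"], float)
        values = np.asarray(spec["values"], float)
        if times.shape != values.shape or times.size < 2:
            raise ValueError("sampled coefficient needs matching times/values")
        xp = np.concatenate([times, [times[0] + period_T]])
        fp = np.concatenate([values, [values[0]]])

        def ev(t, xp=xp, fp=fp):
            return np.interp(np.asarray(t, float), xp, fp)

        return from_expression(ev, period_T, label)
    raise ValueError(f"unknown coefficient kind {kind!r} for {label!r}")


def two_stage_from_config(cfg: dict) -> TwoStageCoefficients:
    model = cfg.get("model", {})
    T = float(model["period"])
    co = cfg["coefficients"]
    fns = {name: coefficient_from_spec(co[name], T, name)
           for name in ("b_E", "d_E", "d_L", "h")}
    c = (coefficient_from_spec(co["c"], T, "c") if "c" in co else None)
    return TwoStageCoefficients(c=c, **fns)


def four_stage_from_config(cfg: dict) -> FourStageCoefficients:
    model = cfg.get("model", {})
    T = float(model["period"])
    co = cfg["coefficients"]
    fns = {name: coefficient_from_spec(co[name], T, name)
           for name in ("b", "d_E", "d_L", "d_P", "d_A", "h", "tau_L",
                        "tau_P", "c")}
    return FourStageCoefficients(
        sigma=float(model.get("sigma", 0.5)),
        K_carry=float(model.get("K_carry", 1000.0)),
        oviposition_form=model.get("oviposition_form", "BS"),
        n=float(model.get("n", 1.0)), **fns)


def coefficients_from_config(cfg: dict):
    """Resolve a config to a coefficient bundle (generator table wins)."""
    gen = cfg.get("generator")
    if gen is not None:
        from . import scenarios

        name = gen["name"]
        if name == "persistent":
            return scenarios.gen_persistent_scenario(
                int(gen.get("seed", 0)), float(gen.get("period", 365.0)),
                float(gen.get("amplitude", 0.4)))
        if name in ("tropical", "temperate"):
            return scenarios.gen_climate_like(name, int(gen.get("seed", 0)))
        if name == "extinction":
            return scenarios.build_extinction_coeffs()
        raise ValueError(f"unknown generator {name!r}")
    kind = cfg.get("model", {}).get("kind", "two_stage")
    if kind == "four_stage":
        return four_stage_from_config(cfg)
    return two_stage_from_config(cfg)


def read_monthly_csv(path) -> list[float]:
    """12 monthly samples from a CSV with header ``month,value``."""
    rows = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or \
                [f.strip() for f in reader.fieldnames[:2]] != ["month", "value"]:
            raise ValueError("monthly CSV must have header 'month,value'")
        for row in reader:
            rows.append((int(row["month"]), float(row["value"])))
    if len(rows) != 12:
        raise ValueError(f"monthly CSV must have 12 rows, got {len(rows)}")
    rows.sort()
    return [v for _, v in rows]


def write_trajectory_csv(traj: Trajectory, path, columns=None) -> None:
    path = Path(path)
    ndim = traj.states.shape[1]
    if columns is None:
        columns = ["t", "E", "L"] if ndim == 2 else ["t", "E", "L", "P", "A"]
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(columns)
        for t, s in zip(traj.times, traj.states):
            w.writerow([f"{t:.10g}"] + [f"{v:.12g}" for v in s])
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    with open(sidecar, "w") as fh:
        json.dump({"columns": columns, "n_points": len(traj.times),
                   "solver": traj.solver_meta}, fh, indent=2)


class _NumpyEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, complex):
            return {"re": o.real, "im": o.imag}
        return super().default(o)


def write_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, cls=_NumpyEncoder)
        fh.write("\n")


#: Allowed values mirroring docs/report_schema.json (kept in sync by tests).
_CLASSIFICATIONS = {"below_one", "at_one", "above_one"}
_STABILITIES = {"attracting", "saddle", "repelling", "marginal"}


def validate_report(report: dict) -> list[str]:
    """Structural validation of a JSON report against the shipped schema.

    Returns a list of problems (empty when valid).  A lightweight checker
    covering the constraints of docs/report_schema.json: required keys,
    enumerated values, sign constraints and condition-block shape.
    """
    problems: list[str] = []
    for key in ("tool", "version"):
        if key not in report:
            problems.append(f"missing required key {key!r}")
    if report.get("tool") != "mosquitodyn":
        problems.append("tool must be 'mosquitodyn'")
    cls = report.get("classification")
    if cls is not None and cls not in _CLASSIFICATIONS:
        problems.append(f"bad classification {cls!r}")
    stab = report.get("stability")
    if stab is not None and stab not in _STABILITIES:
        problems.append(f"bad stability {stab!r}")
    if "R0" in report and not (isinstance(report["R0"], (int, float))
                               and report["R0"] >= 0):
        problems.append("R0 must be a nonnegative number")
    if "residual" in report and report["residual"] < 0:
        problems.append("residual must be nonnegative")
    for key in ("zero_linkage_bE", "zero_linkage_h", "gap_condition",
                "mortality_budget", "mortality_floor_average"):
        block = report.get(key)
        if block is None:
            continue
        if not isinstance(block, dict) or "holds" not in block \
                or "margin" not in block:
            problems.append(f"condition block {key!r} lacks holds/margin")
        elif block["holds"] and block.get("witnesses"):
            problems.append(f"condition {key!r} holds but lists witnesses")
    diss = report.get("dissipativity")
    if diss is not None and not (diss.get("K_bound", 0) > 0):
        problems.append("dissipativity K_bound must be positive")
    return problems


def _toml_value(v) -> str:
    if isinstance(v, str):
        return json.dumps(v)
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (list, tuple, np.ndarray)):
        return "[" + ", ".join(_toml_value(x) for x in v) + "]"
    if isinstance(v, (int, np.integer)):
        return str(int(v))
    return repr(float(v))


def write_coefficient_toml(tables: dict, path) -> None:
    """Write a nested dict of flat tables as TOML (strings, numbers, arrays)."""
    lines: list[str] = []

    def emit(prefix: str, table: dict):
        scalars = {k: v for k, v in table.items() if not isinstance(v, dict)}
        subs = {k: v for k, v in table.items() if isinstance(v, dict)}
        if prefix:
            lines.append(f"[{prefix}]")
        for k, v in scalars.items():
            lines.append(f"{k} = {_toml_value(v)}")
        if scalars or prefix:
            lines.append("")
        for k, v in subs.items():
            emit(f"{prefix}.{k}" if prefix else k, v)

    emit("", tables)
    Path(path).write_text("\n".join(lines))
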