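"""File formats, run configuration and the comparison-report generator.

Trajectories travel as CSV (`time` column plus one column per pool, or a
single `total` column; units echoed in a `#` metadata line).  Models
travel as JSON: B as an n×n array, a named-rate list, or a piecewise-
linear time tabulation; u as an array or tabulation; plus x0, pools and
events.  The report generator emits the stock/CS comparison of several
scenarios against a declared baseline, both as a GitHub-flavoured text
table (stocks and CS at 2 decimals, percentages as integers) and as a
full-precision JSON twin with a provenance block.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .core import (CompartmentalModel, DisturbanceEvent, StockTrajectory,
                   simulate)
from .metrics import (carbon_sequestration, delta_baseline_cs,
                      delta_baseline_stock, relative_metrics,
                      stock_change_time)

__all__ = [
    "SchemaError",
    "RunConfig",
    "read_trajectory",
    "write_trajectory",
    "read_model",
    "write_model",
    "model_from_dict",
    "model_to_dict",
    "report",
    "ReportResult",
]

MASS_UNIT = "kg C m-2"
#: pure relabel: 1 kg C m-2 == 10 Mg C ha-1
UNIT_FACTORS = {"kg_m2": (1.0, "kg C m-2"), "Mg_ha": (10.0, "Mg C ha-1")}


class SchemaError(ValueError):
    """Malformed trajectory or model file."""


@dataclass(frozen=True)
class RunConfig:
    """Shared run settings for simulations, metrics and reports."""

    horizon: float
    step: float = 0.01
    t0_label: object = None
    tolerance: float = 1e-6
    output_format: str = "table"          # table | json | csv
    units: str = "kg_m2"                  # kg_m2 | Mg_ha
    log_level: str = "INFO"

    def __post_init__(self):
        if self.horizon <= 0:
            raise SchemaError(f"horizon must be > 0, got {self.horizon}")
        if not (0 < self.step <= self.horizon / 10):
            raise SchemaError(
                f"step must be in (0, horizon/10]; got step={self.step} "
                f"for horizon={self.horizon}")
        if self.units not in UNIT_FACTORS:
            raise SchemaError(f"unknown units '{self.units}' "
                              f"(choose from {sorted(UNIT_FACTORS)})")

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# trajectories (CSV)

def write_trajectory(traj: StockTrajectory, path, unit: str = MASS_UNIT) -> None:
    """Write a trajectory as CSV with a `# units:` metadata line."""
    df = pd.DataFrame({"time": traj.grid})
    for j, pool in enumerate(traj.pools):
        df[pool] = traj.stocks[:, j]
    with open(path, "w") as fh:
        fh.write(f"# units: time yr, stocks {unit}\n")
        if traj.name:
            fh.write(f"# scenario: {traj.name}\n")
        if traj.t0_label is not None:
            fh.write(f"# t0: {traj.t0_label}\n")
        df.to_csv(fh, index=False, lineterminator="\n")


def read_trajectory(path) -> StockTrajectory:
    """Read a CSV trajectory (`time` column + >= 1 stock column)."""
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if ":" in line:
                key, _, val = line.lstrip("# ").partition(":")
                meta[key.strip()] = val.strip()
    try:
        df = pd.read_csv(path, comment="#")
    except (pd.errors.ParserError, ValueError) as exc:
        raise SchemaError(f"{path}: cannot parse CSV: {exc}") from exc
    if "time" not in df.columns:
        raise SchemaError(f"{path}: missing required 'time' column")
    stock_cols = [c for c in df.columns if c != "time"]
    if not stock_cols:
        raise SchemaError(f"{path}: no stock columns besides 'time'")
    for col in ["time"] + stock_cols:
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            row = int(vals.isna().idxmax())
            raise SchemaError(
                f"{path}: non-numeric value in column '{col}' at data row "
                f"{row + 1} (file line ~{row + 2})")
        df[col] = vals
    t = df["time"].to_numpy(dtype=float)
    dt = np.diff(t)
    if np.any(dt <= 0):
        row = int(np.argmax(dt <= 0)) + 1
        kind = "duplicated" if dt[row - 1] == 0 else "decreasing"
        raise SchemaError(
            f"{path}: {kind} time at data row {row + 1} (t={t[row]})")
    return StockTrajectory(
        grid=t - t[0], stocks=df[stock_cols].to_numpy(dtype=float),
        pools=tuple(stock_cols), unit=meta.get("units", MASS_UNIT),
        name=meta.get("scenario", ""), t0_label=meta.get("t0"))


# ---------------------------------------------------------------------------
# models (JSON)

def _rates_to_matrix(entries, pools) -> np.ndarray:
    index = {p: i for i, p in enumerate(pools)}
    B = np.zeros((len(pools), len(pools)))
    for e in entries:
        try:
            src, dst, rate = e["from"], e["to"], float(e["rate"])
        except (KeyError, TypeError) as exc:
            raise SchemaError(f"named-rate entry {e!r} needs from/to/rate") from exc
        if src not in index:
            raise SchemaError(f"unknown source pool '{src}' in rate list")
        i = index[src]
        B[i, i] -= rate
        if dst in ("atmosphere", "out"):
            continue
        if dst not in index:
            raise SchemaError(f"unknown destination pool '{dst}' in rate list")
        B[index[dst], i] += rate
    return B


def _tabulated(spec: dict, shape):
    times = np.asarray(spec["times"], dtype=float)
    values = np.asarray(spec["values"], dtype=float)
    if values.shape[0] != times.size:
        raise SchemaError("tabulation: len(values) must equal len(times)")

    def f(t, _t=times, _v=values):
        t = np.clip(t, _t[0], _t[-1])
        out = np.empty(shape)
        flat_v = _v.reshape(_t.size, -1)
        for k in range(flat_v.shape[1]):
            out.reshape(-1)[k] = np.interp(t, _t, flat_v[:, k])
        return out

    return f


def model_from_dict(spec: dict) -> CompartmentalModel:
    """Build a validated model from a JSON-style dict."""
    try:
        x0 = np.asarray(spec["x0"], dtype=float)
    except KeyError as exc:
        raise SchemaError("model spec needs 'x0'") from exc
    n = x0.size
    pools = tuple(spec.get("pools", (f"pool_{i + 1}" for i in range(n))))
    B_spec = spec.get("B")
    if B_spec is None:
        raise SchemaError("model spec needs 'B'")
    if isinstance(B_spec, dict):
        B = _tabulated(B_spec, (n, n))
    elif B_spec and isinstance(B_spec, list) and isinstance(B_spec[0], dict):
        B = _rates_to_matrix(B_spec, pools)
    else:
        B = np.asarray(B_spec, dtype=float)
    u_spec = spec.get("u", np.zeros(n))
    u = _tabulated(u_spec, (n,)) if isinstance(u_spec, dict) \
        else np.asarray(u_spec, dtype=float)
    events = [DisturbanceEvent(time=e["time"], fractions=e["fractions"])
              for e in spec.get("events", [])]
    return CompartmentalModel(B=B, u=u, x0=x0, events=events, pools=pools,
                              name=spec.get("name", ""),
                              t0_label=spec.get("t0_label"))


def model_to_dict(model: CompartmentalModel) -> dict:
    if model.B_const is None or model.u_const is None:
        raise SchemaError("only constant-coefficient models serialize to JSON")
    return {
        "name": model.name,
        "t0_label": model.t0_label,
        "pools": list(model.pools),
        "B": model.B_const.tolist(),
        "u": model.u_const.tolist(),
        "x0": model.x0.tolist(),
        "events": [{"time": e.time, "fractions": list(e.fractions)}
                   for e in model.events],
    }


def read_model(path) -> CompartmentalModel:
    with open(path) as fh:
        try:
            spec = json.load(fh)
        except json.JSONDecodeError as exc:
            raise SchemaError(f"{path}: invalid JSON: {exc}") from exc
    return model_from_dict(spec)


def write_model(model: CompartmentalModel, path) -> None:
    with open(path, "w") as fh:
        json.dump(model_to_dict(model), fh, indent=2)
        fh.write("\n")


# ---------------------------------------------------------------------------
# report

ROW_ORDER = ("C", "delta_t_C", "CS", "delta_b_C", "relative_delta_b_C",
             "delta_b_CS", "relative_delta_b_CS")


@dataclass
class ReportResult:
    """Stock/CS comparison table plus its machine-readable twin."""

    table: pd.DataFrame          # full precision, rows in display order
    text: str                    # GitHub-flavoured table, display rounding
    data: dict = field(default_factory=dict)

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.data, **kwargs)


def _round_row(name: str, values):
    if name.startswith("relative"):
        return [int(round(v)) for v in values]
    return [round(v, 2) + 0.0 for v in values]   # +0.0 kills "-0.0"


def report(items: dict, baseline_id: str, config: RunConfig) -> ReportResult:
    """Compare >= 2 scenarios against a baseline, in stocks and CS.

    ``items`` maps labels to models or trajectories; models are
    simulated over the configured horizon first.  Rows, in order: final
    stock C, stock change ΔtC, sequestration CS, baseline differences
    ΔbC and ΔbCS, and their relative (%) forms — stock differences in
    mass, CS differences in mass·time.
    """
    if len(items) < 2:
        raise SchemaError("report needs at least 2 scenarios")
    if baseline_id not in items:
        raise SchemaError(
            f"baseline '{baseline_id}' not among scenarios {sorted(items)}")
    T = config.horizon
    factor, unit_label = UNIT_FACTORS[config.units]
    trajs = {}
    for label, item in items.items():
        if isinstance(item, CompartmentalModel):
            trajs[label] = simulate(item, T, step=config.step)
        elif isinstance(item, StockTrajectory):
            trajs[label] = item
        else:
            raise SchemaError(
                f"scenario '{label}' is neither a model nor a trajectory")
    base = trajs[baseline_id]
    rows = {name: [] for name in ROW_ORDER}
    for label, traj in trajs.items():
        rows["C"].append(factor * traj.total_at(T))
        rows["delta_t_C"].append(factor * stock_change_time(traj, T).value)
        rows["CS"].append(factor * carbon_sequestration(traj, T).value)
        rows["delta_b_C"].append(
            factor * delta_baseline_stock(traj, base, T).value)
        rows["delta_b_CS"].append(
            factor * delta_baseline_cs(traj, base, T).value)
        rel_stock, rel_cs = relative_metrics(traj, base, T)
        rows["relative_delta_b_C"].append(rel_stock.value)
        rows["relative_delta_b_CS"].append(rel_cs.value)

    labels = list(trajs)
    table = pd.DataFrame(rows, index=labels).T
    mass = unit_label
    mass_time = f"{unit_label} yr"
    row_units = {"C": mass, "delta_t_C": mass, "CS": mass_time,
                 "delta_b_C": mass, "relative_delta_b_C": "%",
                 "delta_b_CS": mass_time, "relative_delta_b_CS": "%"}
    header = ["metric", "units"] + labels
    lines = ["| " + " | ".join(header) + " |",
             "| " + " | ".join(["---"] * len(header)) + " |"]
    for name in ROW_ORDER:
        vals = _round_row(name, table.loc[name])
        cells = [f"{v:g}" for v in vals]
        lines.append("| " + " | ".join([name, row_units[name]] + cells) + " |")
    text = "\n".join(lines)

    data = {
        "baseline": baseline_id,
        "horizon_yr": T,
        "units": unit_label,
        "rows": {name: {"units": row_units[name],
                        "values": dict(zip(labels, map(float, table.loc[name]))),
                        "display": dict(zip(labels, _round_row(name, table.loc[name])))}
                 for name in ROW_ORDER},
        "provenance": {
            "config": asdict(config) | {"digest": config.digest()},
            "relative_conventions": {
                "relative_delta_b_C": "100 * delta_b_C(T) / Cb(T)",
                "relative_delta_b_CS": "100 * delta_b_CS / |CS_b|"},
            "grids": {lab: int(tr.grid.size) for lab, tr in trajs.items()},
        },
    }
    return ReportResult(table=table, text=text, data=data)
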