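"""Carbon-accounting metrics: stock change, CS, and baseline differences.

The central quantity is carbon sequestration CS(t0, T): the time-integral
of carbon storage over a horizon, in units of mass·time (kg C m⁻² yr).
Unlike stock-change accounting (ΔtC, a mass), CS credits both how much
carbon is stored and for how long it stays out of the atmosphere.  In the
total-stock case,

    CS(t0, T) = ∫ C(t) dt − T·C(t0)   over [t0, t0+T],

equivalently the double integral of the net exchange flux n(t), or the
integral of C(t) − C(t0).  CS is positive for net accumulation-time,
negative for loss-time, and exactly zero for a constant stock.  The
new-inputs-only variant tracks only carbon entering after t0, obtained
for linear models by re-simulating from empty initial stocks
(superposition makes this exact).

Baseline-referenced forms difference a project against a reference
trajectory b: ΔbC(t) = C(t) − Cb(t) (mass) and
ΔbCS = CS − CSb (mass·time).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import (CompartmentalModel, FluxSeries, GridError,
                   StockTrajectory, integrated_net, release_flux, simulate)

__all__ = [
    "MetricResult",
    "integrate_series",
    "stock_change_time",
    "carbon_sequestration",
    "cs_from_fluxes",
    "cs_new_inputs",
    "delta_baseline_stock",
    "delta_baseline_cs",
    "relative_metrics",
]

MASS = "kg C m-2"
MASS_TIME = "kg C m-2 yr"
PERCENT = "%"

#: fewer grid points than this per horizon triggers a coarseness warning
MIN_POINTS = 10


@dataclass
class MetricResult:
    """A named accounting quantity with units and provenance.

    ``value`` keeps full precision; report layers round for display.
    """

    name: str
    value: float
    units: str
    t0: object = 0.0
    horizon: float | None = None
    baseline_id: str | None = None
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "name": self.name, "value": self.value, "units": self.units,
            "t0": self.t0, "horizon": self.horizon,
            "baseline_id": self.baseline_id, "provenance": self.provenance,
        }

    def __float__(self):
        return float(self.value)

    def __repr__(self):  # pragma: no cover - cosmetic
        base = f" vs {self.baseline_id}" if self.baseline_id else ""
        return f"<{self.name}{base} = {self.value:.6g} {self.units}>"


def integrate_series(grid, values) -> float:
    """Composite trapezoidal integral of ``values`` over ``grid``.

    Exact for integrands piecewise linear on the grid; the quadrature
    backend for every area computation in this module.
    """
    grid = np.asarray(grid, dtype=float)
    values = np.asarray(values, dtype=float)
    if grid.size < 2:
        raise GridError("need at least 2 grid points to integrate")
    if grid.shape != values.shape:
        raise GridError(f"grid length {grid.size} != values length {values.size}")
    if np.any(np.diff(grid) <= 0):
        raise GridError("grid must be strictly increasing")
    return float(np.trapezoid(values, grid))


def _restrict(grid: np.ndarray, values: np.ndarray, T: float):
    """Clip (grid, values) to [0, T], interpolating the endpoint if needed."""
    if T <= 0:
        raise GridError(f"horizon must be positive, got T={T}")
    if T > grid[-1] + 1e-9:
        raise GridError(f"horizon T={T} exceeds trajectory span {grid[-1]}")
    i = int(np.searchsorted(grid, T - 1e-12))
    if abs(grid[i] - T) < 1e-9:
        return grid[: i + 1], values[: i + 1]
    vT = np.interp(T, grid, values)
    return (np.concatenate([grid[: i], [T]]),
            np.concatenate([values[: i], [vT]]))


def _coarseness(grid: np.ndarray, T: float) -> dict:
    n = int(np.sum(grid <= T + 1e-12))
    prov = {"grid_points": n, "span": float(T)}
    if n < MIN_POINTS:
        prov["warning"] = (
            f"only {n} grid points over the horizon; trapezoidal CS may be "
            f"coarse (fewer than {MIN_POINTS} points)")
    return prov


def stock_change_time(traj: StockTrajectory, t: float) -> MetricResult:
    """Stock change ΔtC = C(t) − C(0): traditional stock-change accounting."""
    value = traj.total_at(t) - traj.total_at(0.0)
    return MetricResult("stock_change_time", value, MASS,
                        t0=traj.t0_label or 0.0, horizon=t,
                        provenance={"trajectory": traj.name})


def carbon_sequestration(traj: StockTrajectory, T: float) -> MetricResult:
    """CS over [0, T] from the total-stock curve: ∫C dt − T·C(0).

    Zero for a constant stock; positive iff the system gains
    carbon-time, negative iff it loses it.
    """
    grid, total = _restrict(traj.grid, traj.total, T)
    value = integrate_series(grid, total) - T * total[0]
    prov = _coarseness(traj.grid, T)
    prov["trajectory"] = traj.name
    prov["form"] = "stock_integral_minus_baseline"
    return MetricResult("CS_total", value, MASS_TIME,
                        t0=traj.t0_label or 0.0, horizon=T, provenance=prov)


def cs_from_fluxes(fluxes: FluxSeries, T: float) -> MetricResult:
    """CS over [0, T] as the double integral of the net flux n(t).

    The inner integral M(t) = ∫₀ᵗ n dτ (minus any reversal pulses) is
    accumulated trapezoidally, then integrated again.  Agrees with
    :func:`carbon_sequestration` on the matching trajectory up to
    quadrature error.
    """
    M = integrated_net(fluxes)
    grid, M = _restrict(fluxes.grid, M, T)
    value = integrate_series(grid, M)
    prov = _coarseness(fluxes.grid, T)
    prov["form"] = "double_net_flux_integral"
    return MetricResult("CS_total", value, MASS_TIME, horizon=T,
                        provenance=prov)


def cs_new_inputs(model: CompartmentalModel, T: float,
                  step: float = 0.01) -> MetricResult:
    """CS attributable to inputs entering after t0 only.

    Legacy stocks present at t0 are out of accounting scope: the model
    is re-run with zero initial stocks (same u, same B), giving the
    stock Mu(t) built purely from post-t0 inputs, whose time-integral is
    the new-inputs CS.  Exact for linear dynamics by superposition.
    """
    u_is_zero = model.u_const is not None and not np.any(model.u_const)
    if u_is_zero:
        return MetricResult(
            "CS_new_inputs", 0.0, MASS_TIME, t0=model.t0_label or 0.0,
            horizon=T, provenance={"note": "no new inputs to track (u = 0)"})
    empty = model.with_(x0=np.zeros(model.n_pools))
    traj = simulate(empty, T, step=step)
    grid, Mu = _restrict(traj.grid, traj.total, T)
    value = integrate_series(grid, Mu)
    return MetricResult("CS_new_inputs", value, MASS_TIME,
                        t0=model.t0_label or 0.0, horizon=T,
                        provenance={"model": model.name, "step": step,
                                    "form": "zero_initial_stock_run"})


def _require_span(traj: StockTrajectory, baseline: StockTrajectory, t: float):
    for which, tr in (("project", traj), ("baseline", baseline)):
        if t > tr.span + 1e-9:
            raise GridError(
                f"{which} trajectory spans only [0, {tr.span}], needs t={t}")


def delta_baseline_stock(traj: StockTrajectory, baseline: StockTrajectory,
                         t: float) -> MetricResult:
    """Avoided stock loss ΔbC(t) = C(t) − Cb(t) against a baseline."""
    _require_span(traj, baseline, t)
    value = traj.total_at(t) - baseline.total_at(t)
    return MetricResult("delta_baseline_stock", value, MASS,
                        t0=traj.t0_label or 0.0, horizon=t,
                        baseline_id=baseline.name or "baseline",
                        provenance={"trajectory": traj.name})


def delta_baseline_cs(traj: StockTrajectory, baseline: StockTrajectory,
                      T: float) -> MetricResult:
    """Baseline-referenced sequestration ΔbCS = CS − CSb (mass·time).

    Antisymmetric under swapping project and baseline.
    """
    _require_span(traj, baseline, T)
    cs_p = carbon_sequestration(traj, T).value
    cs_b = carbon_sequestration(baseline, T).value
    return MetricResult("delta_baseline_CS", cs_p - cs_b, MASS_TIME,
                        t0=traj.t0_label or 0.0, horizon=T,
                        baseline_id=baseline.name or "baseline",
                        provenance={"trajectory": traj.name,
                                    "CS_project": cs_p, "CS_baseline": cs_b})


def relative_metrics(traj: StockTrajectory, baseline: StockTrajectory,
                     T: float) -> tuple[MetricResult, MetricResult]:
    """Relative avoided losses, in percent of the baseline.

    Conventions (recorded in provenance): the stock ratio divides
    ΔbC(T) by the baseline's final stock Cb(T); the CS ratio divides
    ΔbCS by |CSb|, so that a project that fully avoids the baseline's
    carbon-time losses scores 100%.
    """
    _require_span(traj, baseline, T)
    dC = delta_baseline_stock(traj, baseline, T)
    dCS = delta_baseline_cs(traj, baseline, T)
    cb_T = baseline.total_at(T)
    cs_b = dCS.provenance["CS_baseline"]
    bid = baseline.name or "baseline"
    if abs(cb_T) < 1e-300:
        raise ZeroDivisionError(
            f"relative stock metric undefined: baseline '{bid}' has zero "
            f"final stock Cb(T)")
    if abs(cs_b) < 1e-300:
        raise ZeroDivisionError(
            f"relative CS metric undefined: baseline '{bid}' has zero CS")
    rel_stock = MetricResult(
        "relative_delta_baseline_stock", 100.0 * dC.value / cb_T, PERCENT,
        t0=traj.t0_label or 0.0, horizon=T, baseline_id=bid,
        provenance={"denominator": "baseline final stock Cb(T)",
                    "Cb_T": cb_T})
    rel_cs = MetricResult(
        "relative_delta_baseline_CS", 100.0 * dCS.value / abs(cs_b), PERCENT,
        t0=traj.t0_label or 0.0, horizon=T, baseline_id=bid,
        provenance={"denominator": "|baseline CS|", "CS_baseline": cs_b})
    return rel_stock, rel_cs


def metrics_from_model(model: CompartmentalModel, T: float,
                       step: float = 0.01) -> dict:
    """Convenience: simulate and compute the single-trajectory metrics."""
    traj = simulate(model, T, step=step)
    fluxes = release_flux(model, traj)
    return {
        "trajectory": traj,
        "fluxes": fluxes,
        "stock_change_time": stock_change_time(traj, T),
        "CS_total": carbon_sequestration(traj, T),
        "CS_new_inputs": cs_new_inputs(model, T, step=step),
    }
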