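"""Linear compartmental carbon systems and their exchange fluxes.

A compartmental system is a mass-balanced network of pools that store
carbon and transfer it among themselves and to the atmosphere.  The
dynamics are linear (possibly time-varying):

    dx/dt = u(t) + B(t) x(t)

where ``x`` is the vector of pool stocks (kg C m⁻²), ``u(t)`` the vector
of gross uptake fluxes from the atmosphere (kg C m⁻² yr⁻¹), and ``B(t)``
the compartmental rate matrix (1/yr): off-diagonal entries are internal
transfer rates (non-negative), and each column sum is non-positive — the
deficit ``−1ᵀB`` is that pool's release rate to the atmosphere.

Abrupt reversals (fire, harvest, venting) are modelled as
:class:`DisturbanceEvent` pulses: an instantaneous transfer of a fraction
of one or more pools to the atmosphere.  The integrator splits at each
event, applies the stock reset exactly, and books the removed mass as a
release pulse, so mass balance holds to solver precision even across
discontinuities.

Internal time is years since the reference time ``t0`` (grid[0] = 0);
calendar years are I/O labels only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "CompartmentalModel",
    "DisturbanceEvent",
    "EventRecord",
    "StockTrajectory",
    "FluxSeries",
    "MassBalanceReport",
    "ModelValidationError",
    "NumericalFailureError",
    "GridError",
    "simulate",
    "release_flux",
    "net_flux",
    "check_mass_balance",
]

#: default relative tolerance for invariant / mass-balance checks
DEFAULT_TOL = 1e-6

#: negatives smaller than this fraction of the max stock are clipped to zero
NEGATIVE_CLIP = 1e-9


class ModelValidationError(ValueError):
    """Raised when a model violates the compartmental-system invariants."""


class NumericalFailureError(RuntimeError):
    """Raised when integration fails or produces unphysical stocks."""


class GridError(ValueError):
    """Raised on malformed or mismatched time grids."""


def _as_time_function(value, shape, name: str) -> tuple[Callable, np.ndarray | None]:
    """Coerce a constant array or callable into ``f(t) -> ndarray``.

    Returns ``(f, const)`` where ``const`` is the constant array if the
    input was time-independent, else None.
    """
    if callable(value):
        probe = np.asarray(value(0.0), dtype=float)
        if probe.shape != shape:
            raise ModelValidationError(
                f"{name}(t) returns shape {probe.shape}, expected {shape}"
            )
        return value, None
    arr = np.asarray(value, dtype=float)
    if arr.shape != shape:
        raise ModelValidationError(f"{name} has shape {arr.shape}, expected {shape}")

    def const_fn(t, _arr=arr):
        return _arr

    return const_fn, arr


@dataclass(frozen=True)
class DisturbanceEvent:
    """Instantaneous transfer of pool fractions to the atmosphere.

    Parameters
    ----------
    time : float
        Years since t0 at which the pulse occurs.
    fractions : array-like
        Per-pool fraction in [0, 1] removed at ``time``.  A scalar is
        broadcast to all pools.
    """

    time: float
    fractions: tuple

    def __init__(self, time: float, fractions):
        frac = np.atleast_1d(np.asarray(fractions, dtype=float))
        if np.any(frac < 0) or np.any(frac > 1):
            raise ModelValidationError(
                f"event at t={time}: fractions must lie in [0, 1], got {frac}"
            )
        if time < 0:
            raise ModelValidationError(f"event time must be >= 0, got {time}")
        object.__setattr__(self, "time", float(time))
        object.__setattr__(self, "fractions", tuple(frac))

    def fraction_vector(self, n_pools: int) -> np.ndarray:
        frac = np.asarray(self.fractions, dtype=float)
        if frac.size == 1:
            return np.full(n_pools, frac[0])
        if frac.size != n_pools:
            raise ModelValidationError(
                f"event at t={self.time}: {frac.size} fractions for {n_pools} pools"
            )
        return frac


class CompartmentalModel:
    """A linear compartmental carbon-storage system.

    Parameters
    ----------
    B : (n, n) array or callable t -> (n, n) array
        Compartmental rate matrix (1/yr).  Off-diagonals >= 0; column
        sums <= 0 (the deficit is the release rate to the atmosphere).
    u : (n,) array or callable t -> (n,) array
        Gross uptake flux from the atmosphere per pool (kg C m⁻² yr⁻¹).
    x0 : (n,) array
        Initial stocks at t0 (kg C m⁻²).
    events : sequence of DisturbanceEvent, optional
        Instantaneous reversal pulses, sorted by time on construction.
    pools : sequence of str, optional
        Pool names (default ``pool_1 .. pool_n``).
    name : str, optional
        Scenario label carried into reports.
    t0_label : optional
        Calendar label for t0 (e.g. 1963); display only.
    """

    def __init__(self, B, u, x0, events: Sequence[DisturbanceEvent] = (),
                 pools: Sequence[str] | None = None, name: str = "",
                 t0_label=None):
        x0 = np.atleast_1d(np.asarray(x0, dtype=float))
        n = x0.size
        self.n_pools = n
        self.x0 = x0
        self.B, self.B_const = _as_time_function(B, (n, n), "B")
        self.u, self.u_const = _as_time_function(
            np.atleast_1d(np.asarray(u, dtype=float)) if not callable(u) else u,
            (n,), "u")
        self.events = tuple(sorted(events, key=lambda e: e.time))
        self.pools = tuple(pools) if pools is not None else tuple(
            f"pool_{i + 1}" for i in range(n))
        if len(self.pools) != n:
            raise ModelValidationError(
                f"{len(self.pools)} pool names for {n} pools")
        self.name = name
        self.t0_label = t0_label
        self.autonomous = self.B_const is not None and self.u_const is not None
        self.validate()

    def validate(self, sample_times: Sequence[float] = (0.0,),
                 tol: float = 1e-10) -> None:
        """Check the compartmental-system invariants.

        For time-varying models the checks run at ``sample_times`` only.
        """
        if np.any(self.x0 < 0):
            raise ModelValidationError(f"negative initial stock: x0={self.x0}")
        times = (0.0,) if self.autonomous else tuple(sample_times)
        for t in times:
            Bt = np.asarray(self.B(t), dtype=float)
            off = Bt - np.diag(np.diag(Bt))
            if np.any(off < -tol):
                i, j = np.unravel_index(np.argmin(off), off.shape)
                raise ModelValidationError(
                    f"negative internal transfer B[{i},{j}]={Bt[i, j]} at t={t}")
            colsum = Bt.sum(axis=0)
            if np.any(colsum > tol):
                j = int(np.argmax(colsum))
                raise ModelValidationError(
                    f"pool '{self.pools[j]}' creates mass: column sum "
                    f"{colsum[j]:.3g} > 0 at t={t}")
            ut = np.asarray(self.u(t), dtype=float)
            if np.any(ut < -tol):
                raise ModelValidationError(f"negative input flux u({t})={ut}")
        for ev in self.events:
            ev.fraction_vector(self.n_pools)

    def release_rates(self, t: float) -> np.ndarray:
        """Per-pool release-rate coefficients −1ᵀB(t) (1/yr), >= 0."""
        return -np.asarray(self.B(t), dtype=float).sum(axis=0)

    def with_(self, **overrides) -> "CompartmentalModel":
        """Copy with selected fields replaced (B, u, x0, events, ...)."""
        kw = dict(
            B=self.B_const if self.B_const is not None else self.B,
            u=self.u_const if self.u_const is not None else self.u,
            x0=self.x0, events=self.events, pools=self.pools,
            name=self.name, t0_label=self.t0_label,
        )
        kw.update(overrides)
        return CompartmentalModel(**kw)

    def steady_state(self) -> np.ndarray:
        """Solve B x* = −u for an autonomous model."""
        if not self.autonomous:
            raise ModelValidationError("steady state requires an autonomous model")
        return np.linalg.solve(self.B_const, -self.u_const)

    def __repr__(self):  # pragma: no cover - cosmetic
        label = f" '{self.name}'" if self.name else ""
        return (f"CompartmentalModel{label}(n_pools={self.n_pools}, "
                f"autonomous={self.autonomous}, events={len(self.events)})")


@dataclass(frozen=True)
class EventRecord:
    """Bookkeeping for one applied disturbance pulse."""

    time: float
    index: int                  # grid index of the event time
    stocks_before: np.ndarray   # x(s⁻), per pool
    removed: np.ndarray         # mass removed per pool, = f ∘ x(s⁻)


@dataclass
class StockTrajectory:
    """Per-pool carbon stocks on a time grid.

    ``grid`` is strictly increasing with grid[0] = 0 (years since t0);
    ``stocks`` has shape (len(grid), n_pools) in kg C m⁻².  At an event
    time the stored stocks are the post-event values; the pre-event state
    is kept in ``event_records``.
    """

    grid: np.ndarray
    stocks: np.ndarray
    pools: tuple = ()
    unit: str = "kg C m-2"
    name: str = ""
    t0_label: object = None
    event_records: tuple = ()

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        self.stocks = np.asarray(self.stocks, dtype=float)
        if self.stocks.ndim == 1:
            self.stocks = self.stocks[:, None]
        if self.grid.ndim != 1 or self.grid.size < 2:
            raise GridError("grid must be 1-D with at least 2 points")
        if np.any(np.diff(self.grid) <= 0):
            bad = int(np.argmin(np.diff(self.grid)))
            raise GridError(
                f"grid must be strictly increasing (violation near index {bad}, "
                f"t={self.grid[bad]})")
        if self.stocks.shape[0] != self.grid.size:
            raise GridError(
                f"{self.stocks.shape[0]} stock rows for {self.grid.size} times")
        if not self.pools:
            self.pools = tuple(f"pool_{i + 1}" for i in range(self.stocks.shape[1]))

    @property
    def n_pools(self) -> int:
        return self.stocks.shape[1]

    @property
    def total(self) -> np.ndarray:
        """Total stock C(t) = sum over pools, per grid point."""
        return self.stocks.sum(axis=1)

    @property
    def span(self) -> float:
        return float(self.grid[-1])

    def total_at(self, t: float) -> float:
        """Total stock at time t, linearly interpolated on the grid."""
        if t < self.grid[0] - 1e-12 or t > self.grid[-1] + 1e-12:
            raise GridError(
                f"t={t} outside trajectory span [0, {self.grid[-1]}]")
        return float(np.interp(t, self.grid, self.total))


@dataclass
class FluxSeries:
    """Gross uptake, gross release and net exchange on a grid.

    ``uptake`` is 1ᵀu(t), ``release`` the continuous release −1ᵀB(t)x(t)
    (both kg C m⁻² yr⁻¹, right-continuous at events), ``net`` their
    difference.  Instantaneous reversal pulses are booked separately in
    ``pulses`` as (time, mass); ``release_pre`` maps an event's grid
    index to the left-limit release rate there, so that quadrature can
    treat the jump exactly.
    """

    grid: np.ndarray
    uptake: np.ndarray
    release: np.ndarray
    pulses: tuple = ()
    release_pre: dict = field(default_factory=dict)

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        self.uptake = np.asarray(self.uptake, dtype=float)
        self.release = np.asarray(self.release, dtype=float)
        if not (self.grid.size == self.uptake.size == self.release.size):
            raise GridError("grid, uptake and release must share a length")

    @property
    def net(self) -> np.ndarray:
        """Net removal n(t) = u(t) − r(t) (continuous part)."""
        return self.uptake - self.release

    def net_pre(self, i: int) -> float:
        """Left limit of n at grid index i (differs only at event times)."""
        r = self.release_pre.get(i, self.release[i])
        return float(self.uptake[i] - r)


@dataclass(frozen=True)
class MassBalanceReport:
    """Result of a mass-balance audit of a trajectory/flux pair."""

    passed: bool
    max_rel_error: float
    worst_index: int
    worst_time: float
    tol: float

    def __bool__(self):
        return self.passed


def _build_grid(T: float, step: float, event_times: Sequence[float]) -> np.ndarray:
    if T <= 0:
        raise GridError(f"horizon must be positive, got T={T}")
    if step <= 0:
        raise GridError(f"step must be positive, got {step}")
    n = max(1, int(round(T / step)))
    grid = np.linspace(0.0, T, n + 1)
    extra = [s for s in event_times
             if 0.0 < s < T and np.min(np.abs(grid - s)) > 1e-9]
    if extra:
        grid = np.sort(np.concatenate([grid, np.asarray(extra, dtype=float)]))
    return grid


def simulate(model: CompartmentalModel, T: float, step: float = 0.01,
             method: str = "LSODA", rtol: float = 1e-10,
             atol: float = 1e-12) -> StockTrajectory:
    """Integrate dx/dt = u(t) + B(t)x(t) from x0 over [0, T].

    The solution is sampled on a uniform grid of resolution ``step``
    (event times are inserted if they fall between grid points).
    Integration splits at each disturbance event: the solver runs to the
    event time, the per-pool fractions are removed exactly, and the run
    restarts — so the reset conserves mass by construction.

    Returns a :class:`StockTrajectory`; stocks at an event time are the
    post-event values, with the pre-event state in ``event_records``.
    """
    events = [e for e in model.events if 0.0 < e.time <= T]
    grid = _build_grid(T, step, [e.time for e in events])
    # snap event times onto grid values so segment bounds are exact floats
    event_times = [float(grid[np.argmin(np.abs(grid - e.time))])
                   for e in events]

    def rhs(t, x):
        return np.asarray(model.u(t), dtype=float) + \
            np.asarray(model.B(t), dtype=float) @ x

    breakpoints = [0.0] + event_times + [float(grid[-1])]
    stocks = np.empty((grid.size, model.n_pools))
    stocks[0] = model.x0
    x = model.x0.copy()
    records = []
    for seg, (a, b) in enumerate(zip(breakpoints[:-1], breakpoints[1:])):
        if b - a > 1e-14:
            mask = (grid > a) & (grid <= b)
            t_eval = grid[mask]
            sol = solve_ivp(rhs, (a, b), x, method=method, t_eval=t_eval,
                            rtol=rtol, atol=atol, dense_output=False)
            if not sol.success:
                raise NumericalFailureError(
                    f"integration failed on [{a}, {b}]: {sol.message}")
            stocks[mask] = sol.y.T
            x = sol.y[:, -1].copy()
        if seg < len(events):
            ev = events[seg]
            idx = int(np.argmin(np.abs(grid - event_times[seg])))
            frac = ev.fraction_vector(model.n_pools)
            removed = frac * x
            records.append(EventRecord(time=float(grid[idx]), index=idx,
                                       stocks_before=x.copy(),
                                       removed=removed))
            x = x - removed
            stocks[idx] = x

    scale = max(np.max(np.abs(stocks)), 1e-300)
    neg = stocks < 0
    if np.any(neg):
        worst = stocks[neg].min()
        if -worst < NEGATIVE_CLIP * scale:
            stocks[neg] = 0.0
        else:
            i, j = np.unravel_index(np.argmin(stocks), stocks.shape)
            raise NumericalFailureError(
                f"negative stock {worst:.3e} kg C m-2 in pool "
                f"'{model.pools[j]}' at t={grid[i]:.4g} yr "
                f"(beyond clip threshold {NEGATIVE_CLIP * scale:.1e})")

    return StockTrajectory(grid=grid, stocks=stocks, pools=model.pools,
                           name=model.name, t0_label=model.t0_label,
                           event_records=tuple(records))


def release_flux(model: CompartmentalModel, traj: StockTrajectory) -> FluxSeries:
    """Gross fluxes along a simulated trajectory.

    Continuous release is r(t) = −1ᵀB(t) x(t); uptake is 1ᵀu(t).  Event
    pulses are booked as (time, mass) pairs, and the pre-event (left
    limit) release rate at each event index is recorded so quadrature
    across the jump stays exact.
    """
    if traj.n_pools != model.n_pools:
        raise GridError(
            f"trajectory has {traj.n_pools} pools, model has {model.n_pools}")
    n_t = traj.grid.size
    uptake = np.empty(n_t)
    release = np.empty(n_t)
    for i, t in enumerate(traj.grid):
        uptake[i] = float(np.sum(model.u(t)))
        release[i] = float(model.release_rates(t) @ traj.stocks[i])
    release = np.clip(release, 0.0, None)  # guard solver-level negatives
    pulses = []
    release_pre = {}
    for rec in traj.event_records:
        pulses.append((rec.time, float(rec.removed.sum())))
        release_pre[rec.index] = float(
            model.release_rates(rec.time) @ rec.stocks_before)
    return FluxSeries(grid=traj.grid, uptake=uptake, release=release,
                      pulses=tuple(pulses), release_pre=release_pre)


def net_flux(fluxes: FluxSeries) -> np.ndarray:
    """Net removal n(t) = u(t) − r(t) on the flux grid."""
    return fluxes.net


def integrated_net(fluxes: FluxSeries) -> np.ndarray:
    """Cumulative ∫₀ᵗ n dτ minus pulse losses, on the grid.

    Reproduces C(t) − C(0) including discontinuities: the flux is
    smooth between events, so each inter-event segment is accumulated
    with composite Simpson quadrature (trapezoid on 2-point segments),
    using the left-limit flux at an event endpoint, and the pulse mass
    is subtracted from the event time onward.
    """
    from scipy.integrate import cumulative_simpson

    grid, net = fluxes.grid, fluxes.net
    last = grid.size - 1
    ev_idx = sorted(i for i in fluxes.release_pre if 0 < i <= last)
    bounds = [0] + ev_idx + ([last] if last not in ev_idx else [])
    cum = np.zeros(grid.size)
    start = 0
    for i_end in bounds[1:]:
        seg = slice(start, i_end + 1)
        vals = net[seg].copy()
        if i_end in fluxes.release_pre:
            vals[-1] = fluxes.net_pre(i_end)
        if vals.size >= 3:
            seg_cum = cumulative_simpson(vals, x=grid[seg], initial=0.0)
        else:
            seg_cum = np.concatenate(
                [[0.0], np.cumsum(0.5 * (vals[1:] + vals[:-1])
                                  * np.diff(grid[seg]))])
        cum[seg] = cum[start] + seg_cum
        start = i_end
    for rec_time, mass in fluxes.pulses:
        i = int(np.argmin(np.abs(grid - rec_time)))
        cum[i:] -= mass
    return cum


def check_mass_balance(traj: StockTrajectory, fluxes: FluxSeries,
                       tol: float = DEFAULT_TOL) -> MassBalanceReport:
    """Audit that C(t) − C(0) equals the integrated net flux.

    Reports the max over grid points of |C(t) − C(0) − ∫₀ᵗ n dτ + pulses|
    relative to max|C|; passes iff below ``tol``.
    """
    if traj.grid.size != fluxes.grid.size or \
            np.max(np.abs(traj.grid - fluxes.grid)) > 1e-12:
        raise GridError("trajectory and fluxes are on different grids")
    C = traj.total
    resid = np.abs(C - C[0] - integrated_net(fluxes))
    scale = max(np.max(np.abs(C)), 1e-300)
    rel = resid / scale
    worst = int(np.argmax(rel))
    return MassBalanceReport(passed=bool(rel[worst] < tol),
                             max_rel_error=float(rel[worst]),
                             worst_index=worst,
                             worst_time=float(traj.grid[worst]),
                             tol=tol)
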