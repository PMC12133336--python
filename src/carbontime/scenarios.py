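"""Built-in scenario fixtures and seeded synthetic model generators.

The headline fixture mimics the soil-carbon trajectories of the
long-term La Estanzuela cropping experiment (Uruguay) with one-pool
exponentials: S1 — intensive continuous cropping, steady degradation;
S2 — fertilized cropping, slower decline; S3 — rotational crop–pasture,
no net change.  All start at 6 kg C m⁻² in 1963 and are evaluated over a
60-year horizon.  Decay rates of 0.01 yr⁻¹ (S1) and 0.005 yr⁻¹ (S2)
reproduce the published 2023 stocks (3.29 and 4.44 kg C m⁻²).

Also here: a saturating two-speed accumulator pair (fast vs slow growth
to the same ceiling), seeded random compartmental models for property
tests, and a helper that attaches reversal events (e.g. fire pulses) to
any base model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import CompartmentalModel, DisturbanceEvent, StockTrajectory, simulate

__all__ = [
    "ScenarioSpec",
    "estanzuela",
    "two_speed",
    "random_model",
    "disturbance_scenario",
    "SCENARIOS",
]

ESTANZUELA_C0 = 6.0       # kg C m-2 at t0
ESTANZUELA_T0 = 1963      # calendar label of t0
ESTANZUELA_T = 60.0       # yr horizon (ends 2023)
ESTANZUELA_K = {"S1": 0.01, "S2": 0.005, "S3": 0.0}   # 1/yr decay


@dataclass(frozen=True)
class ScenarioSpec:
    """A reproducible recipe for a fixture model or trajectory."""

    name: str
    params: dict = field(default_factory=dict)
    seed: int | None = None
    t0_label: object = None
    horizon: float | None = None


def estanzuela(s3_flux_balanced: bool = False) -> dict[str, CompartmentalModel]:
    """The three cropland soil-management scenarios S1, S2, S3.

    One-pool models, x0 = 6 kg C m⁻², t0 labelled 1963.  S1 and S2 decay
    at 0.01 and 0.005 yr⁻¹ with no inputs.  S3 holds a constant stock;
    by default it is inert (B = 0, u = 0).  With ``s3_flux_balanced``
    S3 instead cycles carbon at steady state (u = r > 0): its CS is
    identical (zero) but its transit time is finite — storage-time
    accounting and permanence are distinct questions.
    """
    models = {}
    for name in ("S1", "S2"):
        k = ESTANZUELA_K[name]
        models[name] = CompartmentalModel(
            B=[[-k]], u=[0.0], x0=[ESTANZUELA_C0], pools=("soil",),
            name=name, t0_label=ESTANZUELA_T0)
    if s3_flux_balanced:
        k = ESTANZUELA_K["S1"]
        models["S3"] = CompartmentalModel(
            B=[[-k]], u=[k * ESTANZUELA_C0], x0=[ESTANZUELA_C0],
            pools=("soil",), name="S3", t0_label=ESTANZUELA_T0)
    else:
        models["S3"] = CompartmentalModel(
            B=[[0.0]], u=[0.0], x0=[ESTANZUELA_C0], pools=("soil",),
            name="S3", t0_label=ESTANZUELA_T0)
    return models


def two_speed(cmax: float = 1.0, k_fast: float = 0.2, k_slow: float = 0.05,
              T: float = 30.0, step: float = 0.01
              ) -> tuple[StockTrajectory, StockTrajectory]:
    """Fast vs slow saturating accumulators C(t) = cmax·(1 − e^{−kt}).

    Both start empty and approach the same ceiling; the faster system
    dominates pointwise on (0, T], so its area under the curve — its CS
    — is strictly larger.  Realized as one-pool models with input
    u = cmax·k and turnover k, then simulated.
    """
    if not (k_fast > k_slow > 0):
        raise ValueError(
            f"need k_fast > k_slow > 0, got k_fast={k_fast}, k_slow={k_slow}")
    if cmax <= 0:
        raise ValueError(f"cmax must be positive, got {cmax}")
    out = []
    for label, k in (("fast", k_fast), ("slow", k_slow)):
        m = CompartmentalModel(B=[[-k]], u=[cmax * k], x0=[0.0],
                               pools=("biomass",), name=label)
        out.append(simulate(m, T, step=step))
    return out[0], out[1]


def random_model(seed: int, n_pools: int = 3,
                 rate_bounds: tuple[float, float] = (0.02, 0.5),
                 input_bounds: tuple[float, float] = (0.0, 1.0),
                 stock_bounds: tuple[float, float] = (0.0, 10.0),
                 ) -> CompartmentalModel:
    """A seeded random autonomous compartmental model.

    Column j gets turnover rate k_j drawn from ``rate_bounds``; at least
    20% of each pool's outflow goes to the atmosphere (so B is strictly
    compartmental with negative trace and every pool eventually
    releases), the rest is split among the other pools.  Inputs and
    initial stocks are uniform over their bounds.  The same seed yields
    a bitwise-identical model.
    """
    if n_pools < 1:
        raise ValueError(f"n_pools must be >= 1, got {n_pools}")
    lo, hi = rate_bounds
    if not (0 < lo <= hi):
        raise ValueError(f"infeasible rate bounds {rate_bounds}")
    if input_bounds[0] < 0 or stock_bounds[0] < 0:
        raise ValueError("input and stock bounds must be non-negative")
    rng = np.random.default_rng(seed)
    k = rng.uniform(lo, hi, size=n_pools)
    B = np.zeros((n_pools, n_pools))
    for j in range(n_pools):
        B[j, j] = -k[j]
        if n_pools > 1:
            release_frac = rng.uniform(0.2, 1.0)
            weights = rng.dirichlet(np.ones(n_pools - 1))
            others = [i for i in range(n_pools) if i != j]
            B[others, j] = k[j] * (1.0 - release_frac) * weights
    u = rng.uniform(*input_bounds, size=n_pools)
    x0 = rng.uniform(*stock_bounds, size=n_pools)
    return CompartmentalModel(B=B, u=u, x0=x0, name=f"random[{seed}]")


def disturbance_scenario(base: CompartmentalModel, event_times,
                         severities) -> CompartmentalModel:
    """Attach reversal pulses (e.g. fire) to a base model.

    Each event at ``event_times[i]`` moves fraction ``severities[i]`` of
    every pool to the atmosphere.  CS of the disturbed model never
    exceeds that of the undisturbed one for accumulation scenarios.
    """
    event_times = np.atleast_1d(np.asarray(event_times, dtype=float))
    severities = np.atleast_1d(np.asarray(severities, dtype=float))
    if event_times.size != severities.size:
        raise ValueError(
            f"{event_times.size} event times but {severities.size} severities")
    if np.any(severities < 0) or np.any(severities > 1):
        raise ValueError(f"severities must lie in [0, 1], got {severities}")
    events = list(base.events) + [
        DisturbanceEvent(time=t, fractions=s)
        for t, s in zip(event_times, severities)]
    name = f"{base.name}+events" if base.name else "disturbed"
    return base.with_(events=events, name=name)


#: named fixture registry for the CLI `scenario` verb
SCENARIOS = {
    "estanzuela": ScenarioSpec(
        name="estanzuela",
        params={"C0": ESTANZUELA_C0, "k": dict(ESTANZUELA_K)},
        t0_label=ESTANZUELA_T0, horizon=ESTANZUELA_T),
    "two_speed": ScenarioSpec(
        name="two_speed",
        params={"cmax": 1.0, "k_fast": 0.2, "k_slow": 0.05}, horizon=30.0),
}
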