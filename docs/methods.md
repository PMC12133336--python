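# Methods

## Model

Carbon storage is represented as a linear, possibly time-varying
compartmental system

    dx/dt = u(t) + B(t) x(t),        x(0) = x0,

with `x` the vector of pool stocks (kg C m⁻²), `u(t) ≥ 0` the gross
uptake fluxes from the atmosphere (kg C m⁻² yr⁻¹), and `B(t)` the
compartmental matrix (1/yr): off-diagonal entries `B_ij ≥ 0` are
transfer rates from pool j to pool i, and each column sum is ≤ 0, the
deficit `−1ᵀB` being that pool's release rate to the atmosphere. These
sign constraints are validated at construction (and at sample times for
time-varying coefficients); models violating them are rejected with a
message naming the offending pool. Linearity is an assumption, not a
technicality: the new-inputs/legacy split and the transit-time formulas
both rest on superposition. Density-dependent (nonlinear) pool dynamics
are out of scope.

Mass balance is structural: the total stock `C(t) = 1ᵀx(t)` changes
only through the net exchange flux `n(t) = u(t) − r(t)` with
`r(t) = −1ᵀB(t)x(t)`, so `C(t) − C(0) = ∫ n dτ`. The package treats
this as an auditable invariant (`check_mass_balance`) rather than a
silent assumption.

Abrupt reversals (fire, harvest, venting) are `DisturbanceEvent`s: at
time s a fraction `f_i ∈ [0, 1]` of each pool moves instantaneously to
the atmosphere. The integrator runs to s, applies
`x(s⁺) = (1 − f) ∘ x(s⁻)` exactly, books the removed mass as a release
pulse, and restarts — mass is conserved across the discontinuity by
construction, which integrating a stiff forcing spike would not
guarantee.

## Accounting quantities

- Stock change `ΔtC = C(t) − C(0)` (kg C m⁻²): the traditional metric.
- Carbon sequestration `CS(t0, T) = ∫ C(t) dt − T·C(t0)`
  (kg C m⁻² yr): time-integrated storage relative to the initial stock.
  Positive for net accumulation-time, negative for loss-time, exactly
  zero for a constant stock. Three algebraically equivalent forms exist
  (double integral of n; integral of C − C(0); integral of C minus
  T·C(0)); the package implements the stock-based and flux-based routes
  separately and tests them against each other, because in practice
  they start from different data (trajectories vs flux towers).
- New-inputs-only CS: the stock attributable to post-t0 inputs,
  `Mu(t)`, obtained by re-simulating with `x0 = 0` (same u, same B) and
  integrating. By linearity this equals total CS minus the CS of the
  legacy-only run (`u = 0`), an identity the test suite sweeps over
  seeded random models.
- Baseline-referenced forms: `ΔbC(t) = C(t) − Cb(t)` and
  `ΔbCS = CS − CSb`. The relative forms divide by the baseline's final
  stock `Cb(T)` and by `|CSb|` respectively, so a project that fully
  avoids the baseline's carbon-time losses scores 100%; both
  conventions are recorded in the report's provenance block since other
  normalisations are conceivable.

## Transit time

For autonomous models the mean transit time is `−1ᵀB⁻¹u / 1ᵀu` and the
density is `f(t) = −1ᵀB e^{Bt} u / 1ᵀu` — the exit-time distribution of
a particle injected according to the input mix and moved by the Markov
jump process encoded in B. The density is evaluated by integrating
`dy/dt = By` from `y(0) = u/1ᵀu` (cheaper and better conditioned than
dense matrix exponentials on long grids); quantiles come from inverting
the trapezoid-accumulated CDF with linear interpolation. A singular B
(a pool with no exit path) raises an infinite-transit-time error; zero
total input leaves the quantity undefined.

A seeded Monte-Carlo particle sampler (`sample_transit_times`)
simulates the jump process directly: entry pool ∝ u, Exp(−B_ii) waiting
times, destination probabilities from the column entries. It is an
independent route to the same distribution, used in the tests to
cross-check the closed forms, and the only transit-time support offered
for non-autonomous models (a documented limitation; non-autonomous
transit-time theory is out of scope). No permanence threshold is
defined anywhere: the distribution itself is the deliverable.

## Numerical choices

- Integrator: `scipy.integrate.solve_ivp` with LSODA (stiff-capable,
  automatic switching), rtol 1e-10 / atol 1e-12, sampled on a uniform
  output grid. Defaults this tight cost little on few-pool systems and
  keep solver error (~1e-10 relative on the one-pool closed form) far
  below the 1e-6/1e-8 invariant tolerances, so test failures implicate
  logic, not integration.
- Grid: default step 0.01 yr. CS accuracy is quadrature-limited, not
  dynamics-limited; at this step the trapezoidal CS of the cropland
  fixtures is within ~1e-9 relative of the closed form.
- Quadrature: `integrate_series` is composite trapezoid — exact for
  piecewise-linear integrands, second-order otherwise (the convergence
  tests verify error ratios of 4 per step halving). The *cumulative*
  integral of the net flux (mass-balance audit, flux-based CS) uses
  composite Simpson per inter-event segment with the left-limit flux at
  event endpoints: trapezoidal accumulation leaves O(h²) residuals that
  approach 1e-6 relative for turnover rates near 0.5 yr⁻¹ at the
  default step, too close to the tolerance the audit itself enforces.
- Events are snapped to the nearest grid point (event times falling
  between points are inserted into the grid first), making segment
  bounds exact floats for the solver.
- Negative stocks: values more negative than 1e-9 of the maximum stock
  raise a numerical-failure error naming pool and time; smaller
  undershoot is clipped to zero as solver noise.
- Metrics on user-supplied CSV trajectories use the given grid as-is;
  fewer than 10 points per horizon is echoed as a coarseness warning in
  the metric's provenance.
- Time is internally years since t0 (grid starts at 0); calendar years
  (e.g. 1963) are display labels only. Units are declared, not
  converted — the single `Mg_ha` toggle is a pure relabel by a factor
  of 10.

## Scenario generators

`estanzuela()` encodes the three cropland soil-management trajectories:
one-pool models starting at 6 kg C m⁻² in 1963 with decay rates
0.01 yr⁻¹ (S1, intensive cropping), 0.005 yr⁻¹ (S2, fertilized) and 0
(S3, rotational crop–pasture), evaluated over 60 years. The rates are
the ones that reproduce the published 2023 stocks (3.29 and
4.44 kg C m⁻²) from the 1963 value; the published comparison table
follows to printed precision. S3 is inert (B = 0, u = 0) by default; a
flux-balanced variant (u = r > 0) is provided because it has the same
(zero) CS but a finite transit time — storage-time accounting and
permanence are distinct questions, and the pair illustrates that.

`two_speed()` produces saturating accumulators
`C(t) = cmax(1 − e^{−kt})` as simulated one-pool models (u = cmax·k,
turnover k): two systems reaching the same ceiling at different speeds,
where the faster one dominates pointwise and therefore wins on CS. The
curve parameters are exposed rather than fixed, since only the
qualitative ordering is a testable claim.

`random_model(seed)` generates property-test fodder: turnover rates
uniform in 0.02–0.5 yr⁻¹ (slow soil pools up to fast litter-like
pools), at least 20% of each pool's outflow routed to the atmosphere
(so B is invertible and every pool eventually releases), Dirichlet
splits for internal transfers, uniform non-negative inputs and stocks.
Same seed, same model, bitwise.

These generators emulate the shapes the accounting metrics are defined
on — smooth declines, saturating growth, step reversals. They do not
emulate measurement noise, seasonal or interannual variability, or
nonlinear feedbacks; passing tests demonstrate correctness of the
accounting machinery on clean trajectories, not robustness of CS
estimation from noisy field data (a coarse-grid warning is the only
concession to sampled real-world input).

## Known limitations

- Linear dynamics only; no density dependence, no spatial structure,
  no process-based flux submodels.
- Transit-time closed forms require autonomy; time-varying models get
  only the sampling route.
- No uncertainty propagation on metrics, and no economic weighting
  (discounting) of carbon-time — valuation is deliberately separated
  from accounting.
- Radiative-forcing extensions of the framework (forcing-equivalence of
  storage, warming-potential comparisons) are out of scope.
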