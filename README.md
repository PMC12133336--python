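# carbontime

Time-integrated carbon accounting for compartmental carbon-storage
systems.

## The problem

Carbon removed from the atmosphere by a soil, forest, or engineered
reservoir does not stay there forever. Traditional *stock-change*
accounting — credit the difference in stored carbon between two dates —
is blind to how long the carbon was actually kept out of the
atmosphere: a tonne stored for 60 years and a tonne stored for 6 months
can earn the same credit. `carbontime` implements an accounting
framework in which time is a first-class dimension, aimed at scientists
and methodology developers working on carbon crediting, nature-based
solutions, and carbon-dioxide-removal projects.

The storage system is modelled as a linear compartmental system

```
dx/dt = u(t) + B(t) x(t)
```

with pool stocks `x` (kg C m⁻²), gross uptake fluxes from the
atmosphere `u(t)` (kg C m⁻² yr⁻¹), and a compartmental rate matrix
`B(t)` (1/yr) whose off-diagonals are internal transfers and whose
column-sum deficits are releases back to the atmosphere. Catastrophic
reversals (fire, harvest) are instantaneous pulse transfers of pool
fractions to the atmosphere. Total stock is `C(t) = 1ᵀx(t)`, and the
net removal flux is `n(t) = u(t) − r(t) = dC/dt`.

On top of that, the package computes:

- **Carbon sequestration** `CS(t0, T) = ∫ C(t) dt − T·C(t0)` over a
  horizon `[t0, t0+T]` — an *area* under the stock curve, in units of
  mass·time (kg C m⁻² yr). It credits both how much carbon is stored
  and for how long; it is zero for a constant stock, and can
  equivalently be computed as a double integral of `n(t)` (the package
  verifies the forms against each other).
- A **new-inputs-only** variant that tracks only carbon entering after
  t0 (legacy stocks out of scope), exact for linear models by
  superposition.
- **Baseline-referenced** differences `ΔbC(t) = C(t) − Cb(t)` (mass)
  and `ΔbCS = CS − CSb` (mass·time), plus their relative (%) forms.
- **Transit-time diagnostics** for autonomous models — mean
  `−1ᵀB⁻¹u / 1ᵀu`, full density `f(t) = −1ᵀB e^{Bt} u / 1ᵀu`, quantiles,
  and a seeded Monte-Carlo particle sampler — so the *permanence* of
  storage is a computed property, not an a-priori label.

## Worked example

The built-in `estanzuela` fixture mimics three long-term soil-management
trajectories of a cropland soil (one-pool exponentials from
6 kg C m⁻² in 1963, 60-year horizon): S1 — intensive cropping, decay
0.01 yr⁻¹; S2 — fertilized cropping, decay 0.005 yr⁻¹; S3 — rotational
crop–pasture, constant stock.

```python
import carbontime as ct

models = ct.estanzuela()
cfg = ct.RunConfig(horizon=60.0, step=0.01)
print(ct.report(models, "S1", cfg).text)
```

prints

```
| metric | units | S1 | S2 | S3 |
| --- | --- | --- | --- | --- |
| C | kg C m-2 | 3.29 | 4.44 | 6 |
| delta_t_C | kg C m-2 | -2.71 | -1.56 | 0 |
| CS | kg C m-2 yr | -89.29 | -48.98 | 0 |
| delta_b_C | kg C m-2 | 0 | 1.15 | 2.71 |
| relative_delta_b_C | % | 0 | 35 | 82 |
| delta_b_CS | kg C m-2 yr | 0 | 40.31 | 89.29 |
| relative_delta_b_CS | % | 0 | 45 | 100 |
```

Reading the table: over 60 years the degrading baseline S1 loses
2.71 kg C m⁻² of stock and −89.29 kg C m⁻² yr of carbon-time. Switching
to S2 avoids 1.15 kg C m⁻² of the stock loss — 35% of the baseline's
final stock — but 45% of the baseline's carbon-time losses; the
sustainable system S3 avoids 82% of the stock loss yet 100% of the
carbon-time losses, because a constant stock loses no carbon-time at
all. Stock-based and time-integrated accounting rank projects
differently, which is the point of the metric.

The same table is available from the shell:

```sh
carbontime report --scenario estanzuela --baseline S1
```

and `carbontime simulate / metrics / compare / transit / scenario` cover
the rest of the surface (JSON model specs in, CSV trajectories and JSON
metrics out; `--help` on any verb).

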