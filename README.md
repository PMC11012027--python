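# permgrad

Membrane permeability from **steady-state concentration gradients** in
periodic simulation boxes.

Most simulation estimates of membrane permeability are made at
equilibrium, even though experiments measure permeation down a
concentration gradient. A gradient can be sustained in a periodic box by
biasing selected permeants only in a thin region at the boundary: a grid
potential that is flat across the core and changes linearly near the
periodic boundary costs each boundary traversal a fixed energy step, so
particles preferentially re-enter on one side and a stationary gradient
builds across whatever obstacle — typically a lipid bilayer — sits in the
core. The permeants then obey Fick's steady-state law,

```
J = P · Δc,        P = accumulated flow / (area · Δt · Δc),
```

with `J` the flux density through the membrane, `Δc` the concentration
difference read from thin-slab profiles just outside the headgroups
(z = ±30 Å), and `P` reported in cm/s with block-averaged standard
errors.

`permgrad` implements the full analysis stack around that idea:

* **`gridpot`** — boundary-ramp bias potentials: flat core, linear
  flanks, exact energy step between periodic images; OpenDX export for
  MD grid-forces modules.
* **`bdsim`** — a desk-scale surrogate engine: overdamped Brownian
  dynamics of non-interacting permeants under a Gaussian-component
  membrane PMF plus the ramp, and an exact steady-state Smoluchowski
  solver (tilted-periodic double-quadrature formula) used as an
  independent oracle.
* **`analysis`** — 1-Å slab concentration profiles (mmol/L), the
  wrap-safe four-region flow counter (+1 / −1 for genuine crossings of
  the boundary plane, 0 for periodic-boundary wraps), membrane-area
  series, and block averaging for autocorrelation-honest error bars.
* **`permeability`** — `P = J/Δc` with a documented unit-constant chain,
  gradient-dissipation profiles `ΔΔG(z) = −kBT·ln(c_grad/c_ctrl)`, the
  inhomogeneous solubility-diffusion resistance integral
  `Rp = ∫ e^{w(z)/kBT}/D(z) dz` as a cross-check, and Henry's-law
  solubility helpers.
* **`pipeline` / `cli`** — an end-to-end, seed-reproducible experiment
  runner (`permgrad demo`, `permgrad analyze …`, `permgrad perm …`).

## Worked example

Permeability of a POPC bilayer to O2 from tabulated gradient-simulation
measurements (concentrations at z = ±30 Å in mmol/L, flow per 100 ns,
area in Å²):

```python
import permgrad as pg

p = pg.permeability_from_components(flow_rate=16.1, area=9434.0,
                                    delta_c=27.77 - 9.38)
print(f"{p:.2f} cm/s")     # 15.41 cm/s
```

Running `python examples/permeability_from_measurements.py` prints the
whole series:

```
run              Δc (mmol/L)   P (cm/s)
5 O2,  CSVR            1.64      12.10
50 O2, CSVR           18.39      15.41
500 O2, CSVR         121.68      23.75
50 O2, Langevin       16.86      13.83
```

— permeability rises with permeant load (dissolved O2 spreads the lipids
and makes the membrane leakier), and a Langevin thermostat depresses it
relative to velocity-rescaling through the diffusivity it imposes. The
Henry's-law line (`≈ 250 μM` of O2 at 0.21 atm) shows how far even the
smallest simulated load sits above physiological concentrations.

A full synthetic experiment, from Brownian dynamics to permeability and
dissipation, is one call (`python examples/gradient_pipeline_demo.py`):

```
Δc(+30 Å vs -30 Å) = 151.7 ± 8.4 mmol/L
flow rate          = -1232.5 /100 ns
P                  = 134.9 ± 3.4 cm/s (10 blocks of 20 ns)
flat-potential expectation D/Δz = 133 cm/s
```

The water-box analog (no membrane) recovers the analytic solvent-column
permeability `D/Δz` and a linear core gradient — the signature that the
boundary ramp is holding a true steady state. `examples/` holds one
short script per capability.

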