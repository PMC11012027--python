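# Methods

## The gradient method

A concentration gradient is maintained in a periodic box by biasing the
motion of selected permeants only near the periodic boundary along z.
The bias is a one-dimensional grid potential `U_b(z)`: identically zero
throughout the core `|z| ≤ c` and linear on the two flanks between the
core edge and the boundary at `±Lz/2`, such that the potential differs
by a fixed energy step `Δε` between periodic images. A particle carried
across the boundary in the bias direction gains `Δε`; in the core its
dynamics are untouched. The result is a stationary state with a net flow
and a sustained concentration difference across any obstacle in the
core.

With the steady state established, Fick's law gives the permeability of
the obstacle directly:

```
J = P Δc,    P = F / (A · Δt · Δc)
```

where `F` is the accumulated flow (net signed crossings of the membrane
plane) per averaging window `Δt`, `A` the lateral area, and `Δc` the
concentration difference between thin slabs just outside the obstacle.

### Ramp geometry

The energy step is split half-and-half between the two flanks, each a
single linear segment continuous with the flat core; the tilted periodic
continuation is then continuous everywhere. The reference geometry is a
220-Å box with a 90-Å core half-width, so the step of 1 kcal/mol is
spread over 40 Å of biased region (slope 0.025 kcal/mol/Å). The ramp
junction is snapped outward to the nearest grid node so the core is flat
to machine precision regardless of spacing; grid spacing defaults to
1 Å. The sign convention: `bias_direction = +1` means the potential
rises toward +z, pushing particles toward −z. Forces are the slopes of
the piecewise-linear node interpolant; at the measure-zero junction
nodes the left segment's slope is used, a deterministic tie-break.

## Brownian-dynamics surrogate

The atomistic engine is replaced by overdamped Brownian dynamics of
non-interacting point permeants:

```
z ← z − (D/kBT) U′(z) dt + sqrt(2 D dt) ξ,   ξ ~ N(0,1)
```

with `U = w(z) + U_b(z)`. The membrane enters only through its potential
of mean force `w(z)`, a sum of Gaussian components; the default profile
mimics a phospholipid bilayer as seen by a small hydrophobic gas —
repulsive headgroup barriers of 1.4 kcal/mol at z = ±18 Å (width 4 Å)
and a tail-core well of −0.75 kcal/mol (width 10 Å). Magnitudes are
configurable; the shape, not the numbers, is the point.

Parameter defaults and rationale:

| parameter | default | why |
|---|---|---|
| D | 800 Å²/ns | order of a small gas molecule in water; box-scale relaxation `Lz²/2D ≈ 30 ns`, so steady state is reached in nanoseconds |
| kBT | 0.61603 kcal/mol | 310 K with kB = 1.987204e-3 kcal/mol/K; the temperature that reproduces the reference 0.779 kcal/mol water-box reading |
| dt | 0.001–0.002 ns | keeps the maximum drift displacement per step well under the 1-Å grid scale (warned above 1 Å, rejected above Lz/2); validated by the free-diffusion MSD test |
| save interval | 0.025–0.05 ns | rms frame-to-frame displacement ~9–13 Å, far below the 40-Å counting regions, so multi-region jumps are rare (they are tallied and logged) |
| box | 100×100×220 Å | the reference membrane-patch geometry |

The integrator is Euler–Maruyama with fixed dt — the simplest scheme
with known weak-order behavior, adequate because every acceptance
comparison carries 3-sigma statistical bands much wider than the dt
bias. Position-dependent `D(z)` is supported in the Itô convention with
the spurious-drift correction `dD/dz`; constant D is the tested default.
Randomness comes from one `numpy` PCG64 stream; the seed is recorded in
the trajectory metadata and identical seeds give bit-identical
trajectories. Initial positions may be uniform, Boltzmann (for bias-off
equilibrium runs, by inverse-CDF sampling), or drawn from the exact
steady state so that production runs are stationary from the first
frame.

What the surrogate reproduces about real MD data: steady-state gradient
formation, dissipation by flow, flux statistics, and every analysis
contract (slab profiles, four-region counting, block errors). What it
does not: lipid–permeant coupling (area changes with load, membrane
perturbation), inertial/thermostat physics, and permeant–permeant
interactions — so passing tests validate the *analysis stack* and the
*method's statistical behavior*, not bilayer physics.

### Steady-state oracle

The 1-D Smoluchowski equation on the ring with a tilted potential
(`U(z+L) = U(z) + Δε`) has the classical closed-form stationary
solution

```
ρ(z) ∝ e^{−βU(z)} ∫_z^{z+L} e^{+βU(y)}/D(y) dy,
J = (1 − e^{βΔε}) / Z
```

evaluated by trapezoidal quadrature (default 8192 intervals). The
solver refuses to return a flux whose value changes by more than 1e-5
relative when the grid is halved, reporting the achieved tolerance. This
route shares no code with the trajectory estimators and serves as the
independent reference for counted flux, gradient shape, and recovered
permeability.

## Analysis conventions

* **Slab profiles** — 1-Å bins by default, counts per frame divided by
  slab volume and converted with 1 molecule/Å³ = 1/6.02214076e-4 mol/L.
  A bin width that does not divide Lz truncates the last slab (logged).
  Summing concentration × volume recovers the mean particle count
  exactly.
* **Δc** — the value of the slab *containing* z = ±30 Å, not an
  interpolation: the estimator is defined at slab resolution, and the
  oracle comparisons average the exact density over the same slabs.
  Errors of the two slabs combine in quadrature.
* **Four-region counting** — regions III = [B−h, B) and II = [B, B+h)
  around the boundary B (default h = 40 Å), flanks I and IV absorbing
  periodic wraps. III→II is +1, II→III is −1, everything else 0;
  intervals are half-open lower-inclusive so labeling is deterministic.
  Multi-region jumps (I↔II, III↔IV) contribute 0 and are counted as an
  undersaved-trajectory diagnostic. Counting is exactly antisymmetric
  under time reversal.
* **Block averaging** — consecutive frames are strongly autocorrelated,
  so all standard errors come from means of long blocks treated as
  independent samples; trailing partial blocks are dropped, and fewer
  than two complete blocks is an error. Surrogate runs default to 20-ns
  blocks over 200–400 ns (10 blocks): with D = 800 Å²/ns the box
  decorrelates in a few ns, so 20-ns blocks are comfortably independent
  — the analog of 100-ns blocks over microseconds of atomistic data,
  which remains the default of the analysis functions themselves.
* **Permeability** — computed per block with Δc held at its whole-run
  value (per-block slab statistics are too noisy at low permeant
  counts); `P` is the mean of block values with their standard error,
  and the whole-run value from global means is reported alongside. The
  result is oriented so P > 0 when the net flow runs down the gradient,
  whatever the bias direction; a Δc within two standard errors of zero
  flags the result unreliable rather than raising. Unit chain:
  molecules/(Å²·ns·mmol/L) → Å/ns via 1 mmol/L = 6.02214076e-7
  molecules/Å³, then 1 Å/ns = 10 cm/s; one molecule per 100 ns through
  1 Å² against 1 molecule/Å³ is exactly 0.1 cm/s.
* **Dissipation** — `ΔΔG(z) = −kBT ln(c_grad(z)/c_ctrl(z))` on matching
  bin grids, with zero-concentration bins masked. The chemical potential
  `−ΔΔG` decays monotonically along the flow direction in the water-box
  analog, and its total drop across the core is bounded by the imposed
  energy step.
* **ISD cross-check** — `Rp = ∫ e^{(w−w_ref)/kBT}/D dz` with `w_ref`
  the solvent plateau (mean of w over 35 Å ≤ |z| ≤ 60 Å by default, so
  a constant offset in w cannot change Rp); adaptive quadrature with a
  convergence guard. Valid in the small-gradient limit, which is why it
  is a cross-check and not the estimator.

## Design choices where the design was open

* The ramp is symmetric over both flanks rather than confined to a
  single boundary-adjacent slab; this matches the drawn flat-core /
  linear-ends shape and makes the bias geometry independent of the flow
  direction.
* Flow is measured by the region-transition rule with the membrane
  plane as the II/III boundary; the plane-crossing picture and the
  region picture agree whenever frames are saved densely enough, and
  the skipped-jump tally quantifies "densely enough".
* The error of P is taken block-wise from per-block P values, not by
  propagating component errors — propagation would need the covariance
  of flow, area, and Δc within blocks, which block-wise estimation gets
  for free.
* Temperature is a parameter (default 310 K) everywhere a kBT appears;
  the water-box energy reading back-solves to approximately this
  temperature.
* Henry's-law conversion uses a water molarity of 55.34 mol/L.

## Problem sizes

The shipped configurations are chosen so the whole test suite runs in
about a minute of one CPU: 500–1000 particles for 200–400 ns of
surrogate time, which yields thousands of membrane crossings and
sub-2 % flux errors — the same statistical regime as microsecond
atomistic runs of 50–500 permeants, at desk scale. All acceptance
comparisons are made at three block standard errors of these runs.

## Known limitations

* The surrogate's membrane is a rigid 1-D free-energy profile: no area
  fluctuations (area series are exact constants), no load-dependent
  leakiness, no lateral heterogeneity.
* Euler–Maruyama has O(dt) weak bias; at the default dt this is far
  inside the statistical bands, but very sharp PMFs require a smaller
  dt (the stability screen warns).
* The four-region counter undercounts if frames are saved so sparsely
  that particles skip regions; the `n_skipped` diagnostic should stay
  negligible relative to the net flow.
* `delta_c` at slab resolution carries O(bin width × gradient)
  discretization; comparisons against analytic densities must use the
  same slab convention.
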