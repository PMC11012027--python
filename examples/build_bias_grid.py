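"""Build a boundary-ramp bias potential and export it as an OpenDX grid.

The ramp is flat across the core of the box (here |z| <= 90 Å of a 220 Å
box) and rises linearly on the two boundary flanks so that one traversal
of the periodic boundary changes a particle's energy by exactly the
energy step (1 kcal/mol). An MD engine's grid-forces module can apply
this field to selected permeants to drive a steady concentration
gradient across whatever sits in the core.
"""

import numpy as np

import permgrad as pg

spec = pg.RampSpec(box_length_z=220.0, core_half_width=90.0,
                   energy_step=1.0, grid_spacing=1.0)
grid = pg.build_ramp(spec)

print(f"nodes: {len(grid.z_nodes)}, spacing {spec.effective_spacing} Å")
print(f"flank slope: {abs(spec.slope):.4f} kcal/mol/Å "
      "(1 kcal/mol over the 40 Å of biased region)")
print(f"U at core edge / boundary: {grid.energy(90.0):.3f} / "
      f"{grid.energy(-110.0):.3f} kcal/mol")
print(f"energy step across one period: "
      f"{grid.energy(0.0 + 220.0) - grid.energy(0.0):.6f} kcal/mol")
print(f"force in core / on flank: {pg.force_at(grid, 0.0):.4f} / "
      f"{pg.force_at(grid, -100.0):.4f} kcal/mol/Å")

pg.write_grid(grid, nx=2, ny=2, path="ramp.dx", box_xy=(100.0, 100.0),
              overwrite=True)
counts, values = pg.read_grid("ramp.dx")
assert np.array_equal(values.reshape(2, 2, -1)[0, 0], grid.energies)
print(f"wrote ramp.dx ({counts[0]}x{counts[1]}x{counts[2]} grid, "
      "round-trip verified)")
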