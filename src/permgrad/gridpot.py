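"""Boundary-ramp bias potentials for periodic simulation boxes.

A directional bias is imposed on selected particles by a one-dimensional
grid potential that is flat throughout the core of the box and changes
linearly in a narrow region adjacent to the periodic boundary along z.
Because the potential differs by a fixed energy step between periodic
images, every boundary traversal in the bias direction releases that step
of energy, producing a sustained drift that replenishes a concentration
gradient across whatever obstacle (e.g., a membrane) sits in the core.

The potential is represented on a regular node grid covering one period
[-Lz/2, +Lz/2) and interpolated piecewise-linearly; the tilted periodic
continuation is available through :meth:`GridPotential1D.energy`.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RampSpec",
    "GridPotential1D",
    "build_ramp",
    "force_at",
    "write_grid",
    "read_grid",
]


@dataclass(frozen=True)
class RampSpec:
    """Geometry and magnitude of a boundary bias ramp.

    Parameters
    ----------
    box_length_z : float
        Periodic box length along z, Å.
    core_half_width : float
        Half-width of the unbiased (flat) core region, Å. The bias ramp
        occupies the two flanks between ``±core_half_width`` and the
        periodic boundary at ``±box_length_z/2``.
    energy_step : float
        Energy difference between periodic images, kcal/mol. One full
        traversal of the boundary along the bias direction lowers a
        particle's energy by this amount.
    grid_spacing : float
        Node spacing of the exported grid, Å. Snapped to the nearest
        exact divisor of ``box_length_z``.
    bias_direction : int
        +1 pushes particles toward -z (the potential rises toward +z),
        -1 the opposite.
    """

    box_length_z: float
    core_half_width: float
    energy_step: float = 1.0
    grid_spacing: float = 1.0
    bias_direction: int = +1

    def __post_init__(self) -> None:
        if self.grid_spacing <= 0:
            raise ValueError(f"grid_spacing must be positive, got {self.grid_spacing}")
        if self.core_half_width <= 0:
            raise ValueError("core_half_width must be positive")
        if self.box_length_z <= 2 * self.core_half_width:
            raise ValueError(
                "no room for a ramp: box_length_z must exceed 2*core_half_width "
                f"(got Lz={self.box_length_z}, core={self.core_half_width})"
            )
        if self.energy_step < 0:
            raise ValueError("energy_step must be non-negative")
        if self.bias_direction not in (+1, -1):
            raise ValueError("bias_direction must be +1 or -1")

    @property
    def n_nodes(self) -> int:
        """Number of nodes tiling one period."""
        return max(int(round(self.box_length_z / self.grid_spacing)), 4)

    @property
    def effective_spacing(self) -> float:
        """Spacing after snapping to an exact divisor of the period."""
        return self.box_length_z / self.n_nodes

    @property
    def snapped_core(self) -> float:
        """Core half-width snapped outward to the nearest grid node.

        The ramp junction must sit on a node for the grid potential to be
        exactly flat throughout the requested core; snapping can only
        widen the flat region, never narrow it.
        """
        h = self.effective_spacing
        snapped = h * np.ceil(self.core_half_width / h - 1e-12)
        if snapped >= self.box_length_z / 2 - h / 2:
            raise ValueError(
                f"grid_spacing {self.grid_spacing} too coarse: no node left "
                "for the ramp between the core edge and the boundary"
            )
        return float(snapped)

    @property
    def ramp_width(self) -> float:
        """Total biased length per period (both flanks), Å."""
        return self.box_length_z - 2 * self.snapped_core

    @property
    def slope(self) -> float:
        """Signed dU/dz on the flanks, kcal/mol/Å."""
        return self.bias_direction * self.energy_step / self.ramp_width


@dataclass(frozen=True)
class GridPotential1D:
    """Piecewise-linear periodic potential on a regular z grid.

    ``z_nodes`` covers one period [-Lz/2, +Lz/2); ``energies`` holds the
    node values in kcal/mol. The tilted continuation satisfies
    ``U(z + Lz) - U(z) = bias_direction * energy_step``.
    """

    z_nodes: np.ndarray
    energies: np.ndarray
    spec: RampSpec = field(repr=False)

    def __post_init__(self) -> None:
        if len(self.z_nodes) != len(self.energies):
            raise ValueError("z_nodes and energies must have equal length")

    @property
    def period(self) -> float:
        return self.spec.box_length_z

    def _wrap(self, z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Wrap z into [-Lz/2, +Lz/2); also return the image index."""
        lz = self.period
        shifted = np.asarray(z, dtype=float) + lz / 2
        image = np.floor(shifted / lz)
        return shifted - image * lz - lz / 2, image

    def energy(self, z) -> np.ndarray | float:
        """Evaluate the tilted periodic potential at arbitrary z (kcal/mol)."""
        zw, image = self._wrap(z)
        h = self.spec.effective_spacing
        lz = self.period
        # periodic extension node at +Lz/2 carries the within-period end value
        e_ext = np.append(self.energies, self.energies[0] + self.spec.bias_direction * self.spec.energy_step)
        x = (zw + lz / 2) / h
        u = np.interp(x, np.arange(len(e_ext)), e_ext)
        out = u + image * self.spec.bias_direction * self.spec.energy_step
        return out if np.ndim(z) else float(out)

    def force(self, z) -> np.ndarray | float:
        """Force -dU/dz at arbitrary z, kcal/mol/Å. See :func:`force_at`."""
        return force_at(self, z)


def _analytic_profile(spec: RampSpec, z: np.ndarray) -> np.ndarray:
    """Within-period ramp profile: 0 in the core, linear on the flanks."""
    m = spec.slope
    c = spec.snapped_core
    u = np.zeros_like(z)
    hi = z > c
    lo = z < -c
    u[hi] = m * (z[hi] - c)
    u[lo] = m * (z[lo] + c)
    return u


def build_ramp(spec: RampSpec) -> GridPotential1D:
    """Construct the boundary-ramp potential for ``spec``.

    The core ``|z| <= core_half_width`` is flat at zero; each flank carries
    half the energy step as a single linear segment, so the profile is
    continuous within the period and across the periodic boundary (where
    the tilted continuation takes over).
    """
    n = spec.n_nodes
    h = spec.effective_spacing
    z = -spec.box_length_z / 2 + h * np.arange(n)
    return GridPotential1D(z_nodes=z, energies=_analytic_profile(spec, z), spec=spec)


def force_at(grid: GridPotential1D, z) -> np.ndarray | float:
    """Force -dU/dz of the piecewise-linear potential at arbitrary z.

    Zero in the open core interior; constant magnitude
    ``energy_step / ramp_width`` on the flanks, pointing along the bias
    direction. At a node the slope of the segment to the *left* is used
    (deterministic convention for the measure-zero junction set).
    """
    spec = grid.spec
    lz = grid.period
    h = spec.effective_spacing
    n = len(grid.z_nodes)
    zw, _ = grid._wrap(z)
    x = (zw + lz / 2) / h
    idx = np.floor(x).astype(int)
    at_node = np.abs(x - np.round(x)) < 1e-9
    idx = np.where(at_node, np.round(x).astype(int) - 1, idx) % n
    e_ext = np.append(grid.energies, grid.energies[0] + spec.bias_direction * spec.energy_step)
    slopes = np.diff(e_ext) / h
    out = -slopes[idx]
    return out if np.ndim(z) else float(out)


def write_grid(
    grid: GridPotential1D,
    nx: int,
    ny: int,
    path: str | os.PathLike,
    *,
    box_xy: tuple[float, float] | None = None,
    overwrite: bool = False,
) -> None:
    """Export the potential as an OpenDX regular scalar grid.

    The 3-D field is constant in x and y and follows the 1-D profile along
    z. Values are written with full decimal precision so a read-back
    reproduces the node energies exactly. ``box_xy`` sets the lateral
    extent (defaults to ``(nx-1, ny-1)`` times the z spacing); the data
    are laid out in C order with z varying fastest, the dialect read by
    common MD grid-force modules.
    """
    if nx < 1 or ny < 1:
        raise ValueError("nx and ny must be >= 1")
    path = os.fspath(path)
    if os.path.exists(path) and not overwrite:
        raise FileExistsError(f"{path} exists; pass overwrite=True to replace it")

    spec = grid.spec
    nz = len(grid.z_nodes)
    h = spec.effective_spacing
    if box_xy is None:
        lx = max(nx - 1, 1) * h
        ly = max(ny - 1, 1) * h
    else:
        lx, ly = box_xy
    dx = lx / max(nx - 1, 1)
    dy = ly / max(ny - 1, 1)
    origin = (-lx / 2, -ly / 2, -spec.box_length_z / 2)

    values = np.tile(grid.energies, nx * ny)  # z fastest, C order
    lines = [
        "# OpenDX scalar grid: boundary-ramp bias potential",
        f"# energy_step={spec.energy_step!r} kcal/mol, core_half_width={spec.core_half_width!r} A",
        f"object 1 class gridpositions counts {nx} {ny} {nz}",
        f"origin {origin[0]:.17g} {origin[1]:.17g} {origin[2]:.17g}",
        f"delta {dx:.17g} 0 0",
        f"delta 0 {dy:.17g} 0",
        f"delta 0 0 {h:.17g}",
        f"object 2 class gridconnections counts {nx} {ny} {nz}",
        f"object 3 class array type double rank 0 items {values.size} data follows",
    ]
    for i in range(0, values.size, 3):
        lines.append(" ".join(f"{v:.17g}" for v in values[i : i + 3]))
    lines.append('attribute "dep" string "positions"')
    lines.append('object "bias potential" class field')
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_grid(path: str | os.PathLike) -> tuple[tuple[int, int, int], np.ndarray]:
    """Read back an OpenDX grid written by :func:`write_grid`.

    Returns the (nx, ny, nz) counts and the data values in file order
    (C order, z fastest). Intended for round-trip validation.
    """
    counts: tuple[int, int, int] | None = None
    n_items = None
    values: list[float] = []
    with open(path) as fh:
        in_data = False
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith("object 1"):
                counts = tuple(int(t) for t in line.split()[-3:])  # type: ignore[assignment]
            elif "data follows" in line:
                n_items = int(line.split("items")[1].split()[0])
                in_data = True
            elif in_data:
                if line.startswith(("attribute", "object")):
                    in_data = False
                    continue
                values.extend(float(t) for t in line.split())
    if counts is None or n_items is None or len(values) != n_items:
        raise ValueError(f"malformed DX file {path!r}")
    return counts, np.asarray(values)
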