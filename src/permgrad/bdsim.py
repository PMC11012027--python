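"""Overdamped Brownian dynamics of permeants in a periodic box.

This module is a desk-scale surrogate for an atomistic MD engine: it
propagates non-interacting point permeants by Euler–Maruyama integration
of the overdamped Langevin equation

    dz = -(D/kBT) U'(z) dt + sqrt(2 D dt) dW,

where the total potential U combines a membrane potential of mean force
w(z) (a sum of Gaussian barriers and wells) with the boundary-ramp bias
of :mod:`permgrad.gridpot`. The membrane enters only through its PMF; the
permeants never interact, so concentration profiles and fluxes scale
linearly with particle count.

An independent steady-state oracle, :func:`smoluchowski_steady_state`,
solves the one-dimensional Smoluchowski equation on the periodic ring with
a fixed energy tilt per period by the standard double-quadrature formula,
yielding the exact stationary density and per-particle flux against which
trajectory-based estimates can be validated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .gridpot import GridPotential1D
from .trajectory import Trajectory
from .units import thermal_energy

__all__ = [
    "MembranePMF",
    "BDParams",
    "SteadyState",
    "simulate",
    "smoluchowski_steady_state",
]


@dataclass(frozen=True)
class MembranePMF:
    """Permeant potential of mean force along the membrane normal.

    A sum of Gaussian components ``height * exp(-(z-center)^2 / (2 width^2))``
    with height in kcal/mol (negative for wells) and center/width in Å.
    The default profile mimics a phospholipid bilayer as seen by a small
    hydrophobic gas: repulsive barriers at the polar headgroups and an
    attractive well in the lipid tail core.
    """

    components: tuple[tuple[float, float, float], ...] = ()  # (center, height, width)

    @classmethod
    def bilayer_default(cls) -> "MembranePMF":
        """Headgroup barriers of 1.4 kcal/mol at z = ±18 Å (width 4 Å) and
        a core well of -0.75 kcal/mol at z = 0 (width 10 Å)."""
        return cls(components=((-18.0, 1.4, 4.0), (18.0, 1.4, 4.0), (0.0, -0.75, 10.0)))

    @classmethod
    def flat(cls) -> "MembranePMF":
        return cls(components=())

    def value(self, z) -> np.ndarray | float:
        z = np.asarray(z, dtype=float)
        w = np.zeros_like(z)
        for center, height, width in self.components:
            w += height * np.exp(-((z - center) ** 2) / (2 * width**2))
        return w if w.ndim else float(w)

    def derivative(self, z) -> np.ndarray | float:
        z = np.asarray(z, dtype=float)
        dw = np.zeros_like(z)
        for center, height, width in self.components:
            dw += height * (-(z - center) / width**2) * np.exp(
                -((z - center) ** 2) / (2 * width**2)
            )
        return dw if dw.ndim else float(dw)

    def extent(self) -> float:
        """|z| beyond which the PMF is negligible (center + 3 widths)."""
        if not self.components:
            return 0.0
        return max(abs(c) + 3 * w for c, _, w in self.components)


@dataclass(frozen=True)
class BDParams:
    """Brownian-dynamics run parameters.

    diffusivity is in Å²/ns (constant; a per-z table (z_nodes, D_values)
    is accepted for position-dependent diffusion, integrated in the Itô
    convention with the spurious-drift correction dD/dz). The surrogate
    default of 800 Å²/ns is of the order of a small gas molecule in water,
    which keeps box-scale relaxation within nanoseconds.
    """

    n_particles: int = 500
    diffusivity: float | tuple[np.ndarray, np.ndarray] = 800.0
    kT: float = field(default_factory=thermal_energy)
    dt: float = 0.001
    n_steps: int = 100_000
    save_every: int = 100
    box: tuple[float, float, float] = (100.0, 100.0, 220.0)
    seed: int = 0
    track_xy: bool = False
    init: str = "uniform"  # uniform | equilibrium | steady_state

    def __post_init__(self) -> None:
        if self.n_particles < 1:
            raise ValueError("need at least one particle")
        if self.dt <= 0 or self.n_steps < 1:
            raise ValueError("dt and n_steps must be positive")
        if self.kT <= 0:
            raise ValueError("kT must be positive")
        if isinstance(self.diffusivity, float) and self.diffusivity <= 0:
            raise ValueError("diffusivity must be positive")
        if self.n_steps % self.save_every != 0:
            raise ValueError("n_steps must be a multiple of save_every")
        if self.init not in ("uniform", "equilibrium", "steady_state"):
            raise ValueError(f"unknown init mode {self.init!r}")


def _total_potential_samples(
    pmf: MembranePMF | None,
    bias: GridPotential1D | None,
    lz: float,
    n: int,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Sample w(z) + within-period bias on n+1 nodes over one period.

    Returns (z_nodes, U, tilt) where U[n] = U[0] + tilt.
    """
    z = np.linspace(-lz / 2, lz / 2, n + 1)
    u = np.zeros_like(z)
    if pmf is not None:
        u += pmf.value(z)
    tilt = 0.0
    if bias is not None:
        # energy() evaluates the tilted continuation, so the +Lz/2 node
        # lands on U(-Lz/2) + tilt automatically
        u += bias.energy(z)
        tilt = bias.spec.bias_direction * bias.spec.energy_step
    return z, u, tilt


def _sample_from_density(
    rng: np.random.Generator, z_nodes: np.ndarray, density: np.ndarray, size: int
) -> np.ndarray:
    """Inverse-CDF sampling of a tabulated density on [z0, z1]."""
    cdf = np.concatenate([[0.0], np.cumsum((density[1:] + density[:-1]) / 2 * np.diff(z_nodes))])
    cdf /= cdf[-1]
    # make strictly increasing for interpolation
    cdf = np.maximum.accumulate(cdf)
    u = rng.random(size)
    return np.interp(u, cdf, z_nodes)


def simulate(
    params: BDParams,
    pmf: MembranePMF | None = None,
    bias: GridPotential1D | None = None,
) -> Trajectory:
    """Run overdamped Brownian dynamics and return the saved trajectory.

    Positions are wrapped into [-Lz/2, +Lz/2) every step; the cumulative
    number of boundary wraps is recorded in ``meta['n_wraps']`` so that
    downstream flow counting (which must ignore periodic-boundary
    traversals) can be sanity-checked. Identical parameters and seed give
    a bit-identical trajectory.
    """
    lx, ly, lz = params.box
    if pmf is not None and bias is not None:
        if pmf.extent() > bias.spec.core_half_width:
            warnings.warn(
                "membrane PMF extends into the biasing region; the core is "
                "no longer bias-free",
                stacklevel=2,
            )

    const_d = isinstance(params.diffusivity, (int, float))
    if const_d:
        d_of = None
        d_max = float(params.diffusivity)
    else:
        zt, dtab = params.diffusivity
        zt = np.asarray(zt, dtype=float)
        dtab = np.asarray(dtab, dtype=float)
        if np.any(dtab <= 0):
            raise ValueError("diffusivity table must be positive")
        ddz = np.gradient(dtab, zt)
        d_of = lambda z: (np.interp(z, zt, dtab), np.interp(z, zt, ddz))  # noqa: E731
        d_max = float(dtab.max())

    def force(z: np.ndarray) -> np.ndarray:
        f = np.zeros_like(z)
        if pmf is not None:
            f -= pmf.derivative(z)
        if bias is not None:
            f += bias.force(z)
        return f

    # stability screen on a fine grid
    zs = np.linspace(-lz / 2, lz / 2, 2048, endpoint=False)
    drift_step = np.max(np.abs(force(zs))) * d_max / params.kT * params.dt
    if drift_step > lz / 2:
        raise ValueError(
            f"dt={params.dt} ns gives a drift displacement of {drift_step:.3g} Å "
            "per step (more than half the box); reduce dt"
        )
    if drift_step > 1.0:
        warnings.warn(
            f"drift displacement per step is {drift_step:.3g} Å (> 1 Å grid "
            "scale); consider a smaller dt",
            stacklevel=2,
        )

    rng = np.random.default_rng(params.seed)
    n = params.n_particles
    half = lz / 2

    if params.init == "uniform":
        z = rng.uniform(-half, half, n)
    else:
        zn, u, tilt = _total_potential_samples(pmf, bias, lz, 8192)
        if params.init == "equilibrium":
            z = _sample_from_density(rng, zn, np.exp(-(u - u.min()) / params.kT), n)
        else:
            ss = smoluchowski_steady_state(
                (zn, u), params.diffusivity, lz=lz, kT=params.kT, tilt=tilt
            )
            z = _sample_from_density(rng, ss.z_nodes, ss.density, n)
        z = (z + half) % lz - half
    if params.track_xy:
        xy = np.column_stack([rng.uniform(-lx / 2, lx / 2, n), rng.uniform(-ly / 2, ly / 2, n)])

    n_save = params.n_steps // params.save_every + 1
    zs_out = np.empty((n_save, n))
    xy_out = np.empty((n_save, n, 2)) if params.track_xy else None
    zs_out[0] = z
    if params.track_xy:
        xy_out[0] = xy  # type: ignore[index]

    n_wraps = 0
    sqrt2dt = np.sqrt(2 * params.dt)
    k = 1
    for step in range(1, params.n_steps + 1):
        noise = rng.standard_normal(n)
        if const_d:
            z = z + (d_max / params.kT) * force(z) * params.dt + np.sqrt(d_max) * sqrt2dt * noise
        else:
            d, dd = d_of(z)  # type: ignore[misc]
            z = z + ((d / params.kT) * force(z) + dd) * params.dt + np.sqrt(d) * sqrt2dt * noise
        image = np.floor((z + half) / lz)
        crossed = image != 0
        if crossed.any():
            n_wraps += int(np.count_nonzero(crossed))
            z = np.where(crossed, z - image * lz, z)
        if params.track_xy:
            xy = xy + np.sqrt(d_max) * sqrt2dt * rng.standard_normal((n, 2))
            xy[:, 0] = (xy[:, 0] + lx / 2) % lx - lx / 2
            xy[:, 1] = (xy[:, 1] + ly / 2) % ly - ly / 2
        if step % params.save_every == 0:
            zs_out[k] = z
            if params.track_xy:
                xy_out[k] = xy  # type: ignore[index]
            k += 1

    times = params.dt * params.save_every * np.arange(n_save)
    return Trajectory(
        frame_times=times,
        z=zs_out,
        box_xy=np.tile([lx, ly], (n_save, 1)),
        lz=lz,
        xy=xy_out,
        meta={"seed": params.seed, "n_wraps": n_wraps, "dt": params.dt, "init": params.init},
    )


@dataclass(frozen=True)
class SteadyState:
    """Stationary solution on the periodic ring.

    density integrates to 1 over one period (units 1/Å); flux is the net
    per-particle drift rate around the ring (1/ns), signed along +z.
    """

    z_nodes: np.ndarray
    density: np.ndarray
    flux: float


def smoluchowski_steady_state(
    potential,
    diffusivity: float | tuple[np.ndarray, np.ndarray] = 800.0,
    *,
    lz: float = 220.0,
    kT: float | None = None,
    tilt: float = 0.0,
    n_grid: int = 8192,
    rtol: float = 1e-5,
) -> SteadyState:
    """Exact stationary density and flux for a tilted periodic potential.

    Solves J = -D(z) [rho'(z) + rho(z) U'(z)/kT] = const on a ring of
    period ``lz`` where the potential obeys U(z + lz) = U(z) + tilt. The
    solution is the classical double-quadrature formula

        rho(z) ∝ e^{-U(z)/kT} ∫_z^{z+L} e^{+U(y)/kT} / D(y) dy,
        J = (1 - e^{tilt/kT}) / Z,

    evaluated by trapezoidal quadrature on ``n_grid`` intervals.

    Parameters
    ----------
    potential : callable z -> kcal/mol, or (z_nodes, U) table over one
        period [-lz/2, +lz/2] (table may carry the tilt in its end value).
    tilt : energy gain per +z period traversal, kcal/mol.

    Raises
    ------
    RuntimeError
        If halving the grid changes the flux by more than ``rtol``
        (quadrature not converged); the message reports the achieved
        tolerance.
    """
    if kT is None:
        kT = thermal_energy()

    def solve(m: int) -> tuple[np.ndarray, np.ndarray, float]:
        z = np.linspace(-lz / 2, lz / 2, m + 1)
        if callable(potential):
            u = np.asarray(potential(z), dtype=float)
            u[-1] = u[0] + tilt
        else:
            zt, ut = potential
            u = np.interp(z, np.asarray(zt, dtype=float), np.asarray(ut, dtype=float))
            u[-1] = u[0] + tilt
        if isinstance(diffusivity, (int, float)):
            d = np.full(m + 1, float(diffusivity))
        else:
            zt, dtab = diffusivity
            d = np.interp(z, np.asarray(zt, dtype=float), np.asarray(dtab, dtype=float))
        if np.any(d <= 0):
            raise ValueError("diffusivity must be positive everywhere")

        beta = 1.0 / kT
        u0 = u - u.min()  # overflow guard; shifts cancel in rho and Z
        # extend over two periods for the running integral of e^{+U/kT}/D
        g1 = np.exp(beta * u0) / d
        g2 = g1[:-1] * np.exp(beta * tilt)
        g = np.concatenate([g1[:-1], g2, [g1[0] * np.exp(2 * beta * tilt)]])
        h = lz / m
        t = np.concatenate([[0.0], np.cumsum((g[1:] + g[:-1]) / 2 * h)])
        phi = t[m : 2 * m + 1] - t[: m + 1]
        rho_hat = np.exp(-beta * u0) * phi
        zz = np.trapezoid(rho_hat, z)
        flux = (1.0 - np.exp(beta * tilt)) / zz
        return z, rho_hat / zz, flux

    z, density, flux = solve(n_grid)
    _, _, flux_half = solve(n_grid // 2)
    scale = max(abs(flux), abs(flux_half), 1e-300)
    achieved = abs(flux - flux_half) / scale
    if flux != 0.0 and achieved > rtol:
        raise RuntimeError(
            f"steady-state quadrature not converged at n_grid={n_grid}: "
            f"achieved relative tolerance {achieved:.2e} > {rtol:.0e}; "
            "increase n_grid"
        )
    return SteadyState(z_nodes=z, density=density, flux=flux)
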