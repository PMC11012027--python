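"""Shared fixtures: toy trajectories and session-scoped BD runs.

The Brownian-dynamics runs are the expensive inputs reused across the
statistical tests; running them once per session keeps the suite fast
while every test still exercises the real simulation path.
"""

from __future__ import annotations

import numpy as np
import pytest

import permgrad as pg
from permgrad.bdsim import _total_potential_samples


def make_toy_trajectory(
    z_frames,
    lz: float = 220.0,
    box_xy: tuple[float, float] = (100.0, 100.0),
    frame_interval: float = 1.0,
) -> pg.Trajectory:
    """Trajectory from an explicit per-frame list of particle z positions."""
    z = np.atleast_2d(np.asarray(z_frames, dtype=float))
    f = z.shape[0]
    return pg.Trajectory(
        frame_times=frame_interval * np.arange(f),
        z=z,
        box_xy=np.tile(box_xy, (f, 1)),
        lz=lz,
    )


@pytest.fixture(scope="session")
def ramp_bias() -> pg.GridPotential1D:
    """Reference 220-Å box ramp: 90-Å core, 1 kcal/mol step, 1-Å spacing."""
    return pg.build_ramp(pg.RampSpec(220.0, 90.0, 1.0, 1.0))


@pytest.fixture(scope="session")
def water_box_run(ramp_bias) -> pg.Trajectory:
    """Water-box analog: flat PMF, bias on; 500 particles, 200 ns."""
    params = pg.BDParams(
        n_particles=500, n_steps=100_000, dt=0.002, save_every=25,
        seed=3, init="steady_state",
    )
    return pg.simulate(params, None, ramp_bias)


@pytest.fixture(scope="session")
def membrane_run(ramp_bias) -> pg.Trajectory:
    """Membrane analog: bilayer PMF + bias; 1000 particles, 400 ns."""
    params = pg.BDParams(
        n_particles=1000, n_steps=200_000, dt=0.002, save_every=25,
        seed=11, init="steady_state",
    )
    return pg.simulate(params, pg.MembranePMF.bilayer_default(), ramp_bias)


@pytest.fixture(scope="session")
def equilibrium_run() -> pg.Trajectory:
    """Bias-off run on the bilayer PMF, frames saved 10 ns apart so that
    slab occupancies are effectively independent samples."""
    params = pg.BDParams(
        n_particles=1000, n_steps=100_000, dt=0.002, save_every=5000,
        seed=5, init="equilibrium",
    )
    return pg.simulate(params, pg.MembranePMF.bilayer_default(), None)


def oracle_steady_state(
    pmf: pg.MembranePMF | None, bias: pg.GridPotential1D
) -> pg.SteadyState:
    """Smoluchowski stationary solution for a PMF + ramp combination."""
    lz = bias.spec.box_length_z
    zn, u, tilt = _total_potential_samples(pmf, bias, lz, 8192)
    return pg.smoluchowski_steady_state((zn, u), 800.0, lz=lz, kT=pg.thermal_energy(), tilt=tilt)


def oracle_slab_delta(ss: pg.SteadyState, profile: pg.SlabProfile) -> float:
    """Oracle prediction of the slab-based Δc estimator (relative units).

    Averages the stationary density over the same 1-Å slabs the profile
    uses for z = ±30 Å, mirroring the estimator's discretization.
    """
    def slab_mean(z: float) -> float:
        i = profile.bin_index(z)
        lo, hi = profile.bin_edges[i], profile.bin_edges[i + 1]
        m = (ss.z_nodes >= lo) & (ss.z_nodes < hi)
        return float(ss.density[m].mean())

    return slab_mean(30.0) - slab_mean(-30.0)
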