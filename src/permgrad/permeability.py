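"""Permeability, gradient dissipation, and thermodynamic helpers.

The central relation is Fick's steady-state law J = P·Δc: the flux
density J of permeants through the membrane (crossings per area per
time) is proportional to the concentration difference Δc across it. With
the accumulated flow, membrane area, and Δc measured from a trajectory,

    P = flow / (area · Δt · Δc),

resolved here from molecules/(Å²·ns·mmol/L) to cm/s through a documented
constant chain. Errors come from block averaging: P is computed per
block and the block values are treated as independent samples.

Also provided: the dissipation profile ΔΔG(z) = -kBT·ln(c_grad/c_ctrl)
that localizes the resistance to permeation, the inhomogeneous
solubility-diffusion (ISD) resistance integral as an independent
cross-check, and Henry's-law solubility estimates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import quad

from .analysis import BlockStats, DeltaC, FlowCount, SlabProfile, _stats_from_blocks
from .bdsim import MembranePMF
from .units import (
    A_PER_NS_TO_CM_PER_S,
    ATM_TO_PA,
    MMOL_PER_L_TO_PER_A3,
    NS_PER_A_TO_S_PER_CM,
    thermal_energy,
)

__all__ = [
    "PermeabilityResult",
    "DissipationProfile",
    "permeability_from_components",
    "permeability",
    "dissipation_profile",
    "energy_from_ratio",
    "isd_resistance",
    "henry_concentration",
    "normalized_flow_rate",
]


def permeability_from_components(
    flow_rate: float,
    area: float,
    delta_c: float,
    rate_window: float = 100.0,
) -> float:
    """P in cm/s from a flow rate, membrane area, and Δc.

    Parameters
    ----------
    flow_rate : molecules per ``rate_window`` ns, counted positive in the
        down-gradient direction (the convention of summary tables).
    area : membrane area, Å².
    delta_c : concentration difference, mmol/L.

    Notes
    -----
    Unit chain: molecules/(Å²·ns·mmol/L) → Å/ns via 1 mmol/L =
    6.02214076e-7 molecules/Å³, then 1 Å/ns = 10 cm/s. A flow of one
    molecule per 100 ns through 1 Å² against Δc of one molecule/Å³ is
    exactly 1 Å/100 ns = 0.1 cm/s.
    """
    if delta_c == 0:
        raise ZeroDivisionError("delta_c must be nonzero")
    p_a_per_ns = flow_rate / (area * rate_window * delta_c * MMOL_PER_L_TO_PER_A3)
    return p_a_per_ns * A_PER_NS_TO_CM_PER_S


@dataclass(frozen=True)
class PermeabilityResult:
    """Permeability with block-averaged error and its components.

    ``P`` is the mean of the per-block values; ``whole_run_P`` recomputes
    it from the global means of the components. ``reliable`` is False
    when Δc is statistically consistent with zero (|Δc| < 2 stderr), in
    which case P is reported but should not be trusted.
    """

    P: float  # cm/s
    stderr: float  # cm/s
    per_block_P: np.ndarray
    whole_run_P: float
    flow_rate: BlockStats  # molecules / block
    area: BlockStats  # Å²
    delta_c: DeltaC  # mmol/L
    block_size: float  # ns
    reliable: bool = True

    def summary(self) -> dict:
        return {
            "P_cm_per_s": float(self.P),
            "P_stderr_cm_per_s": float(self.stderr),
            "P_whole_run_cm_per_s": float(self.whole_run_P),
            "flow_per_block": float(self.flow_rate.mean),
            "flow_per_block_stderr": float(self.flow_rate.stderr),
            "area_A2": float(self.area.mean),
            "area_A2_stderr": float(self.area.stderr),
            "delta_c_mmol_L": float(self.delta_c.value),
            "delta_c_stderr": float(self.delta_c.stderr),
            "block_size_ns": float(self.block_size),
            "n_blocks": len(self.per_block_P),
            "reliable": bool(self.reliable),
        }


def permeability(
    flow: FlowCount,
    area: BlockStats,
    dc: DeltaC,
    block_size: float = 100.0,
) -> PermeabilityResult:
    """Combine counted flow, area, and Δc into P = J/Δc with block errors.

    Per block b, P_b = flow_b / (area_b · Δt · Δc) with Δc held at its
    whole-run value (per-block slab statistics are too noisy at low
    permeant counts). ``flow`` carries the +z boundary-normal sign
    convention; the result is oriented so that P > 0 when the net flow
    runs down the concentration gradient, regardless of the bias
    direction used to generate it.

    A Δc consistent with zero (|Δc| < 2 stderr) flags the result
    unreliable instead of raising.
    """
    flow_blocks = flow.block_flows(block_size)
    if area.n_blocks != flow_blocks.n_blocks:
        raise ValueError(
            f"flow and area disagree on block count "
            f"({flow_blocks.n_blocks} vs {area.n_blocks}); use one clock"
        )
    if dc.value == 0:
        raise ZeroDivisionError("delta_c is exactly zero; no gradient to divide by")
    reliable = abs(dc.value) >= 2 * dc.stderr

    # down-gradient orientation: flow counted along +z, gradient sign from dc
    down = -np.sign(dc.value)
    per_block = np.array(
        [
            permeability_from_components(
                down * f, a, abs(dc.value), rate_window=block_size
            )
            for f, a in zip(flow_blocks.block_values, area.block_values)
        ]
    )
    stats = _stats_from_blocks(per_block, block_size)
    whole = permeability_from_components(
        down * flow_blocks.mean, area.mean, abs(dc.value), rate_window=block_size
    )
    return PermeabilityResult(
        P=stats.mean,
        stderr=stats.stderr,
        per_block_P=per_block,
        whole_run_P=whole,
        flow_rate=flow_blocks,
        area=area,
        delta_c=dc,
        block_size=block_size,
        reliable=reliable,
    )


@dataclass(frozen=True)
class DissipationProfile:
    """Chemical-potential dissipation ΔΔG(z) across the box.

    ddG = -kBT·ln(c_gradient/c_control) per slab; slabs where either
    profile is zero are masked (no value). Steep drops along the flow
    direction localize the resistance to permeation.
    """

    bin_edges: np.ndarray
    ddG: np.ndarray  # kcal/mol, NaN where masked
    mask: np.ndarray  # True where a value is defined
    kT: float

    @property
    def bin_centers(self) -> np.ndarray:
        return (self.bin_edges[:-1] + self.bin_edges[1:]) / 2

    def concentration_ratio(self) -> np.ndarray:
        """Invert back to c_gradient/c_control (NaN where masked)."""
        return np.exp(-self.ddG / self.kT)


def dissipation_profile(
    grad: SlabProfile,
    ctrl: SlabProfile,
    kT: float | None = None,
) -> DissipationProfile:
    """ΔΔG(z) = -kBT · ln(c_gradient(z) / c_control(z)) per slab."""
    if kT is None:
        kT = thermal_energy()
    if grad.bin_edges.shape != ctrl.bin_edges.shape or not np.allclose(
        grad.bin_edges, ctrl.bin_edges
    ):
        raise ValueError("gradient and control profiles are on different bin grids")
    ok = (grad.mean_concentration > 0) & (ctrl.mean_concentration > 0)
    ddg = np.full(len(ok), np.nan)
    ddg[ok] = -kT * np.log(grad.mean_concentration[ok] / ctrl.mean_concentration[ok])
    return DissipationProfile(bin_edges=grad.bin_edges.copy(), ddG=ddg, mask=ok, kT=kT)


def energy_from_ratio(c1: float, c2: float, kT: float | None = None) -> float:
    """Free-energy difference kBT·ln(c1/c2) between two concentrations.

    The workhorse of gradient sanity checks: the concentration ratio at
    the two ends of the unbiased core should reflect the imposed energy
    step, less what is dissipated by the flow.
    """
    if kT is None:
        kT = thermal_energy()
    if c1 <= 0 or c2 <= 0:
        raise ValueError(f"concentrations must be positive, got {c1}, {c2}")
    return kT * float(np.log(c1 / c2))


def isd_resistance(
    w,
    D: float = 800.0,
    bounds: tuple[float, float] = (-30.0, 30.0),
    kT: float | None = None,
    solvent_range: tuple[float, float] | None = (35.0, 60.0),
) -> tuple[float, float]:
    """Inhomogeneous solubility-diffusion resistance and permeability.

    Evaluates Rp = ∫ exp(+w(z)/kBT) / D(z) dz over ``bounds``, with the
    potential of mean force w referenced to its solvent plateau (the mean
    of w over |z| in ``solvent_range``; pass None to use w as given).
    Returns ``(Rp in s/cm, P = 1/Rp in cm/s)``.

    Parameters
    ----------
    w : MembranePMF, callable z -> kcal/mol, or (z, w) table.
    D : diffusivity in Å²/ns, constant or callable or (z, D) table.
    """
    if kT is None:
        kT = thermal_energy()
    if isinstance(w, MembranePMF):
        w_fn = w.value
    elif callable(w):
        w_fn = w
    else:
        zt, wt = w
        zt = np.asarray(zt, dtype=float)
        wt = np.asarray(wt, dtype=float)
        w_fn = lambda z: np.interp(z, zt, wt)  # noqa: E731

    if isinstance(D, (int, float)):
        if D <= 0:
            raise ValueError("diffusivity must be positive")
        d_fn = lambda z: float(D)  # noqa: E731
    elif callable(D):
        d_fn = D
    else:
        zt, dt = D
        zt = np.asarray(zt, dtype=float)
        dt = np.asarray(dt, dtype=float)
        if np.any(dt <= 0):
            raise ValueError("diffusivity must be positive")
        d_fn = lambda z: np.interp(z, zt, dt)  # noqa: E731

    w_ref = 0.0
    if solvent_range is not None:
        lo, hi = solvent_range
        zs = np.linspace(lo, hi, 201)
        samples = [float(w_fn(z)) for z in zs] + [float(w_fn(-z)) for z in zs]
        w_ref = float(np.mean(samples))

    integrand = lambda z: np.exp((float(w_fn(z)) - w_ref) / kT) / float(d_fn(z))  # noqa: E731
    rp_internal, abserr = quad(integrand, bounds[0], bounds[1], limit=200)
    if rp_internal <= 0:
        raise RuntimeError("resistance integral is non-positive; check inputs")
    if abserr > 1e-6 * rp_internal:
        raise RuntimeError(
            f"resistance quadrature not converged: estimated error "
            f"{abserr:.2e} vs integral {rp_internal:.2e}"
        )
    rp_s_per_cm = rp_internal * NS_PER_A_TO_S_PER_CM
    p_cm_per_s = (1.0 / rp_internal) * A_PER_NS_TO_CM_PER_S
    return rp_s_per_cm, p_cm_per_s


def henry_concentration(
    partial_pressure: float,
    H: float = 4.7521e9,
    water_molarity: float = 55.34,
) -> float:
    """Dissolved-gas molarity from Henry's law, mol/L.

    The mole fraction x = p/H (H in Pa, vapor-pressure form) is converted
    to molarity with the molar concentration of water. The default H is
    that of O2 near ambient temperature; 0.21 atm of O2 gives ≈ 2.5e-4
    mol/L (250 μM).
    """
    if H <= 0:
        raise ValueError("Henry constant must be positive")
    if partial_pressure < 0:
        raise ValueError("partial pressure must be non-negative")
    if partial_pressure > H:
        raise ValueError(
            f"partial pressure {partial_pressure} Pa exceeds H={H} Pa "
            "(mole fraction > 1)"
        )
    return partial_pressure / H * water_molarity


def atm(p_atm: float) -> float:
    """Convenience: pressure in atmospheres to Pa."""
    return p_atm * ATM_TO_PA


def normalized_flow_rate(flow_rate: float, n_permeants: int) -> float:
    """Flow rate per permeant molecule (same time window as the input)."""
    if n_permeants <= 0:
        raise ValueError("permeant count must be positive")
    return flow_rate / n_permeants
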