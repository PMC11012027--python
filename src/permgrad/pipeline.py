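"""End-to-end gradient experiment: simulate, profile, count, combine.

A :class:`RunConfig` bundles the box geometry, bias ramp, membrane PMF,
Brownian-dynamics parameters, and analysis settings; :func:`run_pipeline`
chains simulation → concentration profiling → flow counting → area →
permeability → dissipation, writes every intermediate as TSV, and emits a
machine-readable summary. Runs are fully reproducible from (config, seed).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import yaml

from . import units
from .analysis import area_series, concentration_profile, count_flow, delta_c
from .bdsim import BDParams, MembranePMF, simulate
from .gridpot import RampSpec, build_ramp
from .permeability import dissipation_profile, permeability

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; partial outputs are retained on disk."""

    def __init__(self, stage: str, original: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {original}")
        self.stage = stage
        self.original = original


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce a gradient experiment.

    Defaults describe the reference setup: a 100×100×220 Å box with an
    unbiased core from -90 to +90 Å, a 1 kcal/mol energy step between
    periodic images, 1-Å concentration slabs, Δc read at z = ±30 Å, and
    flow counted at z = 0 with 40-Å counting regions. The Brownian
    surrogate runs 200 ns of 500 particles at D = 800 Å²/ns with 20-ns
    error blocks — box-scale relaxation takes only a few ns at this
    diffusivity, so 10 blocks are comfortably independent.
    """

    ramp: RampSpec = field(default_factory=lambda: RampSpec(220.0, 90.0, 1.0, 1.0))
    bd: BDParams = field(
        default_factory=lambda: BDParams(
            n_particles=500, n_steps=200_000, dt=0.001, save_every=50,
            init="steady_state",
        )
    )
    pmf: MembranePMF = field(default_factory=MembranePMF.bilayer_default)
    bin_width: float = 1.0
    block_size: float = 20.0
    z_plus: float = 30.0
    z_minus: float = -30.0
    region_half_width: float = 40.0
    temperature: float = units.DEFAULT_TEMPERATURE_K
    run_control: bool = True
    write_trajectories: bool = False

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["pmf"] = {"components": [list(c) for c in self.pmf.components]}
        d["bd"]["box"] = list(self.bd.box)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "ramp" in d:
            d["ramp"] = RampSpec(**d["ramp"])
        if "bd" in d:
            bd = dict(d["bd"])
            if "box" in bd:
                bd["box"] = tuple(bd["box"])
            d["bd"] = BDParams(**bd)
        if "pmf" in d:
            comps = d["pmf"].get("components", [])
            d["pmf"] = MembranePMF(components=tuple(tuple(c) for c in comps))
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: RunConfig, outdir, seed: int | None = None) -> dict:
    """Run the full gradient experiment and write results under ``outdir``.

    Returns the summary dict (also written to ``summary.yaml``). Any
    stage failure raises :class:`PipelineError` naming the stage; outputs
    of completed stages remain on disk.
    """
    os.makedirs(outdir, exist_ok=True)
    kT = units.thermal_energy(config.temperature)
    bd = dataclasses.replace(
        config.bd, kT=kT, seed=config.bd.seed if seed is None else seed
    )
    from . import __version__

    log.info(
        "pipeline start: version=%s seed=%s config_hash=%s", __version__, bd.seed,
        config.config_hash(),
    )
    for name, value in units.constant_table().items():
        log.info("constant %s = %r", name, value)

    stage = "build_ramp"
    try:
        bias = build_ramp(config.ramp)

        stage = "simulate_gradient"
        traj = simulate(bd, config.pmf, bias)
        if config.write_trajectories:
            traj.to_tsv(os.path.join(outdir, "traj_gradient.tsv"))

        stage = "concentration_profile"
        prof = concentration_profile(traj, config.bin_width, config.block_size)
        prof.to_tsv(os.path.join(outdir, "profile_gradient.tsv"))

        stage = "count_flow"
        flow = count_flow(traj, 0.0, config.region_half_width)
        flow.to_tsv(os.path.join(outdir, "flow.tsv"))

        stage = "area_series"
        area = area_series(traj, config.block_size)
        area.to_tsv(os.path.join(outdir, "area.tsv"))

        stage = "permeability"
        dc = delta_c(prof, config.z_plus, config.z_minus, config.ramp.core_half_width)
        result = permeability(flow, area, dc, config.block_size)

        dissipation = None
        if config.run_control:
            stage = "simulate_control"
            ramp0 = dataclasses.replace(config.ramp, energy_step=0.0)
            bd_ctrl = dataclasses.replace(bd, seed=bd.seed + 1, init="equilibrium")
            traj_ctrl = simulate(bd_ctrl, config.pmf, build_ramp(ramp0))
            if config.write_trajectories:
                traj_ctrl.to_tsv(os.path.join(outdir, "traj_control.tsv"))

            stage = "dissipation_profile"
            prof_ctrl = concentration_profile(traj_ctrl, config.bin_width, config.block_size)
            prof_ctrl.to_tsv(os.path.join(outdir, "profile_control.tsv"))
            dissipation = dissipation_profile(prof, prof_ctrl, kT)
            _write_dissipation(dissipation, os.path.join(outdir, "dissipation.tsv"))
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    summary = {
        "version": __version__,
        "seed": int(bd.seed),
        "config_hash": config.config_hash(),
        "constants": {k: float(v) for k, v in units.constant_table().items()},
        "permeability": result.summary(),
        "flow_rate_per_100ns": flow.rate(100.0),
        "n_wraps": int(traj.meta.get("n_wraps", 0)),
        "n_skipped_jumps": int(flow.n_skipped),
    }
    with open(os.path.join(outdir, "summary.yaml"), "w") as fh:
        yaml.safe_dump(_plain(summary), fh, sort_keys=True)
    config.to_yaml(os.path.join(outdir, "config.yaml"))
    return summary


def _plain(obj):
    """Recursively convert numpy scalars for clean YAML output."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def _write_dissipation(d, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# kT_kcal_mol\t{float(d.kT)!r}\n")
        fh.write("z_lo\tz_hi\tddG_kcal_mol\tdefined\n")
        for i in range(len(d.ddG)):
            fh.write(
                f"{float(d.bin_edges[i])!r}\t{float(d.bin_edges[i + 1])!r}\t"
                f"{float(d.ddG[i])!r}\t{int(d.mask[i])}\n"
            )
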