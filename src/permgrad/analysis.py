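"""Trajectory analysis: concentration profiles, flow counting, block errors.

Three measurables feed the permeability calculation:

* time-averaged permeant concentrations in thin slabs along z
  (:func:`concentration_profile`), from which the concentration difference
  across the membrane is read (:func:`delta_c`);
* the accumulated flow through a boundary plane, counted by the
  four-region algorithm that is robust to periodic-boundary wraps
  (:func:`count_flow`);
* the lateral membrane area per frame (:func:`area_series`).

All standard errors use block averaging: frames inside a block are
averaged first and the block means are treated as independent samples,
because consecutive frames are strongly autocorrelated and a naive
SD/sqrt(N_frames) would understate the error.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .trajectory import Trajectory
from .units import PER_A3_TO_MMOL_PER_L

__all__ = [
    "BlockStats",
    "SlabProfile",
    "FlowCount",
    "DeltaC",
    "block_average",
    "concentration_profile",
    "count_flow",
    "area_series",
    "delta_c",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class BlockStats:
    """Block-averaged statistics of a scalar time series."""

    block_size: float  # ns
    block_values: np.ndarray
    mean: float
    stderr: float

    @property
    def n_blocks(self) -> int:
        return len(self.block_values)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# block_size_ns\t{self.block_size}\n")
            fh.write(f"# mean\t{float(self.mean)!r}\n# stderr\t{float(self.stderr)!r}\n")
            fh.write("block\tvalue\n")
            for i, v in enumerate(self.block_values):
                fh.write(f"{i}\t{float(v)!r}\n")

    @classmethod
    def from_tsv(cls, path) -> "BlockStats":
        meta = _read_meta(path)
        df = pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip")
        values = df["value"].to_numpy()
        return _stats_from_blocks(values, float(meta["block_size_ns"]))


def _read_meta(path) -> dict[str, str]:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, val = line[1:].strip().partition("\t")
            meta[key.strip()] = val.strip()
    return meta


def _stats_from_blocks(block_values: np.ndarray, block_size: float) -> BlockStats:
    block_values = np.asarray(block_values, dtype=float)
    n = len(block_values)
    if n < 2:
        raise ValueError(f"need at least 2 complete blocks for an error estimate, got {n}")
    return BlockStats(
        block_size=block_size,
        block_values=block_values,
        mean=float(block_values.mean()),
        stderr=float(block_values.std(ddof=1) / np.sqrt(n)),
    )


def _frames_per_block(frame_interval: float, block_size: float) -> int:
    fpb = int(round(block_size / frame_interval))
    if fpb < 1:
        raise ValueError(
            f"block_size {block_size} ns is shorter than the frame interval "
            f"{frame_interval} ns"
        )
    return fpb


def block_average(
    values,
    block_size: float,
    frame_interval: float | None = None,
    times=None,
) -> BlockStats:
    """Block-average a uniformly sampled scalar series.

    ``frame_interval`` (ns between samples) or explicit sample ``times``
    must be given. The incomplete trailing block is dropped; fewer than
    two complete blocks is an error (no error estimate is possible).
    """
    values = np.asarray(values, dtype=float)
    if frame_interval is None:
        if times is None:
            raise ValueError("provide frame_interval or times")
        times = np.asarray(times, dtype=float)
        if len(times) < 2:
            raise ValueError("need at least two samples")
        frame_interval = float(times[1] - times[0])
    fpb = _frames_per_block(frame_interval, block_size)
    n_blocks = len(values) // fpb
    if n_blocks < 2:
        raise ValueError(
            f"series of {len(values)} samples at {frame_interval} ns covers "
            f"fewer than 2 complete {block_size} ns blocks"
        )
    trimmed = values[: n_blocks * fpb].reshape(n_blocks, fpb)
    return _stats_from_blocks(trimmed.mean(axis=1), block_size)


@dataclass(frozen=True)
class SlabProfile:
    """Binned, time-averaged concentration profile along z.

    Concentrations are in mmol/L; errors are block-averaged standard
    errors of the per-block time averages.
    """

    bin_edges: np.ndarray  # (B+1,)
    mean_concentration: np.ndarray  # (B,)
    stderr: np.ndarray  # (B,)
    block_means: np.ndarray  # (n_blocks, B)
    block_size: float  # ns
    mean_area: float  # Å², lateral box area used for slab volumes

    @property
    def n_blocks(self) -> int:
        return self.block_means.shape[0]

    @property
    def bin_centers(self) -> np.ndarray:
        return (self.bin_edges[:-1] + self.bin_edges[1:]) / 2

    def bin_index(self, z: float) -> int:
        """Index of the slab containing z (half-open [lo, hi) bins)."""
        if not (self.bin_edges[0] <= z < self.bin_edges[-1]):
            raise ValueError(f"z={z} outside profiled range "
                             f"[{self.bin_edges[0]}, {self.bin_edges[-1]})")
        return int(np.searchsorted(self.bin_edges, z, side="right") - 1)

    def concentration_at(self, z: float) -> tuple[float, float]:
        """(mean, stderr) of the slab containing z, mmol/L."""
        i = self.bin_index(z)
        return float(self.mean_concentration[i]), float(self.stderr[i])

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# block_size_ns\t{self.block_size}\n")
            fh.write(f"# mean_area_A2\t{self.mean_area!r}\n")
            fh.write(f"# n_blocks\t{self.n_blocks}\n")
            cols = "\t".join(f"block_{b}" for b in range(self.n_blocks))
            fh.write(f"z_lo\tz_hi\tconc_mmol_L\tstderr\t{cols}\n")
            for i in range(len(self.mean_concentration)):
                blocks = "\t".join(repr(float(v)) for v in self.block_means[:, i])
                fh.write(
                    f"{float(self.bin_edges[i])!r}\t{float(self.bin_edges[i + 1])!r}\t"
                    f"{float(self.mean_concentration[i])!r}\t{float(self.stderr[i])!r}\t{blocks}\n"
                )

    @classmethod
    def from_tsv(cls, path) -> "SlabProfile":
        meta = _read_meta(path)
        df = pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip")
        block_cols = [c for c in df.columns if c.startswith("block_")]
        edges = np.append(df["z_lo"].to_numpy(), df["z_hi"].to_numpy()[-1])
        return cls(
            bin_edges=edges,
            mean_concentration=df["conc_mmol_L"].to_numpy(),
            stderr=df["stderr"].to_numpy(),
            block_means=df[block_cols].to_numpy().T,
            block_size=float(meta["block_size_ns"]),
            mean_area=float(meta["mean_area_A2"]),
        )


def concentration_profile(
    traj: Trajectory,
    bin_width: float = 1.0,
    block_size: float = 100.0,
) -> SlabProfile:
    """Time-averaged slab concentrations along z with block errors.

    Per frame, particles are histogrammed into slabs of ``bin_width`` Å;
    counts are divided by the slab volume Lx·Ly·bin_width and converted
    to mmol/L. If ``bin_width`` does not divide the box length the last
    slab is truncated (its smaller volume is accounted for) and a warning
    is logged. Summing mean concentration times slab volume over all
    slabs recovers the average particle count per frame exactly.
    """
    lz = traj.lz
    n_bins = int(np.ceil(lz / bin_width - 1e-9))
    edges = -lz / 2 + bin_width * np.arange(n_bins + 1)
    if edges[-1] > lz / 2 + 1e-9:
        edges[-1] = lz / 2
        log.warning(
            "bin_width %.4g does not divide Lz=%.4g; last slab truncated to %.4g Å",
            bin_width, lz, edges[-1] - edges[-2],
        )
    widths = np.diff(edges)

    fpb = _frames_per_block(traj.frame_interval, block_size)
    n_blocks = traj.n_frames // fpb
    if n_blocks < 2:
        raise ValueError(
            f"{traj.n_frames} frames at {traj.frame_interval} ns cover fewer "
            f"than 2 complete {block_size} ns blocks"
        )

    areas = traj.box_xy[:, 0] * traj.box_xy[:, 1]
    block_means = np.empty((n_blocks, n_bins))
    for b in range(n_blocks):
        sl = slice(b * fpb, (b + 1) * fpb)
        counts, _ = np.histogram(traj.z[sl].ravel(), bins=edges)
        volume = float(areas[sl].mean()) * widths
        block_means[b] = counts / fpb / volume * PER_A3_TO_MMOL_PER_L
    mean = block_means.mean(axis=0)
    stderr = (
        block_means.std(axis=0, ddof=1) / np.sqrt(n_blocks)
        if n_blocks > 1
        else np.zeros(n_bins)
    )
    return SlabProfile(
        bin_edges=edges,
        mean_concentration=mean,
        stderr=stderr,
        block_means=block_means,
        block_size=block_size,
        mean_area=float(areas[: n_blocks * fpb].mean()),
    )


@dataclass(frozen=True)
class FlowCount:
    """Accumulated signed crossings of a boundary plane over time.

    The sign convention is the boundary normal +z: a crossing from the
    region below the boundary to the region above contributes +1.
    """

    frame_times: np.ndarray  # (F,)
    increments: np.ndarray  # (F-1,) net increment per frame pair
    boundary_z: float
    region_half_width: float
    n_skipped: int = 0  # multi-region jumps, counted but contributing 0
    meta: dict = field(default_factory=dict)

    @property
    def accumulated(self) -> np.ndarray:
        """Running accumulated flow, one value per frame (starts at 0)."""
        return np.concatenate([[0.0], np.cumsum(self.increments)])

    @property
    def total(self) -> float:
        return float(self.increments.sum())

    @property
    def frame_interval(self) -> float:
        return float(self.frame_times[1] - self.frame_times[0])

    def rate(self, per: float = 100.0) -> float:
        """Mean flow rate in crossings per ``per`` ns."""
        span = self.frame_times[-1] - self.frame_times[0]
        return self.total / span * per

    def block_flows(self, block_size: float) -> BlockStats:
        """Net flow per block (crossings per block of ``block_size`` ns)."""
        fpb = _frames_per_block(self.frame_interval, block_size)
        n_blocks = len(self.increments) // fpb
        if n_blocks < 2:
            raise ValueError("fewer than 2 complete blocks of flow data")
        sums = self.increments[: n_blocks * fpb].reshape(n_blocks, fpb).sum(axis=1)
        return _stats_from_blocks(sums, block_size)

    def to_tsv(self, path) -> None:
        acc = self.accumulated
        with open(path, "w") as fh:
            fh.write(f"# boundary_z\t{self.boundary_z}\n")
            fh.write(f"# region_half_width\t{self.region_half_width}\n")
            fh.write(f"# n_skipped\t{self.n_skipped}\n")
            fh.write("frame_time_ns\taccumulated_flow\n")
            for t, a in zip(self.frame_times, acc):
                fh.write(f"{float(t)!r}\t{float(a)!r}\n")

    @classmethod
    def from_tsv(cls, path) -> "FlowCount":
        meta = _read_meta(path)
        df = pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip")
        acc = df["accumulated_flow"].to_numpy()
        return cls(
            frame_times=df["frame_time_ns"].to_numpy(),
            increments=np.diff(acc),
            boundary_z=float(meta["boundary_z"]),
            region_half_width=float(meta["region_half_width"]),
            n_skipped=int(meta.get("n_skipped", 0)),
        )


def count_flow(
    traj: Trajectory,
    boundary_z: float = 0.0,
    region_half_width: float = 40.0,
) -> FlowCount:
    """Count net crossings of the plane ``boundary_z`` by the four-region rule.

    The box is split into region III = [B-h, B), region II = [B, B+h)
    (h = ``region_half_width``), and two flank regions I (below III) and
    IV (above II) that absorb periodic-boundary wraps. Per consecutive
    frame pair, a particle moving III→II contributes +1, II→III
    contributes -1, and every other move — including wraps between the
    flanks and multi-region jumps — contributes 0. Region intervals are
    half-open, lower-inclusive. Multi-region jumps (I↔II, III↔IV) are
    tallied in ``n_skipped`` as a diagnostic for undersaved trajectories.
    """
    lz = traj.lz
    b, h = boundary_z, region_half_width
    if h <= 0:
        raise ValueError("region_half_width must be positive")
    if b + h >= lz / 2 or b - h <= -lz / 2:
        raise ValueError(
            f"regions II/III of half-width {h} Å around z={b} leave no flank "
            f"regions in a {lz} Å box; shrink region_half_width"
        )
    # region codes in z order: 0 = I, 1 = III, 2 = II, 3 = IV
    codes = np.digitize(traj.z, [b - h, b, b + h])
    prev, cur = codes[:-1], codes[1:]
    plus = (prev == 1) & (cur == 2)
    minus = (prev == 2) & (cur == 1)
    increments = plus.sum(axis=1).astype(float) - minus.sum(axis=1)
    skipped = int((((prev == 0) & (cur == 2)) | ((prev == 2) & (cur == 0))
                   | ((prev == 1) & (cur == 3)) | ((prev == 3) & (cur == 1))).sum())
    if skipped:
        log.warning(
            "%d multi-region jumps contributed 0 to the flow count; the "
            "trajectory may be undersaved", skipped,
        )
    return FlowCount(
        frame_times=traj.frame_times,
        increments=increments,
        boundary_z=b,
        region_half_width=h,
        n_skipped=skipped,
    )


def area_series(traj: Trajectory, block_size: float = 100.0) -> BlockStats:
    """Block-averaged lateral membrane area Lx·Ly in Å²."""
    bad = np.nonzero(~np.isfinite(traj.box_xy).all(axis=1))[0]
    if bad.size:
        raise ValueError(f"missing box record at frame {bad[0]}")
    areas = traj.box_xy[:, 0] * traj.box_xy[:, 1]
    return block_average(areas, block_size, frame_interval=traj.frame_interval)


@dataclass(frozen=True)
class DeltaC:
    """Concentration difference across the membrane, mmol/L."""

    value: float
    stderr: float
    z_plus: float
    z_minus: float


def delta_c(
    profile: SlabProfile,
    z_plus: float = 30.0,
    z_minus: float = -30.0,
    core_half_width: float | None = None,
) -> DeltaC:
    """Δc = c(z_plus) - c(z_minus) from the slabs containing those points.

    The slab containing each position is used directly (no interpolation),
    matching the slab discretization of the profile. Standard errors of
    the two slabs combine in quadrature. If ``core_half_width`` is given
    and either position lies in the biasing region a warning is logged:
    Δc is meant to bracket the membrane inside the unbiased core.
    """
    if core_half_width is not None and (
        abs(z_plus) > core_half_width or abs(z_minus) > core_half_width
    ):
        log.warning(
            "delta_c positions (%.4g, %.4g) reach into the biasing region "
            "(core half-width %.4g Å)", z_plus, z_minus, core_half_width,
        )
    cp, sp = profile.concentration_at(z_plus)
    cm, sm = profile.concentration_at(z_minus)
    return DeltaC(
        value=cp - cm,
        stderr=float(np.hypot(sp, sm)),
        z_plus=z_plus,
        z_minus=z_minus,
    )
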