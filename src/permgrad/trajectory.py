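"""Trajectory container and plain-text I/O.

Positions are stored wrapped into one period [-Lz/2, +Lz/2) along z, the
membrane normal. Lateral coordinates are optional. The columnar TSV format
(frame_time_ns, particle_id, z[, x, y], Lx, Ly, Lz) is the interchange
format of the whole toolkit; a minimal XYZ importer is provided for
trajectories exported from visualization tools.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["Trajectory", "read_tsv", "read_xyz"]


@dataclass
class Trajectory:
    """Time-ordered per-particle positions in a periodic box.

    Attributes
    ----------
    frame_times : (F,) array, ns
    z : (F, N) array, Å, wrapped into [-Lz/2, +Lz/2)
    box_xy : (F, 2) array, lateral box lengths Lx, Ly per frame, Å
    lz : float, periodic box length along z, Å
    xy : optional (F, N, 2) array of lateral positions, Å
    meta : free-form provenance (seed, parameters, wrap counts)
    """

    frame_times: np.ndarray
    z: np.ndarray
    box_xy: np.ndarray
    lz: float
    xy: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        self.box_xy = np.asarray(self.box_xy, dtype=float)
        if self.z.ndim != 2 or len(self.frame_times) != self.z.shape[0]:
            raise ValueError("z must be (n_frames, n_particles) matching frame_times")
        if self.box_xy.shape != (self.z.shape[0], 2):
            raise ValueError("box_xy must be (n_frames, 2)")
        half = self.lz / 2
        if np.any(self.z < -half) or np.any(self.z >= half):
            raise ValueError("z positions must be wrapped into [-Lz/2, +Lz/2)")

    @property
    def n_frames(self) -> int:
        return self.z.shape[0]

    @property
    def n_particles(self) -> int:
        return self.z.shape[1]

    @property
    def frame_interval(self) -> float:
        """Spacing between saved frames, ns (assumes a uniform clock)."""
        if self.n_frames < 2:
            raise ValueError("frame_interval undefined for a single frame")
        return float(self.frame_times[1] - self.frame_times[0])

    @property
    def total_time(self) -> float:
        return float(self.frame_times[-1] - self.frame_times[0])

    def slice_time(self, t_min: float = -np.inf, t_max: float = np.inf) -> "Trajectory":
        """Sub-trajectory with frame times in [t_min, t_max]."""
        keep = (self.frame_times >= t_min) & (self.frame_times <= t_max)
        return Trajectory(
            frame_times=self.frame_times[keep],
            z=self.z[keep],
            box_xy=self.box_xy[keep],
            lz=self.lz,
            xy=self.xy[keep] if self.xy is not None else None,
            meta=dict(self.meta),
        )

    def to_frame(self) -> pd.DataFrame:
        """Long-format DataFrame in the columnar interchange layout."""
        f, n = self.n_frames, self.n_particles
        data = {
            "frame_time_ns": np.repeat(self.frame_times, n),
            "particle_id": np.tile(np.arange(n), f),
            "z": self.z.ravel(),
        }
        if self.xy is not None:
            data["x"] = self.xy[:, :, 0].ravel()
            data["y"] = self.xy[:, :, 1].ravel()
        data["Lx"] = np.repeat(self.box_xy[:, 0], n)
        data["Ly"] = np.repeat(self.box_xy[:, 1], n)
        data["Lz"] = np.full(f * n, self.lz)
        return pd.DataFrame(data)

    def to_tsv(self, path: str | os.PathLike) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.8g")


def read_tsv(path: str | os.PathLike) -> Trajectory:
    """Read a columnar TSV trajectory written by :meth:`Trajectory.to_tsv`."""
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    required = {"frame_time_ns", "particle_id", "z", "Lx", "Ly", "Lz"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"trajectory file missing columns: {sorted(missing)}")
    times = np.sort(df["frame_time_ns"].unique())
    n = df["particle_id"].nunique()
    df = df.sort_values(["frame_time_ns", "particle_id"])
    if len(df) != len(times) * n:
        raise ValueError("trajectory is ragged: particle count varies between frames")
    z = df["z"].to_numpy().reshape(len(times), n)
    box_xy = df.groupby("frame_time_ns", sort=True)[["Lx", "Ly"]].first().to_numpy()
    xy = None
    if {"x", "y"} <= set(df.columns):
        xy = np.stack(
            [df["x"].to_numpy().reshape(len(times), n), df["y"].to_numpy().reshape(len(times), n)],
            axis=-1,
        )
    lz = float(df["Lz"].iloc[0])
    return Trajectory(frame_times=times, z=z, box_xy=box_xy, lz=lz, xy=xy)


def read_xyz(
    path: str | os.PathLike,
    box: tuple[float, float, float],
    frame_interval: float,
) -> Trajectory:
    """Import a plain XYZ file (fixed particle count, frames concatenated).

    XYZ carries no box or clock information, so the box dimensions and the
    interval between frames must be supplied. The z column (third
    coordinate) is wrapped into the periodic box.
    """
    lx, ly, lz = box
    frames: list[np.ndarray] = []
    with open(path) as fh:
        while True:
            header = fh.readline()
            if not header.strip():
                break
            n = int(header)
            fh.readline()  # comment line
            coords = np.array(
                [fh.readline().split()[1:4] for _ in range(n)], dtype=float
            )
            frames.append(coords)
    if not frames:
        raise ValueError(f"no frames found in {path!r}")
    arr = np.stack(frames)  # (F, N, 3)
    zw = (arr[:, :, 2] + lz / 2) % lz - lz / 2
    f = arr.shape[0]
    return Trajectory(
        frame_times=frame_interval * np.arange(f),
        z=zw,
        box_xy=np.tile([lx, ly], (f, 1)),
        lz=lz,
        xy=arr[:, :, :2],
    )
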