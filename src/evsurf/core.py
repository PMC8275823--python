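"""Shared domain containers: trajectories, neurite axes, video stacks.

Coordinates are continuous micrometres in the image plane; for pixel data
the origin sits at the centre of pixel (0, 0). Times are seconds from the
start of the recording.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "Trajectory",
    "NeuriteAxis",
    "VideoStack",
    "read_trajectory_csv",
    "write_trajectory_csv",
    "read_axis_csv",
    "write_axis_csv",
    "read_video",
    "write_video",
]


@dataclass
class Trajectory:
    """Time-ordered 2D positions of a single EV.

    Parameters
    ----------
    t_s, x_um, y_um:
        Sample times (strictly increasing, seconds) and positions (μm).
    ev_diameter_um:
        EV diameter in μm; the static/mobile rule compares displacement
        against this value. Must be positive.
    contact_point:
        (x, y) in μm where the EV first adhered; defaults to the first
        tracked position. Origin for all displacement metrics.
    x_true_um, y_true_um:
        Optional noise-free coordinates (simulator output only): the
        positions before localization jitter was added.
    """

    t_s: np.ndarray
    x_um: np.ndarray
    y_um: np.ndarray
    ev_diameter_um: float
    contact_point: Optional[tuple[float, float]] = None
    compartment: str = "neurite"
    experiment_id: str = ""
    ev_id: str = "ev0"
    x_true_um: Optional[np.ndarray] = None
    y_true_um: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.t_s = np.asarray(self.t_s, dtype=float)
        self.x_um = np.asarray(self.x_um, dtype=float)
        self.y_um = np.asarray(self.y_um, dtype=float)
        if not (self.t_s.shape == self.x_um.shape == self.y_um.shape):
            raise ValueError("t_s, x_um, y_um must have equal length")
        if self.t_s.size < 2:
            raise ValueError("a trajectory needs at least 2 points")
        if np.any(np.diff(self.t_s) <= 0):
            raise ValueError("times must be strictly increasing")
        if not self.ev_diameter_um > 0:
            raise ValueError("ev_diameter_um must be > 0")
        if self.compartment not in ("neurite", "soma"):
            raise ValueError(f"unknown compartment {self.compartment!r}")
        if self.contact_point is None:
            self.contact_point = (float(self.x_um[0]), float(self.y_um[0]))
        else:
            self.contact_point = (float(self.contact_point[0]),
                                  float(self.contact_point[1]))
        for arr in (self.x_true_um, self.y_true_um):
            if arr is not None and np.asarray(arr).shape != self.t_s.shape:
                raise ValueError("noise-free coordinates must match length")

    @property
    def n_points(self) -> int:
        return int(self.t_s.size)

    @property
    def duration_s(self) -> float:
        return float(self.t_s[-1] - self.t_s[0])

    def positions(self) -> np.ndarray:
        """(n, 2) array of positions in μm."""
        return np.column_stack([self.x_um, self.y_um])

    def select(self, idx: np.ndarray) -> "Trajectory":
        """Sub-trajectory at integer indices ``idx`` (metadata preserved)."""
        return Trajectory(
            t_s=self.t_s[idx],
            x_um=self.x_um[idx],
            y_um=self.y_um[idx],
            ev_diameter_um=self.ev_diameter_um,
            contact_point=self.contact_point,
            compartment=self.compartment,
            experiment_id=self.experiment_id,
            ev_id=self.ev_id,
            x_true_um=None if self.x_true_um is None else self.x_true_um[idx],
            y_true_um=None if self.y_true_um is None else self.y_true_um[idx],
        )


@dataclass
class NeuriteAxis:
    """Oriented polyline tracing a neurite, with a marked soma end.

    ``soma_end`` says which end of the vertex list touches the cell body;
    anterograde motion moves away from that end.
    """

    vertices: np.ndarray
    soma_end: str = "first_vertex"

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise ValueError("vertices must be an (n, 2) array")
        if self.vertices.shape[0] < 2:
            raise ValueError("axis needs at least 2 vertices")
        seg = np.linalg.norm(np.diff(self.vertices, axis=0), axis=1)
        if np.any(seg <= 0):
            raise ValueError("zero-length axis segment")
        if self.soma_end not in ("first_vertex", "last_vertex"):
            raise ValueError(f"invalid soma_end {self.soma_end!r}")
        self._cumlen = np.concatenate([[0.0], np.cumsum(seg)])

    @property
    def arc_length_um(self) -> float:
        return float(self._cumlen[-1])

    def point_at(self, s: np.ndarray) -> np.ndarray:
        """Interpolate (x, y) at arc length ``s`` (clipped to the axis)."""
        s = np.clip(np.atleast_1d(np.asarray(s, dtype=float)),
                    0.0, self.arc_length_um)
        x = np.interp(s, self._cumlen, self.vertices[:, 0])
        y = np.interp(s, self._cumlen, self.vertices[:, 1])
        return np.column_stack([x, y])


@dataclass
class VideoStack:
    """Sequence of equally shaped intensity frames with physical metadata."""

    frames: np.ndarray
    frame_interval_s: float
    pixel_size_um: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (t, h, w) array")
        if self.frames.shape[0] < 2:
            raise ValueError("a video needs at least 2 frames")
        if np.any(self.frames < 0):
            raise ValueError("intensities must be non-negative")
        if self.frame_interval_s <= 0 or self.pixel_size_um <= 0:
            raise ValueError("frame_interval_s and pixel_size_um must be > 0")

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])


# ---------------------------------------------------------------------------
# File formats
# ---------------------------------------------------------------------------

def write_trajectory_csv(trajs: Trajectory | Sequence[Trajectory],
                         path: str | Path) -> None:
    """Write trajectories as CSV (ev_id, frame, t_s, x_um, y_um)."""
    if isinstance(trajs, Trajectory):
        trajs = [trajs]
    rows = []
    for tr in trajs:
        rows.append(pd.DataFrame({
            "ev_id": tr.ev_id,
            "frame": np.arange(tr.n_points),
            "t_s": tr.t_s,
            "x_um": tr.x_um,
            "y_um": tr.y_um,
        }))
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)


def read_trajectory_csv(path: str | Path,
                        ev_diameter_um: float = 0.5,
                        **kwargs) -> list[Trajectory]:
    """Read a trajectory CSV; one Trajectory per distinct ev_id."""
    df = pd.read_csv(path)
    required = {"ev_id", "frame", "t_s", "x_um", "y_um"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"trajectory CSV missing columns {sorted(missing)}")
    out = []
    for ev_id, grp in df.groupby("ev_id", sort=False):
        grp = grp.sort_values("t_s")
        out.append(Trajectory(
            t_s=grp["t_s"].to_numpy(),
            x_um=grp["x_um"].to_numpy(),
            y_um=grp["y_um"].to_numpy(),
            ev_diameter_um=ev_diameter_um,
            ev_id=str(ev_id),
            **kwargs,
        ))
    return out


def write_axis_csv(axis: NeuriteAxis, path: str | Path) -> None:
    """Polyline CSV with the soma end recorded in a header comment."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# soma_end={axis.soma_end}\n")
        fh.write("vertex_index,x_um,y_um\n")
        for i, (x, y) in enumerate(axis.vertices):
            fh.write(f"{i},{float(x)!r},{float(y)!r}\n")


def read_axis_csv(path: str | Path) -> NeuriteAxis:
    path = Path(path)
    soma_end = "first_vertex"
    with open(path, encoding="utf-8") as fh:
        first = fh.readline().strip()
        if first.startswith("#") and "soma_end=" in first:
            soma_end = first.split("soma_end=")[1].strip()
    df = pd.read_csv(path, comment="#")
    df = df.sort_values("vertex_index")
    return NeuriteAxis(df[["x_um", "y_um"]].to_numpy(), soma_end=soma_end)


def write_video(video: VideoStack, path: str | Path) -> None:
    """Multi-page TIFF plus a JSON metadata sidecar (<path>.json)."""
    path = Path(path)
    tifffile.imwrite(path, np.asarray(video.frames),
                     photometric="minisblack")
    meta = {"pixel_size_um": video.pixel_size_um,
            "frame_interval_s": video.frame_interval_s}
    Path(str(path) + ".json").write_text(json.dumps(meta), encoding="utf-8")


def read_video(path: str | Path) -> VideoStack:
    path = Path(path)
    frames = tifffile.imread(path)
    sidecar = Path(str(path) + ".json")
    if not sidecar.exists():
        raise FileNotFoundError(f"metadata sidecar {sidecar} not found")
    meta = json.loads(sidecar.read_text(encoding="utf-8"))
    return VideoStack(frames=frames,
                      frame_interval_s=float(meta["frame_interval_s"]),
                      pixel_size_um=float(meta["pixel_size_um"]))
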