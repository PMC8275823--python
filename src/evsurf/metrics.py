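"""Per-EV motion metrics.

All headline metrics are computed on the trajectory resampled at the
analysis interval (2.5 s by default): point-to-point path length, signed
excursions along the neurite axis, mean speed over the whole recording,
stop-and-go segmentation and the fraction of time in motion, and the
time-averaged radial displacement from the contact point.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from shapely.geometry import LineString, Point

from .core import NeuriteAxis, Trajectory

__all__ = [
    "SignedPositionSeries",
    "MotionMetrics",
    "DEFAULT_ANALYSIS_INTERVAL_S",
    "DEFAULT_MOTION_EPS_UM",
    "resample",
    "path_length",
    "project_onto_axis",
    "excursions",
    "stop_go",
    "mean_speed",
    "radial_displacement",
    "compute_metrics",
]

DEFAULT_ANALYSIS_INTERVAL_S = 2.5

# "go" threshold on the 2D displacement per analysis interval: 2x the RMS
# displacement noise sqrt(2) * sqrt(2) * sigma_loc with the default 0.05 um
# localization sigma. Below this, interval displacements are jitter.
DEFAULT_MOTION_EPS_UM = 0.2

DEFAULT_CAPTURE_DISTANCE_UM = 3.0


@dataclass
class SignedPositionSeries:
    """Arc-length position along a neurite axis over time.

    Positive values lie on the anterograde side (away from the soma);
    zero is the projection of the contact point.
    """

    t_s: np.ndarray
    s_um: np.ndarray

    def __post_init__(self) -> None:
        self.t_s = np.asarray(self.t_s, dtype=float)
        self.s_um = np.asarray(self.s_um, dtype=float)
        if self.t_s.shape != self.s_um.shape:
            raise ValueError("t_s and s_um must have equal length")
        if np.any(np.diff(self.t_s) <= 0):
            raise ValueError("times must be strictly increasing")


@dataclass
class MotionMetrics:
    """Motion metrics of a single EV at the analysis sampling."""

    path_length_um: float
    max_dist_pos_um: float
    max_dist_neg_um: float
    max_dist_contact_um: float
    mean_speed_um_s: float
    fraction_time_moving: float
    stop_go_segments: list = field(default_factory=list)
    radial_displacement_um: float = 0.0
    run_length_pos_um: float = float("nan")
    run_length_neg_um: float = float("nan")


def resample(traj: Trajectory,
             interval_s: float = DEFAULT_ANALYSIS_INTERVAL_S) -> Trajectory:
    """Keep the sample nearest each multiple of ``interval_s``.

    The first and last samples are always kept. Raises when the requested
    interval is finer than the native frame spacing.
    """
    t = traj.t_s - traj.t_s[0]
    native = float(np.min(np.diff(t)))
    if interval_s < native - 1e-9:
        raise ValueError(
            f"interval {interval_s} s finer than native spacing {native} s")
    targets = np.arange(0.0, t[-1] + interval_s / 2, interval_s)
    # nearest sample to each target (ties -> earlier sample)
    right = np.searchsorted(t, targets)
    left = np.clip(right - 1, 0, t.size - 1)
    right = np.clip(right, 0, t.size - 1)
    pick = np.where(np.abs(t[left] - targets) <= np.abs(t[right] - targets),
                    left, right)
    idx = np.unique(np.concatenate([[0], pick, [t.size - 1]]))
    return traj.select(idx)


def path_length(traj: Trajectory) -> float:
    """Point-to-point (Pythagorean) path length in um."""
    d = np.hypot(np.diff(traj.x_um), np.diff(traj.y_um))
    return float(d.sum())


def project_onto_axis(
    traj: Trajectory,
    axis: NeuriteAxis,
    capture_distance_um: float = DEFAULT_CAPTURE_DISTANCE_UM,
) -> SignedPositionSeries:
    """Map each position to signed arc length along the neurite axis.

    Each point goes to the arc length of its nearest point on the
    polyline, re-zeroed at the contact point's projection; the sign makes
    motion away from the soma end positive. Points farther than
    ``capture_distance_um`` from the axis raise, listing the offending
    times.
    """
    line = LineString(axis.vertices)
    pts = [Point(xy) for xy in traj.positions()]
    dists = np.array([line.distance(p) for p in pts])
    far = dists > capture_distance_um
    if np.any(far):
        times = ", ".join(f"{tt:.3g}" for tt in traj.t_s[far][:10])
        raise ValueError(
            f"{int(far.sum())} point(s) beyond the {capture_distance_um} um "
            f"capture distance from the axis (t_s = {times} ...)")
    s_raw = np.array([line.project(p) for p in pts])
    s_contact = line.project(Point(traj.contact_point))
    orient = 1.0 if axis.soma_end == "first_vertex" else -1.0
    s = orient * (s_raw - s_contact)
    s[0] = 0.0 if abs(s[0]) < 1e-9 else s[0]
    return SignedPositionSeries(t_s=traj.t_s, s_um=s)


def excursions(series: SignedPositionSeries
               ) -> tuple[float, float, float, float]:
    """Maximal signed excursions and directional run lengths.

    Returns (max_dist_pos_um, max_dist_neg_um, run_length_pos_um,
    run_length_neg_um): the farthest the EV reached on the anterograde
    and retrograde sides of the contact point, and the cumulative path
    travelled in each direction.
    """
    s = series.s_um
    if s.size < 2:
        raise ValueError("need at least 2 samples")
    ds = np.diff(s)
    max_pos = float(max(s.max(), 0.0))
    max_neg = float(max(-s.min(), 0.0))
    run_pos = float(ds[ds > 0].sum())
    run_neg = float(-ds[ds < 0].sum())
    return max_pos, max_neg, run_pos, run_neg


def stop_go(series: Optional[SignedPositionSeries], traj: Trajectory,
            motion_eps_um: float = DEFAULT_MOTION_EPS_UM
            ) -> tuple[list[tuple[float, float, str]], float]:
    """Segment the record into alternating stop/go intervals.

    An analysis interval is "go" iff the 2D displacement across it
    exceeds ``motion_eps_um``; adjacent same-state intervals are merged.
    Returns the segments (t_start, t_end, state) partitioning the record
    and the fraction of time in motion. ``series`` is accepted so callers
    holding a signed series keep the same timeline; the displacement test
    itself is 2D.
    """
    t = traj.t_s
    disp = np.hypot(np.diff(traj.x_um), np.diff(traj.y_um))
    go = disp > motion_eps_um

    segments: list[tuple[float, float, str]] = []
    start = t[0]
    for i in range(1, go.size):
        if go[i] != go[i - 1]:
            segments.append((float(start), float(t[i]),
                             "go" if go[i - 1] else "stop"))
            start = t[i]
    segments.append((float(start), float(t[-1]), "go" if go[-1] else "stop"))

    go_time = float(np.sum((t[1:] - t[:-1])[go]))
    total = float(t[-1] - t[0])
    return segments, go_time / total


def mean_speed(traj: Trajectory,
               interval_s: Optional[float] = DEFAULT_ANALYSIS_INTERVAL_S
               ) -> float:
    """Path length at the analysis sampling over total recording time.

    The denominator is the whole recording, not only the moving time:
    this is the reading under which a mean run length of 143 um per
    20 min (0.119 um/s) is consistent with a mean speed of 0.126 um/s.
    Pass ``interval_s=None`` to skip resampling.
    """
    rs = traj if interval_s is None else resample(traj, interval_s)
    return path_length(rs) / rs.duration_s


def radial_displacement(traj: Trajectory) -> float:
    """Time-averaged Euclidean distance from the contact point, in um."""
    cx, cy = traj.contact_point
    r = np.hypot(traj.x_um - cx, traj.y_um - cy)
    return float(r.mean())


def compute_metrics(
    traj: Trajectory,
    axis: Optional[NeuriteAxis] = None,
    interval_s: Optional[float] = DEFAULT_ANALYSIS_INTERVAL_S,
    motion_eps_um: float = DEFAULT_MOTION_EPS_UM,
    capture_distance_um: float = DEFAULT_CAPTURE_DISTANCE_UM,
) -> MotionMetrics:
    """All per-EV metrics at the analysis sampling.

    With an axis the signed arc-length excursions are authoritative for
    the maximal distance from the contact point; without one, the 2D
    distance from the contact point is used and run lengths are NaN.
    ``interval_s=None`` computes native-rate metrics.
    """
    rs = traj if interval_s is None else resample(traj, interval_s)
    plen = path_length(rs)
    cx, cy = rs.contact_point
    r = np.hypot(rs.x_um - cx, rs.y_um - cy)

    if axis is not None:
        series = project_onto_axis(rs, axis, capture_distance_um)
        max_pos, max_neg, run_pos, run_neg = excursions(series)
        max_contact = max(max_pos, max_neg)
    else:
        series = None
        max_pos = max_neg = run_pos = run_neg = float("nan")
        max_contact = float(r.max())

    segments, frac = stop_go(series, rs, motion_eps_um)
    return MotionMetrics(
        path_length_um=plen,
        max_dist_pos_um=max_pos,
        max_dist_neg_um=max_neg,
        max_dist_contact_um=max_contact,
        mean_speed_um_s=plen / rs.duration_s,
        fraction_time_moving=frac,
        stop_go_segments=segments,
        radial_displacement_um=radial_displacement(rs),
        run_length_pos_um=run_pos,
        run_length_neg_um=run_neg,
    )
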