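"""Motion classification rules.

Mobility: an EV is static when its maximal distance from the contact
point stays below its own diameter (virtually immobile) or when it moved
farther but only diffusively (tethered Brownian), detected by the MSD
scaling exponent. Otherwise it is mobile.

Direction: a mobile EV is anterograde or retrograde when the run length
in one direction exceeds twice the run length in the other; otherwise it
is bidirectional.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .core import NeuriteAxis, Trajectory
from .metrics import (DEFAULT_ANALYSIS_INTERVAL_S, DEFAULT_MOTION_EPS_UM,
                      MotionMetrics, compute_metrics, resample)

__all__ = [
    "MotionLabels",
    "DEFAULT_ALPHA_STAR",
    "DEFAULT_RUN_RATIO",
    "msd_exponent",
    "classify_mobility",
    "classify_direction",
    "classify_trajectory",
]

# MSD-exponent boundary between diffusive (tethered Brownian) and
# directed motion. Pure diffusion gives alpha <= 1, the ballistic runs of
# a stop-and-go EV push alpha towards 2; 1.3 splits the two with margin.
DEFAULT_ALPHA_STAR = 1.3

# "run length > 2 x length in the opposite direction" rule
DEFAULT_RUN_RATIO = 2.0


@dataclass
class MotionLabels:
    """Mobility and direction calls for one EV, with the rule trace."""

    mobility: str
    direction: str
    msd_alpha: float
    decision_trace: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if (self.direction == "undefined") != (self.mobility != "mobile"):
            raise ValueError("direction is undefined iff EV is not mobile")


def msd_exponent(traj: Trajectory, max_lag_fraction: float = 0.25) -> float:
    """Anomalous-diffusion exponent from the time-averaged MSD.

    MSD(k dt) is averaged over all start frames for lags up to
    ``max_lag_fraction`` of the record; alpha is the least-squares slope
    of log MSD against log lag, fitted on log-spaced lags so every
    decade of lag carries equal weight (linear lag spacing would crowd
    the fit at the longest lags). A zero-variance (degenerate)
    trajectory returns alpha = 0. The trajectory is expected at the
    analysis sampling with >= 20 points.
    """
    if not 0 < max_lag_fraction <= 1:
        raise ValueError("max_lag_fraction must lie in (0, 1]")
    n = traj.n_points
    if n < 20:
        raise ValueError("need >= 20 resampled points for an MSD fit")
    xy = traj.positions()
    if np.ptp(xy[:, 0]) == 0 and np.ptp(xy[:, 1]) == 0:
        return 0.0
    max_lag = max(2, int(np.floor(max_lag_fraction * n)))
    lags = np.unique(np.round(
        np.logspace(0.0, np.log10(max_lag), 25)).astype(int))
    msd = np.empty(lags.size)
    for i, k in enumerate(lags):
        d = xy[k:] - xy[:-k]
        msd[i] = np.mean(np.einsum("ij,ij->i", d, d))
    dt = np.median(np.diff(traj.t_s))
    good = msd > 0
    if good.sum() < 2:
        return 0.0
    slope, _ = np.polyfit(np.log(lags[good] * dt), np.log(msd[good]), 1)
    return float(slope)


def classify_mobility(metrics: MotionMetrics, alpha: float,
                      ev_diameter_um: Optional[float] = None,
                      alpha_star: float = DEFAULT_ALPHA_STAR,
                      trace: Optional[list] = None) -> str:
    """Static/mobile call from displacement and the MSD exponent.

    static_immobile if the maximal distance from the contact point does
    not exceed the EV diameter (a moving EV shows a displacement
    *greater* than its diameter, so ties go to the static side);
    otherwise static_brownian if alpha does not exceed ``alpha_star``
    (moved more than a diameter, but only diffusively); otherwise
    mobile.
    """
    if ev_diameter_um is None or not ev_diameter_um > 0:
        raise ValueError("a positive ev_diameter_um is required")
    if trace is None:
        trace = []
    d = metrics.max_dist_contact_um
    if d <= ev_diameter_um:
        trace.append(f"max_dist_contact {d:.3g} um <= diameter "
                     f"{ev_diameter_um:.3g} um -> static_immobile")
        return "static_immobile"
    trace.append(f"max_dist_contact {d:.3g} um > diameter "
                 f"{ev_diameter_um:.3g} um -> displaced")
    if alpha <= alpha_star:
        trace.append(f"alpha {alpha:.3g} <= {alpha_star:.3g} "
                     "-> static_brownian")
        return "static_brownian"
    trace.append(f"alpha {alpha:.3g} > {alpha_star:.3g} -> mobile")
    return "mobile"


def classify_direction(run_length_pos_um: float, run_length_neg_um: float,
                       ratio: float = DEFAULT_RUN_RATIO,
                       trace: Optional[list] = None) -> str:
    """Anterograde / retrograde / bidirectional from run lengths.

    Anterograde when the anterograde run length exceeds ``ratio`` times
    the retrograde one; retrograde symmetrically; otherwise (including
    equality at exactly the ratio) bidirectional.
    """
    rp, rn = run_length_pos_um, run_length_neg_um
    if rp < 0 or rn < 0:
        raise ValueError("run lengths must be >= 0")
    if rp == 0 and rn == 0:
        raise ValueError("both run lengths are zero: the EV is static")
    if trace is None:
        trace = []
    if rp > ratio * rn:
        trace.append(f"run_pos {rp:.3g} > {ratio:g} x run_neg {rn:.3g} "
                     "-> anterograde")
        return "anterograde"
    if rn > ratio * rp:
        trace.append(f"run_neg {rn:.3g} > {ratio:g} x run_pos {rp:.3g} "
                     "-> retrograde")
        return "retrograde"
    trace.append(f"neither run length exceeds {ratio:g} x the other "
                 "-> bidirectional")
    return "bidirectional"


def classify_trajectory(
    traj: Trajectory,
    axis: Optional[NeuriteAxis] = None,
    interval_s: Optional[float] = DEFAULT_ANALYSIS_INTERVAL_S,
    motion_eps_um: float = DEFAULT_MOTION_EPS_UM,
    alpha_star: float = DEFAULT_ALPHA_STAR,
    ratio: float = DEFAULT_RUN_RATIO,
    metrics: Optional[MotionMetrics] = None,
) -> MotionLabels:
    """Full per-EV classification: metrics, MSD exponent, rule cascade."""
    if metrics is None:
        metrics = compute_metrics(traj, axis, interval_s, motion_eps_um)
    rs = traj if interval_s is None else resample(traj, interval_s)
    alpha = msd_exponent(rs)
    trace: list[str] = []
    mobility = classify_mobility(metrics, alpha, traj.ev_diameter_um,
                                 alpha_star, trace)
    if mobility == "mobile" and np.isfinite(metrics.run_length_pos_um):
        direction = classify_direction(metrics.run_length_pos_um,
                                       metrics.run_length_neg_um,
                                       ratio, trace)
    elif mobility == "mobile":
        direction = "bidirectional"
        trace.append("no axis: direction defaults to bidirectional")
    else:
        direction = "undefined"
    return MotionLabels(mobility=mobility, direction=direction,
                        msd_alpha=alpha, decision_trace=trace)
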