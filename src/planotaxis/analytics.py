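"""Trajectory and circular statistics for orientation assays.

Summaries operate in a light-referenced frame: bearings are expressed in
[0, 360) with the direction *toward* the light source at 0 and "directly
away" at 180, increasing clockwise viewed from above.  This makes the
180-degree left/right split of the twin-tail analysis literal.

The precision index is the inverse circular standard deviation,
``1 / sqrt(-2 ln R)`` with R the sample mean resultant length; the escape
value is the net displacement projected onto the light-propagation axis
divided by the path length, so an ideal straight escape scores 1 and a
straight march into the light scores -1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import TYPE_CHECKING, Sequence

import numpy as np
from scipy import stats

from .geometry import wrap180, wrap360

if TYPE_CHECKING:  # pragma: no cover
    from .simulator import LightSource, Trajectory

__all__ = [
    "CircularSummary",
    "TwinTailResult",
    "WigwagFit",
    "circular_summary",
    "escape_value",
    "exit_bearing",
    "twin_tail_separation",
    "rose_histogram",
    "turn_light_regression",
    "heading_from_positions",
    "extract_wigwag",
    "fit_wigwag_distributions",
    "summarize_cohort",
]

_R_ONE_TOL = 1.0 - 1e-12
_R_ZERO_TOL = 1e-12


@dataclass(frozen=True)
class CircularSummary:
    n: int
    mean_bearing: float        # degrees in [0, 360)
    resultant_length: float    # R, in [0, 1]
    circular_sd: float         # radians; inf when R = 0
    precision_index: float     # 1/sqrt(-2 ln R); inf when R = 1, 0 when R = 0


def circular_summary(bearings_deg: Sequence[float]) -> CircularSummary:
    """Vector-mean circular summary of a set of bearings (degrees)."""
    b = np.asarray(bearings_deg, dtype=float)
    if b.size == 0:
        raise ValueError("circular_summary requires at least one bearing")
    rad = np.radians(b)
    c, s = np.cos(rad).mean(), np.sin(rad).mean()
    r = float(math.hypot(c, s))
    mean_bearing = wrap360(math.degrees(math.atan2(s, c)))
    if r >= _R_ONE_TOL:
        circ_sd, precision = 0.0, math.inf
    elif r <= _R_ZERO_TOL:
        circ_sd, precision = math.inf, 0.0
    else:
        circ_sd = math.sqrt(-2.0 * math.log(r))
        precision = 1.0 / circ_sd
    return CircularSummary(
        n=int(b.size),
        mean_bearing=mean_bearing,
        resultant_length=r,
        circular_sd=circ_sd,
        precision_index=precision,
    )


def escape_value(traj: "Trajectory", source: "LightSource") -> float:
    """Net displacement along the light-propagation axis per unit path.

    1 for a straight path directly away from the source, -1 straight
    toward it, 0 for motion perpendicular to the light axis.
    """
    x = np.asarray(traj.x, dtype=float)
    y = np.asarray(traj.y, dtype=float)
    if x.size < 2:
        raise ValueError("escape_value requires at least two samples")
    path = float(np.hypot(np.diff(x), np.diff(y)).sum())
    if path == 0.0:
        raise ValueError("escape_value undefined for a zero-length path")
    prop = math.radians(source.propagation_bearing)
    projected = (x[-1] - x[0]) * math.sin(prop) + (y[-1] - y[0]) * math.cos(prop)
    return float(projected / path)


def exit_bearing(traj: "Trajectory", source: "LightSource") -> float:
    """Bearing of the final position from the start, light source at 0.

    Degrees in [0, 360); 180 = directly away from the source.
    """
    dx = float(traj.x[-1] - traj.x[0])
    dy = float(traj.y[-1] - traj.y[0])
    if dx == 0.0 and dy == 0.0:
        raise ValueError("exit_bearing undefined for a zero net displacement")
    arena_bearing = math.degrees(math.atan2(dx, dy))
    return wrap360(arena_bearing - source.source_bearing)


@dataclass(frozen=True)
class TwinTailResult:
    left_median: float
    right_median: float
    separation: float
    n_left: int
    n_right: int


def twin_tail_separation(exit_bearings_deg: Sequence[float]) -> TwinTailResult:
    """Median separation of left- vs right-escaping bearings.

    Bearings (light at 0, away at 180, [0, 360)) below 180 form the left
    group, the rest the right group; the separation is the absolute
    difference of the group medians.  Raises ``ValueError`` when either
    group is empty (callers may fall back to circular-SD reporting).
    """
    b = wrap360(np.asarray(exit_bearings_deg, dtype=float))
    left = b[b < 180.0]
    right = b[b >= 180.0]
    if left.size == 0 or right.size == 0:
        raise ValueError(
            f"twin_tail_separation needs both groups non-empty "
            f"(left={left.size}, right={right.size})"
        )
    lm = float(np.median(left))
    rm = float(np.median(right))
    return TwinTailResult(
        left_median=lm,
        right_median=rm,
        separation=abs(rm - lm),
        n_left=int(left.size),
        n_right=int(right.size),
    )


def rose_histogram(bearings_deg: Sequence[float], n_bins: int = 4) -> np.ndarray:
    """Percentages per angular bin, bins centered on 0, 360/n, ... degrees.

    With the default four bins (90-degree intervals) and light-referenced
    bearings the bins are centered on toward (0), right (90), away (180)
    and left (270); percentages sum to 100.
    """
    b = wrap360(np.asarray(bearings_deg, dtype=float))
    if b.size == 0:
        raise ValueError("rose_histogram requires at least one bearing")
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    width = 360.0 / n_bins
    idx = np.floor(np.mod(b + width / 2.0, 360.0) / width).astype(int)
    counts = np.bincount(idx, minlength=n_bins)
    return 100.0 * counts / b.size


def turn_light_regression(
    light_angles_deg: Sequence[float],
    turn_angles_deg: Sequence[float],
    split_deg: float = 130.0,
) -> tuple[float, float]:
    """r^2 of signed turn angle on signed light angle, all vs below split.

    Ordinary least squares of the turn-angle scatter; returns
    ``(r2_all, r2_below_split)`` where the second value restricts to
    |light angle| <= split.  Within the responsive band the turn-away
    rule is an odd, near-linear function of the light bearing, so the
    restricted fit is tight; beyond the split the reorientations are
    undirected and dilute the correlation.  Each subset needs >= 3 points
    and non-degenerate variance.
    """
    light = wrap180(np.asarray(light_angles_deg, dtype=float))
    turn = wrap180(np.asarray(turn_angles_deg, dtype=float))
    if light.shape != turn.shape:
        raise ValueError("light and turn angle arrays must have equal length")

    def _r2(x: np.ndarray, y: np.ndarray) -> float:
        if x.size < 3:
            raise ValueError("regression needs at least 3 pairs per subset")
        if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
            raise ValueError("regression undefined for zero-variance input")
        return float(stats.linregress(x, y).rvalue ** 2)

    below = np.abs(light) <= split_deg
    return _r2(light, turn), _r2(light[below], turn[below])


def heading_from_positions(x: Sequence[float], y: Sequence[float]) -> np.ndarray:
    """Movement bearings (degrees, compass convention) from positions."""
    dx = np.diff(np.asarray(x, dtype=float))
    dy = np.diff(np.asarray(y, dtype=float))
    return np.degrees(np.arctan2(dx, dy))


@dataclass
class WigwagFit:
    angles: np.ndarray          # degrees, signed, one per sway event
    intervals: np.ndarray       # seconds, between consecutive events
    normal_mean_mle: float
    normal_sd_mle: float        # MLE (1/n) estimator
    lognormal_mu_mle: float
    lognormal_sigma_mle: float


def extract_wigwag(
    t: Sequence[float],
    phi_deg: Sequence[float],
    deadband_deg: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Detect sway events in a heading time series.

    A turning event is a sign reversal of the (supra-deadband) heading
    increments; the sway angle is the heading change accumulated over the
    run that the reversal ends, and intervals are the times between
    consecutive reversals.  Sub-deadband increments are treated as
    tracking jitter and ignored.  A monotone heading series yields no
    events (empty arrays), which is not an error.
    """
    t = np.asarray(t, dtype=float)
    phi = np.asarray(phi_deg, dtype=float)
    if t.size != phi.size:
        raise ValueError("t and phi must have equal length")
    if t.size < 3:
        raise ValueError("extract_wigwag requires at least 3 samples")
    increments = wrap180(np.diff(phi))
    angles: list[float] = []
    intervals: list[float] = []
    direction = 0.0
    accumulated = 0.0
    last_event_t: float | None = None
    for dt_phi, ti in zip(increments, t[1:]):
        if abs(dt_phi) <= deadband_deg:
            continue
        sign = math.copysign(1.0, dt_phi)
        if direction == 0.0 or sign == direction:
            accumulated += dt_phi
            direction = sign
            continue
        # reversal: close the previous run
        angles.append(accumulated)
        if last_event_t is not None:
            intervals.append(ti - last_event_t)
        last_event_t = float(ti)
        accumulated = dt_phi
        direction = sign
    return np.asarray(angles), np.asarray(intervals)


def fit_wigwag_distributions(
    angles_deg: Sequence[float],
    intervals_s: Sequence[float],
) -> WigwagFit:
    """Maximum-likelihood fits of the wigwag distributions.

    Normal MLE (mean, 1/n SD) for sway angles; log-normal MLE — i.e. the
    normal MLE of the log intervals — for inter-sway intervals.
    """
    angles = np.asarray(angles_deg, dtype=float)
    intervals = np.asarray(intervals_s, dtype=float)
    if angles.size < 2 or intervals.size < 2:
        raise ValueError("fits require at least 2 observations each")
    if np.any(intervals <= 0):
        raise ValueError("intervals must be strictly positive")
    log_intervals = np.log(intervals)
    return WigwagFit(
        angles=angles,
        intervals=intervals,
        normal_mean_mle=float(angles.mean()),
        normal_sd_mle=float(angles.std(ddof=0)),
        lognormal_mu_mle=float(log_intervals.mean()),
        lognormal_sigma_mle=float(log_intervals.std(ddof=0)),
    )


def summarize_cohort(trajectories, source) -> dict:
    """One summary row for a cohort of trajectories.

    Reports exit-bearing circular statistics, mean escape value, the
    twin-tail separation when both tails are populated (NaN otherwise),
    and the axial (doubled-angle) resultant length, which quantifies
    bow-tie symmetry in two-source assays.
    """
    bearings = [exit_bearing(tr, source) for tr in trajectories]
    escapes = [escape_value(tr, source) for tr in trajectories]
    summary = circular_summary(bearings)
    axial = circular_summary([2.0 * b for b in bearings])
    try:
        twin = twin_tail_separation(bearings).separation
    except ValueError:
        twin = float("nan")
    return {
        "n": summary.n,
        "mean_bearing_deg": summary.mean_bearing,
        "resultant_length": summary.resultant_length,
        "precision_index": summary.precision_index,
        "axial_resultant_length": axial.resultant_length,
        "mean_escape": float(np.mean(escapes)),
        "twin_tail_separation_deg": twin,
    }
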