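"""Synthetic video-tracking fixtures emulating gliding planarians.

Generates frame-sampled 2-D tracks in physical units (mm, s) with the
statistical structure of real assays: constant gliding speed ~1 mm/s,
side-to-side wigwag head sway with Normal(0, 18.7 deg^2) amplitudes at
log-normally distributed intervals, and optionally the threshold-gated
phototaxis turn rule.  Sway direction alternates left/right (that is what
"wigwag" means), with magnitudes drawn as |Normal(0, sd^2)|; the pooled
signed sway-angle distribution is then exactly Normal(0, sd^2) while
reversal-based event detection recovers every individual sway.

These fixtures exercise the analytics without the simulator and without
any downloads; they do not emulate body deformation, head-vs-centroid
tracking offsets, wall interactions, or occlusion artifacts of real video.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .behavior import BehaviorParams, turn_update
from .geometry import EyeGeometry, eye_inputs, input_difference, wrap180, wrap360

__all__ = [
    "TrackingFixtureParams",
    "generate_tracking",
    "generate_turn_dataset",
]


@dataclass(frozen=True)
class TrackingFixtureParams:
    """Ground-truth parameters of a synthetic tracking export."""

    speed: float = 1.0                  # mm/s
    frame_rate: float = 30.0            # Hz
    duration_s: float = 60.0
    wigwag_angle_sd: float = 18.7       # degrees
    wigwag_log_mean: float = -0.15      # log-seconds
    wigwag_log_sd: float = 0.44
    phototaxis_enabled: bool = False
    bf_deg: float = 40.0
    tau: float = 0.5
    gain: float = 3.0
    gain_units: str = "radians"
    light_propagation_deg: float = 0.0  # direction rays travel, arena frame
    arena_radius_mm: float = 40.0
    include_heading: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.speed <= 0 or self.frame_rate <= 0:
            raise ValueError("speed and frame_rate must be positive")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.wigwag_angle_sd < 0:
            raise ValueError("wigwag_angle_sd must be non-negative")

    def behavior(self) -> BehaviorParams:
        return BehaviorParams(
            tau=self.tau,
            gain=self.gain,
            gain_units=self.gain_units,
            wigwag_angle_sd=max(self.wigwag_angle_sd, 1e-12),
            wigwag_log_mean=self.wigwag_log_mean,
            wigwag_log_sd=self.wigwag_log_sd,
        )

    def to_dict(self) -> dict:
        return asdict(self)


def _animal_rng(seed: int, animal: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(animal)]))


def generate_tracking(params: TrackingFixtureParams, n_animals: int = 1) -> pd.DataFrame:
    """Frame-sampled tracks for ``n_animals`` starting at the arena center.

    Columns: ``animal_id, frame, t_s, x_mm, y_mm`` and, when
    ``params.include_heading``, ``heading_deg``.  Heading is piecewise
    constant between sway events; events are scheduled in continuous time
    from the log-normal interval distribution and applied at the next
    frame boundary, so the per-frame displacement is exactly
    ``speed / frame_rate``.  Deterministic per ``(seed, animal)``.
    """
    if n_animals < 1:
        raise ValueError("n_animals must be >= 1")
    dt = 1.0 / params.frame_rate
    step_mm = params.speed * dt
    n_frames = int(round(params.duration_s * params.frame_rate))
    geom = EyeGeometry(binocular_field=params.bf_deg)
    behavior = params.behavior()
    source_bearing = wrap180(params.light_propagation_deg + 180.0)

    frames_out = []
    for animal in range(n_animals):
        rng = _animal_rng(params.seed, animal)
        phi = float(rng.uniform(0.0, 360.0))
        sway_sign = 1.0 if rng.random() < 0.5 else -1.0
        next_event = float(rng.lognormal(params.wigwag_log_mean, params.wigwag_log_sd))
        x = y = 0.0
        rows = []
        for frame in range(n_frames + 1):
            t = frame * dt
            rows.append((animal, frame, t, x, y, wrap180(phi)))
            if math.hypot(x, y) >= params.arena_radius_mm:
                break
            # apply all sway events that have come due in this frame window
            while next_event <= t + dt:
                xi = sway_sign * abs(rng.normal(0.0, params.wigwag_angle_sd))
                sway_sign = -sway_sign
                if params.phototaxis_enabled:
                    theta = wrap180(source_bearing - phi)
                    phi = turn_update(phi, eye_inputs(theta, geom), behavior, xi)
                else:
                    phi = wrap180(phi + xi)
                next_event += float(
                    rng.lognormal(params.wigwag_log_mean, params.wigwag_log_sd)
                )
            phi_rad = math.radians(phi)
            x += step_mm * math.sin(phi_rad)
            y += step_mm * math.cos(phi_rad)
        frames_out.extend(rows)

    df = pd.DataFrame(
        frames_out, columns=["animal_id", "frame", "t_s", "x_mm", "y_mm", "heading_deg"]
    )
    if not params.include_heading:
        df = df.drop(columns=["heading_deg"])
    return df


def generate_turn_dataset(
    params: TrackingFixtureParams,
    n: int,
    turn_noise_sd_deg: float = 20.0,
) -> pd.DataFrame:
    """Synthetic (light angle, turn angle) scatter.

    Light angles are uniform on (-180, 180].  Within the response band the
    turn follows the proportional gain rule plus normal measurement/behavior
    noise; outside it (front blind-like spot and posterior blind field) the
    recorded turn is uniform on (-180, 180], emulating the undirected
    reorientations seen beyond the responsive range.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence([int(params.seed), 7]))
    geom = EyeGeometry(binocular_field=params.bf_deg)
    behavior = params.behavior()
    light = wrap180(rng.uniform(-180.0, 180.0, size=n))
    turns = np.empty(n)
    for i, theta in enumerate(light):
        diff = input_difference(float(theta), geom)
        if abs(diff) > params.tau:
            model_turn = turn_update(0.0, eye_inputs(float(theta), geom), behavior, 0.0)
            turns[i] = wrap180(model_turn + rng.normal(0.0, turn_noise_sd_deg))
        else:
            turns[i] = wrap180(rng.uniform(-180.0, 180.0))
    return pd.DataFrame({"light_angle_deg": light, "turn_angle_deg": turns})
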