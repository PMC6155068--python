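"""Event-driven arena simulation of photo-responding agents.

Agents start at the arena center with uniform random headings and glide
in unit steps (one step per wigwag event) until they cross the arena edge
or exhaust the event budget.  Light is directional (parallel rays): the
physical source sits ~30 cm from a 4 cm arena, so the light bearing is
independent of position and only the agent's heading matters.

Arena-frame bearings are compass-style: 0 degrees along +y, increasing
clockwise toward +x, so a step is ``(x + sin(phi), y + cos(phi))``.
A light source is given by the bearing its rays travel along
(``propagation_bearing``); the direction *toward* the source is the
opposite bearing.

Perturbation models for the classic eye manipulations:

* lidocaine — multiplies the affected eye's input by a gain in [0, 1]
  (0 = fully silenced);
* eyecup removal — the eye loses its pigment shield and responds to light
  from either side, |sin| instead of the one-sided clamped sine.

Wigwag head sway enters through the sensed light bearing by default
(``wigwag_mode="sensing"``; see :func:`step`): the head sways, samples
the world at the deflected angle, and the body turns only on a
supra-threshold sensed difference.  Below threshold the animal glides
straight, which is what makes the front blind-like spot behaviorally
costly and the ~40-degree binocular field optimal.

Reproducibility: every agent draws from its own ``numpy`` generator
seeded by ``(master_seed, agent_index)``, so enlarging a cohort never
reshuffles earlier agents.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .behavior import (
    BehaviorParams,
    sample_wigwag_angle,
    sample_wigwag_interval,
    turn_update,
)
from .geometry import EyeGeometry, InputPair, wrap180

__all__ = [
    "LightSource",
    "PerturbationConfig",
    "ArenaConfig",
    "SimulationConfig",
    "AgentState",
    "Trajectory",
    "light_bearing",
    "perceived_inputs",
    "step",
    "run_agent",
    "run_cohort",
    "sweep_binocular_field",
]


@dataclass(frozen=True)
class LightSource:
    """Directional light; ``propagation_bearing`` is the ray direction."""

    propagation_bearing: float = 0.0
    active: bool = True

    @property
    def source_bearing(self) -> float:
        """Arena bearing pointing from the arena toward the source."""
        return wrap180(self.propagation_bearing + 180.0)


@dataclass(frozen=True)
class PerturbationConfig:
    """Per-eye input manipulations (identity by default)."""

    left_gain: float = 1.0
    right_gain: float = 1.0
    left_unshielded: bool = False
    right_unshielded: bool = False

    def __post_init__(self) -> None:
        for name in ("left_gain", "right_gain"):
            g = getattr(self, name)
            if not 0.0 <= g <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {g}")


@dataclass(frozen=True)
class ArenaConfig:
    radius: float = 40.0          # in unit steps
    max_events: int = 400

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if self.max_events <= 0:
            raise ValueError("max_events must be positive")


_ASSAY_SOURCES = {
    "oa1l": (LightSource(0.0),),
    "oa2l": (LightSource(0.0), LightSource(180.0)),
}


@dataclass(frozen=True)
class SimulationConfig:
    """Full description of one simulated assay."""

    assay: str = "oa1l"
    eye: EyeGeometry = field(default_factory=EyeGeometry)
    behavior: BehaviorParams = field(default_factory=BehaviorParams)
    perturbation: PerturbationConfig = field(default_factory=PerturbationConfig)
    arena: ArenaConfig = field(default_factory=ArenaConfig)
    n_agents: int = 40
    seed: int = 0

    def __post_init__(self) -> None:
        if self.assay not in _ASSAY_SOURCES:
            raise ValueError(f"assay must be one of {sorted(_ASSAY_SOURCES)}")
        if self.n_agents < 1:
            raise ValueError("n_agents must be >= 1")

    @property
    def sources(self) -> tuple[LightSource, ...]:
        return _ASSAY_SOURCES[self.assay]


@dataclass(frozen=True)
class AgentState:
    x: float
    y: float
    phi: float      # heading, degrees, (-180, 180]
    t: float        # seconds


@dataclass
class Trajectory:
    """Ordered record of agent states, starting at the origin."""

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    phi: np.ndarray
    metadata: dict = field(default_factory=dict)

    @property
    def n_events(self) -> int:
        return len(self.t) - 1

    def to_dataframe(self, agent_id: int = 0) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "agent_id": agent_id,
                "event_index": np.arange(len(self.t)),
                "t_s": self.t,
                "x": self.x,
                "y": self.y,
                "phi_deg": self.phi,
            }
        )


def light_bearing(phi_deg: float, source: LightSource) -> float:
    """Bearing of incoming light relative to the agent's anterior axis.

    0 = light arrives head-on (agent moving straight toward the source),
    +-180 = from directly behind; positive = source on the agent's right.
    """
    if not source.active:
        raise ValueError("light_bearing requires an active source")
    return wrap180(source.source_bearing - phi_deg)


def perceived_inputs(
    thetas_deg,
    geom: EyeGeometry,
    pert: PerturbationConfig | None = None,
) -> InputPair:
    """Per-eye inputs summed over sources, perturbed, clamped to [0, 1].

    ``thetas_deg`` is an iterable of per-source light bearings.  An
    unshielded eye responds as |sin| (light admitted from both sides);
    lidocaine gains scale each eye's summed input before the final clamp.
    """
    pert = pert or PerturbationConfig()
    thetas = list(thetas_deg)
    if not thetas:
        raise ValueError("at least one active light source is required")
    beta = math.radians(geom.obliqueness)
    left_total = 0.0
    right_total = 0.0
    for theta_deg in thetas:
        theta = math.radians(wrap180(theta_deg))
        left_raw = -math.sin(theta - beta)
        right_raw = math.sin(theta + beta)
        left_total += abs(left_raw) if pert.left_unshielded else max(0.0, left_raw)
        right_total += abs(right_raw) if pert.right_unshielded else max(0.0, right_raw)
    left = min(1.0, left_total * pert.left_gain)
    right = min(1.0, right_total * pert.right_gain)
    return InputPair(left, right)


def step(
    agent: AgentState,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> AgentState:
    """Advance one wigwag event: draw interval and sway, turn, unit step.

    The event clock runs on the log-normal interval distribution whether
    or not wigwag sway is enabled.

    In the default ``wigwag_mode="sensing"`` the sway deflects the head:
    light is sensed at the swayed bearing ``theta + xi``, and the body
    keeps gliding straight unless the sensed difference exceeds the
    threshold, in which case the commanded turn (and the sway itself)
    enter the heading.  This makes the anterior blind-like spot sticky —
    an agent facing the light walks toward it until a sway large enough
    to leave the spot lets it sense the light's side.  In
    ``wigwag_mode="heading"`` the sway is simply added to the heading
    every event and sensing uses the true body bearing.
    """
    params = config.behavior
    k = float(sample_wigwag_interval(params, rng))
    xi = float(sample_wigwag_angle(params, rng))
    sensed_offset = xi if params.wigwag_mode == "sensing" else 0.0
    thetas = [
        light_bearing(agent.phi, s) + sensed_offset
        for s in config.sources
        if s.active
    ]
    if thetas:
        inputs = perceived_inputs(thetas, config.eye, config.perturbation)
    else:
        inputs = InputPair(0.0, 0.0)
    if params.wigwag_mode == "sensing" and abs(inputs.right - inputs.left) <= params.tau:
        phi_new = agent.phi  # head swings back; body glides straight
    else:
        phi_new = turn_update(agent.phi, inputs, params, xi)
    phi_rad = math.radians(phi_new)
    return AgentState(
        x=agent.x + math.sin(phi_rad),
        y=agent.y + math.cos(phi_rad),
        phi=phi_new,
        t=agent.t + k,
    )


def run_agent(
    config: SimulationConfig,
    rng: np.random.Generator,
    initial_phi: float | None = None,
) -> Trajectory:
    """Simulate one agent from the arena center until edge or event cap."""
    if initial_phi is None:
        initial_phi = float(rng.uniform(0.0, 360.0))
    state = AgentState(x=0.0, y=0.0, phi=wrap180(initial_phi), t=0.0)
    ts, xs, ys, phis = [state.t], [state.x], [state.y], [state.phi]
    reached_edge = False
    for _ in range(config.arena.max_events):
        state = step(state, config, rng)
        ts.append(state.t)
        xs.append(state.x)
        ys.append(state.y)
        phis.append(state.phi)
        if math.hypot(state.x, state.y) >= config.arena.radius:
            reached_edge = True
            break
    return Trajectory(
        t=np.array(ts),
        x=np.array(xs),
        y=np.array(ys),
        phi=np.array(phis),
        metadata={
            "assay": config.assay,
            "bf_deg": config.eye.binocular_field,
            "reached_edge": reached_edge,
            "initial_phi": wrap180(initial_phi),
        },
    )


def _agent_rng(seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(index)]))


def run_cohort(config: SimulationConfig, n: int | None = None) -> list[Trajectory]:
    """Simulate ``n`` independent agents (default ``config.n_agents``).

    Agent ``i`` uses the substream seeded ``(config.seed, i)``; cohorts of
    different sizes share their common prefix of agents.
    """
    n = config.n_agents if n is None else n
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    trajectories = []
    for i in range(n):
        traj = run_agent(config, _agent_rng(config.seed, i))
        traj.metadata["agent_id"] = i
        traj.metadata["seed"] = config.seed
        trajectories.append(traj)
    return trajectories


def sweep_binocular_field(
    bf_values,
    n: int,
    config: SimulationConfig,
) -> pd.DataFrame:
    """Escape-value summary for cohorts at each binocular-field width.

    Returns a table with columns ``bf_deg, n, mean_escape, sd_escape``
    (SD across agents within the cohort).  Each binocular field gets a
    fresh seed substream derived from ``config.seed``.
    """
    from .analytics import escape_value  # local import avoids cycle

    if n < 1:
        raise ValueError("n must be >= 1")
    bf_list = list(bf_values)
    if not bf_list:
        raise ValueError("bf_values must be non-empty")
    source = config.sources[0]
    rows = []
    for idx, bf in enumerate(bf_list):
        sub_seed = int(
            np.random.SeedSequence([int(config.seed), 1000 + idx]).generate_state(1)[0]
            % (2**31)
        )
        cfg = dataclasses.replace(
            config,
            eye=EyeGeometry(binocular_field=float(bf),
                            monocular_field=config.eye.monocular_field),
            seed=sub_seed,
        )
        escapes = [escape_value(tr, source) for tr in run_cohort(cfg, n)]
        rows.append(
            {
                "bf_deg": float(bf),
                "n": n,
                "mean_escape": float(np.mean(escapes)),
                "sd_escape": float(np.std(escapes, ddof=1)),
            }
        )
    return pd.DataFrame(rows)
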