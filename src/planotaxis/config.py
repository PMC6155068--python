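"""Config-file loading for simulation runs (YAML or JSON).

Schema (all keys optional, defaults in parentheses)::

    assay: oa1l | oa2l          (oa1l)
    bf_deg: float               (40)
    alpha_deg: float | null     (null, morphometric only)
    tau: float                  (0.5)
    gain: float                 (3)
    gain_units: radians|degrees (radians)
    wigwag:
      enabled: bool             (true)
      mode: sensing | heading   (sensing)
      angle_sd_deg: float       (18.7)
      log_mean: float           (-0.15)
      log_sd: float             (0.44)
    perturbation:
      left_gain: float          (1.0)
      right_gain: float         (1.0)
      left_unshielded: bool     (false)
      right_unshielded: bool    (false)
    arena:
      radius: float             (40)
      max_events: int           (400)
    n_agents: int               (40)
    seed: int                   (0)
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml

from .behavior import BehaviorParams
from .geometry import EyeGeometry
from .simulator import ArenaConfig, PerturbationConfig, SimulationConfig

__all__ = ["load_config", "config_from_dict", "config_to_dict", "config_hash"]


def config_from_dict(raw: dict) -> SimulationConfig:
    """Build a ``SimulationConfig`` from a (possibly partial) mapping."""
    raw = dict(raw or {})
    wigwag = dict(raw.get("wigwag") or {})
    pert = dict(raw.get("perturbation") or {})
    arena = dict(raw.get("arena") or {})
    try:
        return SimulationConfig(
            assay=str(raw.get("assay", "oa1l")).lower(),
            eye=EyeGeometry(
                binocular_field=float(raw.get("bf_deg", 40.0)),
                monocular_field=(
                    float(raw["alpha_deg"]) if raw.get("alpha_deg") is not None else None
                ),
            ),
            behavior=BehaviorParams(
                tau=float(raw.get("tau", 0.5)),
                gain=float(raw.get("gain", 3.0)),
                gain_units=str(raw.get("gain_units", "radians")),
                wigwag_enabled=bool(wigwag.get("enabled", True)),
                wigwag_mode=str(wigwag.get("mode", "sensing")),
                wigwag_angle_sd=float(wigwag.get("angle_sd_deg", 18.7)),
                wigwag_log_mean=float(wigwag.get("log_mean", -0.15)),
                wigwag_log_sd=float(wigwag.get("log_sd", 0.44)),
            ),
            perturbation=PerturbationConfig(
                left_gain=float(pert.get("left_gain", 1.0)),
                right_gain=float(pert.get("right_gain", 1.0)),
                left_unshielded=bool(pert.get("left_unshielded", False)),
                right_unshielded=bool(pert.get("right_unshielded", False)),
            ),
            arena=ArenaConfig(
                radius=float(arena.get("radius", 40.0)),
                max_events=int(arena.get("max_events", 400)),
            ),
            n_agents=int(raw.get("n_agents", 40)),
            seed=int(raw.get("seed", 0)),
        )
    except (TypeError, ValueError) as exc:
        raise ValueError(f"invalid configuration: {exc}") from exc


def load_config(path) -> SimulationConfig:
    """Load a YAML or JSON config file."""
    text = Path(path).read_text(encoding="utf-8")
    raw = yaml.safe_load(text)  # YAML is a superset of JSON
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError(f"config root must be a mapping, got {type(raw).__name__}")
    return config_from_dict(raw)


def config_to_dict(config: SimulationConfig) -> dict:
    """Round-trippable plain-dict snapshot of a configuration."""
    return {
        "assay": config.assay,
        "bf_deg": config.eye.binocular_field,
        "alpha_deg": config.eye.monocular_field,
        "tau": config.behavior.tau,
        "gain": config.behavior.gain,
        "gain_units": config.behavior.gain_units,
        "wigwag": {
            "enabled": config.behavior.wigwag_enabled,
            "mode": config.behavior.wigwag_mode,
            "angle_sd_deg": config.behavior.wigwag_angle_sd,
            "log_mean": config.behavior.wigwag_log_mean,
            "log_sd": config.behavior.wigwag_log_sd,
        },
        "perturbation": {
            "left_gain": config.perturbation.left_gain,
            "right_gain": config.perturbation.right_gain,
            "left_unshielded": config.perturbation.left_unshielded,
            "right_unshielded": config.perturbation.right_unshielded,
        },
        "arena": {
            "radius": config.arena.radius,
            "max_events": config.arena.max_events,
        },
        "n_agents": config.n_agents,
        "seed": config.seed,
    }


def config_hash(config: SimulationConfig) -> str:
    """Stable short hash of the canonical config snapshot."""
    canonical = json.dumps(config_to_dict(config), sort_keys=True)
    return hashlib.sha256(canonical.encode("utf-8")).hexdigest()[:16]
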