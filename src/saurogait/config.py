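"""Configuration loading, validation and canned fixtures.

Configs are YAML or JSON with the printed-table units at the interface
(mm, g, degrees); models are built in SI.  Canned fixtures reproduce the
published parameter sets digit for digit: the three-link morphometrics,
the five morphometric variants of the planar study, the 15-link table and
the body-amplitude sweep.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .biomech import TABLE2_LINKS, BiomechModel, TrajectoryParams, build_biomech_model
from .planar import (
    TABLE1_MORPHOMETRICS,
    GaitSchedule,
    GrfProfile,
    PdGains,
    PlanarModel,
    SineParams,
    build_planar_model,
)

__all__ = [
    "RunConfig",
    "load_config",
    "save_config",
    "make_fixture",
    "FIG5_VARIANTS",
    "planar_model_from_config",
    "planar_blocks_from_config",
    "biomech_model_from_config",
    "trajectory_from_config",
]

log = logging.getLogger("saurogait")

#: The five (length, mass) morphometric variants of the planar study, mm/g:
#: (l1, l2, l3, m1, m2, m3).
FIG5_VARIANTS: list[tuple[float, float, float, float, float, float]] = [
    (66.0, 42.0, 84.0, 4.0, 4.0, 2.0),
    (60.0, 40.0, 92.0, 4.0, 4.0, 2.0),
    (72.0, 42.0, 78.0, 4.0, 4.0, 2.0),
    (66.0, 42.0, 84.0, 4.2, 4.0, 1.8),
    (66.0, 42.0, 84.0, 3.8, 4.0, 2.2),
]

_SCHEMA: dict[str, set[str]] = {
    "": {"kind", "model", "gait", "grf", "controller", "optimizer",
         "integrator", "trajectory", "output"},
    "model": set(TABLE1_MORPHOMETRICS) | set(TABLE2_LINKS)
    | {"foot_offset_distance_mm", "foot_offset_angle_deg", "shoulder_x_mm",
       "shoulder_y_mm", "pelvic_x_mm", "pelvic_y_mm", "foot_pitch_deg"},
    "gait": {"period_s", "stance_fraction", "pelvic_amplitude_deg", "speed_mps",
             "n_strides"},
    "grf": {"fore_aft_amplitude_n", "lateral_amplitude_n"},
    "controller": {"kp", "kd", "grm_bound_nm"},
    "optimizer": {"n_starts", "maxiter", "seed", "amplitude_bound_deg",
                  "method", "amplitudes_deg"},
    "integrator": {"dt_fraction", "steps_per_period"},
    "trajectory": {
        "period_s", "pelvic_amplitude_deg",
        "waist_amplitude_deg", "waist_phase_deg",
        "tail_amplitude_deg", "tail_phase_deg",
        "hip_swing_amplitude_deg", "hip_swing_phase_deg", "hip_swing_offset_deg",
        "hip_lift_amplitude_deg", "hip_lift_phase_deg", "hip_lift_offset_deg",
        "hip_roll_amplitude_deg", "hip_roll_phase_deg", "hip_roll_offset_deg",
        "knee_amplitude_deg", "knee_phase_deg", "knee_offset_deg",
    },
    "output": {"trace_csv", "summary_json"},
}


@dataclass
class RunConfig:
    """Validated configuration for one command run."""

    kind: str = "planar"  # 'planar' or 'biomech'
    model: dict = field(default_factory=dict)
    gait: dict = field(default_factory=dict)
    grf: dict = field(default_factory=dict)
    controller: dict = field(default_factory=dict)
    optimizer: dict = field(default_factory=dict)
    integrator: dict = field(default_factory=dict)
    trajectory: dict = field(default_factory=dict)
    output: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {k: v for k, v in asdict(self).items() if v or k == "kind"}


def _validate(data: dict) -> RunConfig:
    unknown = set(data) - _SCHEMA[""]
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    kind = data.get("kind", "planar")
    if kind not in ("planar", "biomech"):
        raise ValueError(f"kind must be 'planar' or 'biomech', got {kind!r}")
    cfg = RunConfig(kind=kind)
    for block, allowed in _SCHEMA.items():
        if not block or block not in data:
            continue
        body = data[block]
        if not isinstance(body, dict):
            raise ValueError(f"config block {block!r} must be a mapping")
        bad = set(body) - allowed
        if bad:
            raise ValueError(f"unknown keys in block {block!r}: {sorted(bad)}")
        setattr(cfg, block, dict(body))
    return cfg


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML/JSON config file."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"config root of {path} must be a mapping")
    cfg = _validate(data)
    log.debug("loaded config %s: %s", path, cfg.as_dict())
    return cfg


def save_config(cfg: RunConfig, path: str | Path) -> None:
    path = Path(path)
    data = cfg.as_dict()
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2, sort_keys=True))
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=True))


# --------------------------------------------------------------------------
# fixtures


def make_fixture(name: str) -> RunConfig | list[RunConfig]:
    """Return a canned configuration by name.

    Available: ``table1_planar``, ``fig5_variants`` (a list of five),
    ``table2_biomech``, ``fig13_sweep``.
    """
    registry = {
        "table1_planar": _fixture_table1,
        "fig5_variants": _fixture_fig5,
        "table2_biomech": _fixture_table2,
        "fig13_sweep": _fixture_sweep,
    }
    if name not in registry:
        raise KeyError(
            f"unknown fixture {name!r}; available: {sorted(registry)}"
        )
    return registry[name]()


def _fixture_table1() -> RunConfig:
    return _validate({"kind": "planar", "model": dict(TABLE1_MORPHOMETRICS)})


def _fixture_fig5() -> list[RunConfig]:
    out = []
    for l1, l2, l3, m1, m2, m3 in FIG5_VARIANTS:
        model = dict(TABLE1_MORPHOMETRICS)
        model.update(
            anterior_body_length_mm=l1, posterior_body_length_mm=l2,
            tail_length_mm=l3, anterior_body_mass_g=m1,
            posterior_body_mass_g=m2, tail_mass_g=m3,
        )
        out.append(_validate({"kind": "planar", "model": model}))
    return out


def _fixture_table2() -> RunConfig:
    return _validate({
        "kind": "biomech",
        "model": {k: list(v) for k, v in TABLE2_LINKS.items()},
    })


def _fixture_sweep() -> RunConfig:
    cfg = _fixture_table2()
    cfg.optimizer = {"amplitudes_deg": [2, 10, 20, 30, 40]}
    return cfg


# --------------------------------------------------------------------------
# object construction


def planar_model_from_config(cfg: RunConfig) -> PlanarModel:
    model = cfg.model or dict(TABLE1_MORPHOMETRICS)
    table = {k: v for k, v in model.items() if k in TABLE1_MORPHOMETRICS}
    kwargs = {}
    if "foot_offset_distance_mm" in model:
        kwargs["foot_offset_distance_mm"] = model["foot_offset_distance_mm"]
    if "foot_offset_angle_deg" in model:
        kwargs["foot_offset_angle_deg"] = model["foot_offset_angle_deg"]
    return build_planar_model(table or None, **kwargs)


def planar_blocks_from_config(cfg: RunConfig):
    """(model, schedule, grf, gains) for the planar pipeline."""
    model = planar_model_from_config(cfg)
    g = cfg.gait
    schedule = GaitSchedule(
        period=g.get("period_s", 0.092),
        stance_fraction=g.get("stance_fraction", 0.5),
        pelvic_amplitude=np.deg2rad(g.get("pelvic_amplitude_deg", 20.0)),
        initial_speed=g.get("speed_mps", 4.0),
    )
    f = cfg.grf
    grf = GrfProfile(
        fore_aft_amplitude=f.get("fore_aft_amplitude_n", 0.1),
        lateral_amplitude=f.get("lateral_amplitude_n", 0.1),
    )
    c = cfg.controller
    gains = PdGains(kp=c.get("kp", 0.25), kd=c.get("kd", 1.5e-3))
    return model, schedule, grf, gains


def biomech_model_from_config(cfg: RunConfig) -> BiomechModel:
    model = cfg.model or {}
    table = {k: v for k, v in model.items() if k in TABLE2_LINKS}
    kwargs = {
        k: model[k]
        for k in ("shoulder_x_mm", "shoulder_y_mm", "pelvic_x_mm",
                  "pelvic_y_mm", "foot_pitch_deg")
        if k in model
    }
    return build_biomech_model(table or None, **kwargs)


def _sine_from(block: dict, name: str, default: SineParams) -> SineParams:
    amp = block.get(f"{name}_amplitude_deg")
    phase = block.get(f"{name}_phase_deg")
    off = block.get(f"{name}_offset_deg")
    return SineParams(
        np.deg2rad(amp) if amp is not None else default.amplitude,
        np.deg2rad(phase) if phase is not None else default.phase,
        np.deg2rad(off) if off is not None else default.offset,
    )


def trajectory_from_config(cfg: RunConfig) -> TrajectoryParams:
    t = cfg.trajectory
    base = TrajectoryParams()
    return TrajectoryParams(
        period=t.get("period_s", base.period),
        pelvic_amplitude=np.deg2rad(t.get("pelvic_amplitude_deg", 20.0)),
        waist=_sine_from(t, "waist", base.waist),
        tail=_sine_from(t, "tail", base.tail),
        hip_swing=_sine_from(t, "hip_swing", base.hip_swing),
        hip_lift=_sine_from(t, "hip_lift", base.hip_lift),
        hip_roll=_sine_from(t, "hip_roll", base.hip_roll),
        knee=_sine_from(t, "knee", base.knee),
    )
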