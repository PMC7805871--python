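"""Configuration loading/validation and trajectory/trace CSV round-trips.

The shipped default configuration (``data/default.yaml``) carries the
published and tuned controller constants; ``load_config`` validates the full
object graph, rejects unknown keys, and fills each muscle's optimal length
from the neutral-angle geometry when ``L0`` is null.
"""

from __future__ import annotations

import dataclasses
import importlib.resources
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

from .ankle import (ActivationSchedule, AnkleGeometry, GaitTrajectory,
                    MomentTrace, neutral_lengths)
from .muscle import MuscleParams, ParameterError
from .strides import ankle_power

__all__ = [
    "RunConfig",
    "ConfigError",
    "load_config",
    "default_config",
    "dump_config",
    "read_trajectory",
    "write_trajectory",
    "read_moment_trace",
    "write_moment_trace",
]


class ConfigError(ValueError):
    """A configuration file failed validation; the message names the key path."""


@dataclass(frozen=True)
class RunConfig:
    """Run-level options resolved from the ``controller`` config section."""

    params_A: MuscleParams
    params_P: MuscleParams
    geometry: AnkleGeometry
    schedule: ActivationSchedule
    sample_rate_hz: float = 500.0
    resistance_gain: float = 0.0
    mass_kg: float = 82.0
    profile: str = "profile1"

    def __post_init__(self) -> None:
        if not self.sample_rate_hz > 0:
            raise ConfigError(f"sample_rate_hz must be > 0, got {self.sample_rate_hz}")
        if not self.mass_kg > 0:
            raise ConfigError(f"controller.mass_kg must be > 0, got {self.mass_kg}")


def _require_keys(mapping: dict, allowed: set, path: str) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} under {path!r}")


def _muscle_from(section: dict, name: str, L0_neutral: float) -> MuscleParams:
    _require_keys(section, {"P0", "kts", "kss", "Cce_l", "Cce_s", "L0", "fl_width"},
                  f"muscle.{name}")
    L0 = section.get("L0")
    try:
        return MuscleParams(name=name, P0=section["P0"], kts=section["kts"],
                            kss=section["kss"], Cce_l=section["Cce_l"],
                            Cce_s=section["Cce_s"],
                            L0=float(L0) if L0 is not None else float(L0_neutral),
                            fl_width=section.get("fl_width", 0.5))
    except (KeyError, ParameterError) as exc:
        raise ConfigError(f"muscle.{name}: {exc}") from exc


def _schedule_from(section: dict, profile: str, smoothing: float) -> ActivationSchedule:
    if profile not in section:
        raise ConfigError(f"schedule has no profile {profile!r}")
    prof = section[profile]
    _require_keys(prof, {"act_A", "act_P"}, f"schedule.{profile}")
    try:
        return ActivationSchedule(act_A={int(k): float(v) for k, v in prof["act_A"].items()},
                                  act_P={int(k): float(v) for k, v in prof["act_P"].items()},
                                  profile=profile, smoothing_s=smoothing)
    except ParameterError as exc:
        raise ConfigError(f"schedule.{profile}: {exc}") from exc


def _config_from_mapping(raw: dict) -> RunConfig:
    _require_keys(raw, {"sample_rate_hz", "muscle", "geometry", "schedule", "controller"},
                  "<root>")
    geo_raw = dict(raw.get("geometry", {}))
    _require_keys(geo_raw, {f.name for f in dataclasses.fields(AnkleGeometry)}, "geometry")
    try:
        geom = AnkleGeometry(**geo_raw)
    except Exception as exc:
        raise ConfigError(f"geometry: {exc}") from exc
    L0_A, L0_P = neutral_lengths(geom)

    muscles = raw.get("muscle", {})
    _require_keys(muscles, {"anterior", "posterior"}, "muscle")
    if "anterior" not in muscles or "posterior" not in muscles:
        raise ConfigError("muscle section must define both 'anterior' and 'posterior'")
    params_A = _muscle_from(muscles["anterior"], "anterior", L0_A)
    params_P = _muscle_from(muscles["posterior"], "posterior", L0_P)

    ctrl = dict(raw.get("controller", {}))
    _require_keys(ctrl, {"profile", "resistance_gain", "mass_kg"}, "controller")
    profile = ctrl.get("profile", "profile1")

    sched_raw = dict(raw.get("schedule", {}))
    smoothing = float(sched_raw.pop("smoothing_s", 0.0))
    schedule = _schedule_from(sched_raw, profile, smoothing)

    return RunConfig(params_A=params_A, params_P=params_P, geometry=geom,
                     schedule=schedule,
                     sample_rate_hz=float(raw.get("sample_rate_hz", 500.0)),
                     resistance_gain=float(ctrl.get("resistance_gain", 0.0)),
                     mass_kg=float(ctrl.get("mass_kg", 82.0)),
                     profile=profile)


def load_config(path=None) -> RunConfig:
    """Load and validate a controller configuration (the shipped default when
    ``path`` is None)."""
    if path is None:
        text = (importlib.resources.files("wfhankle") / "data" / "default.yaml").read_text()
    else:
        with open(path, "r", encoding="utf-8") as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise ConfigError("configuration root must be a mapping")
    return _config_from_mapping(raw)


def default_config() -> RunConfig:
    return load_config(None)


def dump_config(cfg: RunConfig, path) -> None:
    """Write a configuration back to YAML; ``load_config`` of the result
    reproduces identical objects."""
    raw = {
        "sample_rate_hz": cfg.sample_rate_hz,
        "muscle": {
            name: {"P0": p.P0, "kts": p.kts, "kss": p.kss, "Cce_l": p.Cce_l,
                   "Cce_s": p.Cce_s, "L0": p.L0, "fl_width": p.fl_width}
            for name, p in (("anterior", cfg.params_A), ("posterior", cfg.params_P))
        },
        "geometry": {f.name: getattr(cfg.geometry, f.name)
                     for f in dataclasses.fields(AnkleGeometry)},
        "schedule": {
            cfg.profile: {"act_A": {int(k): float(v) for k, v in cfg.schedule.act_A.items()},
                          "act_P": {int(k): float(v) for k, v in cfg.schedule.act_P.items()}},
            "smoothing_s": cfg.schedule.smoothing_s,
        },
        "controller": {"profile": cfg.profile, "resistance_gain": cfg.resistance_gain,
                       "mass_kg": cfg.mass_kg},
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(raw, fh, sort_keys=False)


# ---------------------------------------------------------------- CSV I/O

def write_trajectory(traj: GaitTrajectory, path) -> None:
    """GaitTrajectory CSV: ``time_s,theta_deg,stage`` with an optional
    ``# mass_kg=<value>`` metadata comment line."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if traj.mass_kg is not None:
            fh.write(f"# mass_kg={traj.mass_kg:g}\n")
        pd.DataFrame({"time_s": traj.time_s, "theta_deg": traj.theta_deg,
                      "stage": traj.stage}).to_csv(fh, index=False)


def read_trajectory(path) -> GaitTrajectory:
    mass = None
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline()
        if first.startswith("#"):
            key, _, value = first.lstrip("# ").strip().partition("=")
            if key.strip() == "mass_kg":
                mass = float(value)
            df = pd.read_csv(fh)
        else:
            fh.seek(0)
            df = pd.read_csv(fh)
    return GaitTrajectory(time_s=df["time_s"].to_numpy(),
                          theta_deg=df["theta_deg"].to_numpy(),
                          stage=df["stage"].to_numpy(), mass_kg=mass)


TRACE_COLUMNS = ["time_s", "theta_deg", "stage", "moment_Nm", "moment_Nm_per_kg",
                 "power_W_per_kg", "Fss_A_N", "Fss_P_N"]


def write_moment_trace(trace: MomentTrace, path) -> None:
    """MomentTrace CSV with mass-normalized moment and power columns (NaN
    when no body mass is attached)."""
    if trace.mass_kg is not None:
        per_kg = trace.moment_Nm / trace.mass_kg
        power = ankle_power(trace)
    else:
        per_kg = np.full(len(trace), np.nan)
        power = np.full(len(trace), np.nan)
    df = pd.DataFrame({"time_s": trace.time_s, "theta_deg": trace.theta_deg,
                       "stage": trace.stage, "moment_Nm": trace.moment_Nm,
                       "moment_Nm_per_kg": per_kg, "power_W_per_kg": power,
                       "Fss_A_N": trace.Fss_A_N, "Fss_P_N": trace.Fss_P_N})
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if trace.mass_kg is not None:
            fh.write(f"# mass_kg={trace.mass_kg:g}\n")
        df.to_csv(fh, index=False)


def read_moment_trace(path) -> MomentTrace:
    mass = None
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline()
        if first.startswith("#"):
            key, _, value = first.lstrip("# ").strip().partition("=")
            if key.strip() == "mass_kg":
                mass = float(value)
            df = pd.read_csv(fh)
        else:
            fh.seek(0)
            df = pd.read_csv(fh)
    moment = df["moment_Nm"].to_numpy()
    fa = df["Fss_A_N"].to_numpy()
    fp = df["Fss_P_N"].to_numpy()
    return MomentTrace(time_s=df["time_s"].to_numpy(), theta_deg=df["theta_deg"].to_numpy(),
                       stage=df["stage"].to_numpy(), moment_Nm=moment,
                       moment_A_Nm=np.full(len(df), np.nan),
                       moment_P_Nm=np.full(len(df), np.nan),
                       Fss_A_N=fa, Fss_P_N=fp, mass_kg=mass)
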