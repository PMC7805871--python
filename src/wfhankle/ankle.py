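"""Hinge-ankle musculoskeletal layer and net-moment controller.

Two antagonist virtual muscles span a hinge ankle: an anterior group
(tibialis anterior and synergists, dorsiflexor) and a posterior group
(soleus/gastrocnemius/plantaris lumped, plantarflexor; the biarticular knee
coupling of the gastrocnemius is ignored). Each muscle runs in a straight
line from a shank attachment (``SAL``) to a foot attachment (``FMA``), so its
length follows from the law of cosines on the included shank-foot angle, and
its moment arm is the angular derivative of that length.

Sign conventions: ankle angle ``theta`` is zero with the foot perpendicular
to the shank, dorsiflexion positive, plantarflexion negative. Net ankle
moment is positive in plantarflexion.

A gait-cycle state machine supplies square-wave activation per stage
(2 early swing, 3 late swing, 4 early stance, 5 late stance, 6 powered
plantarflexion): the anterior muscle is active in stages 2-4, the posterior
only in stage 6. The controller's single real-time input is the ankle angle;
everything else (preflex load response, terrain adaptation) emerges from the
muscle model's intrinsic length/velocity dependence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .muscle import (InputDomainError, MuscleParams, ParameterError, _step,
                     init_state)

__all__ = [
    "AnkleGeometry",
    "ActivationSchedule",
    "GaitTrajectory",
    "MomentTrace",
    "GeometryError",
    "STAGES",
    "PROFILES",
    "muscle_lengths",
    "moment_arms",
    "attachment_angles",
    "activation_at",
    "net_ankle_moment",
    "run_controller",
    "neutral_lengths",
]

STAGES = (2, 3, 4, 5, 6)


class GeometryError(ValueError):
    """The ankle configuration leaves the attachment triangle degenerate."""


@dataclass(frozen=True)
class AnkleGeometry:
    """Attachment geometry of the two virtual muscles.

    ``SAL_*``: shank attachment lengths (cm), ``FMA_*``: foot moment arms
    (cm), ``gamma0_*``: included shank-foot angle at the neutral ankle angle
    (degrees; 90 means foot perpendicular to shank). ``constant_moment_arm``
    switches the moment arm from the geometric dL/dtheta to the fixed FMA
    values for comparison.
    """

    SAL_A: float = 29.0
    SAL_P: float = 33.0
    FMA_A: float = 4.0
    FMA_P: float = 5.5
    gamma0_A: float = 90.0
    gamma0_P: float = 90.0
    constant_moment_arm: bool = False

    def __post_init__(self) -> None:
        for name in ("SAL_A", "SAL_P", "FMA_A", "FMA_P"):
            if not getattr(self, name) > 0:
                raise GeometryError(f"{name} must be > 0, got {getattr(self, name)}")
        for name in ("gamma0_A", "gamma0_P"):
            if not 0 < getattr(self, name) < 180:
                raise GeometryError(f"{name} must be in (0, 180) deg, got {getattr(self, name)}")


@dataclass(frozen=True)
class ActivationSchedule:
    """Square-wave activation per gait stage for both muscles.

    ``act_A`` / ``act_P`` map stage labels 2-6 to activation fractions.
    ``smoothing_s`` > 0 applies a linear ramp of that duration at stage
    transitions instead of an instantaneous step (off by default).
    """

    act_A: dict = field(default_factory=dict)
    act_P: dict = field(default_factory=dict)
    profile: str = "profile1"
    smoothing_s: float = 0.0

    def __post_init__(self) -> None:
        for side, table in (("act_A", self.act_A), ("act_P", self.act_P)):
            if set(table) != set(STAGES):
                raise ParameterError(f"{side} must define exactly stages {STAGES}, got {sorted(table)}")
            for stage, a in table.items():
                if not 0.0 <= a <= 1.0:
                    raise ParameterError(
                        f"schedule.{side}[{stage}] must be in [0, 1], got {a}")
        for stage in STAGES:
            if self.act_A[stage] > 0 and self.act_P[stage] > 0:
                raise ParameterError(
                    f"schedule: stage {stage} activates both muscles; the stages are exclusive")
        if self.smoothing_s < 0:
            raise ParameterError(f"smoothing_s must be >= 0, got {self.smoothing_s}")


#: Subject activation presets (anterior stages 2/3/4, posterior stage 6).
PROFILES = {
    "profile1": {"act_A": {2: 0.93, 3: 0.28, 4: 0.31, 5: 0.0, 6: 0.0},
                 "act_P": {2: 0.0, 3: 0.0, 4: 0.0, 5: 0.0, 6: 0.44}},
    "profile2": {"act_A": {2: 0.63, 3: 0.48, 4: 0.51, 5: 0.0, 6: 0.0},
                 "act_P": {2: 0.0, 3: 0.0, 4: 0.0, 5: 0.0, 6: 0.69}},
}


def default_schedule(profile: str = "profile1", smoothing_s: float = 0.0) -> ActivationSchedule:
    if profile not in PROFILES:
        raise ParameterError(f"unknown activation profile {profile!r}")
    p = PROFILES[profile]
    return ActivationSchedule(act_A=dict(p["act_A"]), act_P=dict(p["act_P"]),
                              profile=profile, smoothing_s=smoothing_s)


@dataclass
class GaitTrajectory:
    """Sampled ankle-angle input with per-sample gait-stage labels.

    ``time_s`` strictly increasing (nominally uniform 500 Hz), ``theta_deg``
    the ankle angle (plantarflexion negative), ``stage`` labels from
    {2,3,4,5,6}. ``mass_kg`` enables mass-normalized outputs.
    """

    time_s: np.ndarray
    theta_deg: np.ndarray
    stage: np.ndarray
    mass_kg: float | None = None

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.theta_deg = np.asarray(self.theta_deg, dtype=float)
        self.stage = np.asarray(self.stage, dtype=int)
        n = len(self.time_s)
        if not (len(self.theta_deg) == n == len(self.stage)):
            raise InputDomainError("trajectory channels must share one length")
        if n < 2:
            raise InputDomainError("trajectory needs at least two samples")
        if not np.all(np.diff(self.time_s) > 0):
            raise InputDomainError("trajectory time base must be strictly increasing")
        bad = set(np.unique(self.stage)) - set(STAGES)
        if bad:
            raise InputDomainError(f"unknown gait stage labels {sorted(bad)}")
        if np.any(np.abs(self.theta_deg) >= 90.0):
            raise InputDomainError("|theta| must stay below 90 degrees")
        if self.mass_kg is not None and not self.mass_kg > 0:
            raise InputDomainError(f"mass_kg must be > 0, got {self.mass_kg}")

    def __len__(self) -> int:
        return len(self.time_s)


@dataclass
class MomentTrace:
    """Controller output aligned with its driving trajectory.

    ``moment_Nm`` is the net command (plantarflexion positive); per-muscle
    moments and series forces are kept for inspection.
    """

    time_s: np.ndarray
    theta_deg: np.ndarray
    stage: np.ndarray
    moment_Nm: np.ndarray
    moment_A_Nm: np.ndarray
    moment_P_Nm: np.ndarray
    Fss_A_N: np.ndarray
    Fss_P_N: np.ndarray
    mass_kg: float | None = None

    @property
    def moment_Nm_per_kg(self) -> np.ndarray:
        if self.mass_kg is None:
            raise ParameterError("mass_kg is required for mass-normalized moment")
        return self.moment_Nm / self.mass_kg

    def __len__(self) -> int:
        return len(self.time_s)


def _gammas(theta, geom: AnkleGeometry):
    """Included shank-foot angles (deg) for both muscles at ankle angle theta."""
    theta = np.asarray(theta, dtype=float)
    if np.any(np.abs(theta) >= 90.0):
        raise InputDomainError("|theta| must be below 90 degrees")
    gA = geom.gamma0_A - theta   # plantarflexion opens the anterior triangle
    gP = geom.gamma0_P + theta   # dorsiflexion opens the posterior triangle
    for g, side in ((gA, "anterior"), (gP, "posterior")):
        if np.any(g <= 0) or np.any(g >= 180):
            raise GeometryError(f"{side} included angle out of (0, 180) deg")
    return gA, gP


def muscle_lengths(theta, geom: AnkleGeometry):
    """Straight-line muscle-tendon lengths (cm) by the law of cosines.

    Anterior and posterior lengths change in opposite directions with theta:
    plantarflexion stretches the anterior muscle and slackens the posterior.
    """
    gA, gP = _gammas(theta, geom)
    LA = np.sqrt(geom.SAL_A**2 + geom.FMA_A**2
                 - 2 * geom.SAL_A * geom.FMA_A * np.cos(np.radians(gA)))
    LP = np.sqrt(geom.SAL_P**2 + geom.FMA_P**2
                 - 2 * geom.SAL_P * geom.FMA_P * np.cos(np.radians(gP)))
    return LA, LP


def moment_arms(theta, geom: AnkleGeometry):
    """Moment arms (cm) of both muscles about the ankle.

    Geometric mode (default): ``r = |dLm/dtheta| = SAL*FMA*sin(gamma)/Lm``
    with theta in radians, identical to the perpendicular distance from the
    joint to the muscle line. Constant mode returns the fixed FMA values.
    """
    if geom.constant_moment_arm:
        shape = np.shape(np.asarray(theta, dtype=float))
        return (np.broadcast_to(geom.FMA_A, shape).copy() if shape else geom.FMA_A,
                np.broadcast_to(geom.FMA_P, shape).copy() if shape else geom.FMA_P)
    gA, gP = _gammas(theta, geom)
    LA, LP = muscle_lengths(theta, geom)
    rA = geom.SAL_A * geom.FMA_A * np.sin(np.radians(gA)) / LA
    rP = geom.SAL_P * geom.FMA_P * np.sin(np.radians(gP)) / LP
    return rA, rP


def attachment_angles(theta, geom: AnkleGeometry):
    """Muscle-line attachment angles at the shank (degrees), by the law of cosines.

    For each muscle, the angle between the muscle line and the shank segment
    at the shank attachment; with the foot-side angle it completes the
    attachment triangle (the three angles sum to 180 degrees).
    """
    LA, LP = muscle_lengths(theta, geom)
    alpha = np.degrees(np.arccos(
        (geom.SAL_A**2 + LA**2 - geom.FMA_A**2) / (2 * geom.SAL_A * LA)))
    beta = np.degrees(np.arccos(
        (geom.SAL_P**2 + LP**2 - geom.FMA_P**2) / (2 * geom.SAL_P * LP)))
    return alpha, beta


def neutral_lengths(geom: AnkleGeometry):
    """Muscle-tendon lengths at the neutral ankle angle; used as the optimal
    lengths of the two virtual muscles so that quiet stance sits on the
    force-length plateau."""
    return muscle_lengths(0.0, geom)


def activation_at(stage: int, schedule: ActivationSchedule):
    """Square-wave activation pair ``(act_A, act_P)`` for a gait stage."""
    if stage not in schedule.act_A:
        raise InputDomainError(f"unknown gait stage {stage!r}")
    return schedule.act_A[stage], schedule.act_P[stage]


def net_ankle_moment(Fss_A: float, Fss_P: float, theta: float, geom: AnkleGeometry) -> float:
    """Net ankle moment in N*m, plantarflexion positive.

    ``M = (Fss_P*r_P - Fss_A*r_A)/100`` (cm to m); muscles can only pull, so
    negative input forces are rejected.
    """
    if Fss_A < 0 or Fss_P < 0:
        raise InputDomainError("muscle forces must be non-negative (muscles pull only)")
    rA, rP = moment_arms(theta, geom)
    return (Fss_P * rP - Fss_A * rA) / 100.0


def _slew_limit(act: np.ndarray, dt: float, window: float) -> np.ndarray:
    """Linear ramp at stage transitions: activation may change by at most
    (full scale step)/window per second toward its square-wave target."""
    if window <= 0:
        return act
    out = np.empty_like(act)
    out[0] = act[0]
    max_step = dt / window  # full-scale transition spread over `window` seconds
    for i in range(1, len(act)):
        delta = np.clip(act[i] - out[i - 1], -max_step, max_step)
        out[i] = out[i - 1] + delta
    return out


def run_controller(traj: GaitTrajectory, params_A: MuscleParams, params_P: MuscleParams,
                   geom: AnkleGeometry, schedule: ActivationSchedule,
                   resistance_gain: float = 0.0) -> MomentTrace:
    """Run the two-muscle torque controller over an ankle-angle trajectory.

    Per sample: muscle lengths from the geometry, activations from the stage
    schedule, one 500 Hz Euler step per muscle, net moment from the series
    forces and moment arms, plus an optional viscous compensation term
    ``resistance_gain * theta_dot`` (N*m*s/deg; default 0, pure model
    output). One parameter set serves every terrain - nothing here depends
    on whether the trajectory is level walking, stairs, or a transition.

    A slack series spring transmits no force: negative series-spring values
    are clamped to zero before the moment computation.
    """
    theta = traj.theta_deg
    n = len(traj)
    dt_all = np.diff(traj.time_s)
    dt = float(np.median(dt_all))
    LA, LP = muscle_lengths(theta, geom)
    rA, rP = moment_arms(theta, geom)
    if geom.constant_moment_arm:
        rA = np.broadcast_to(rA, theta.shape)
        rP = np.broadcast_to(rP, theta.shape)
    aA = np.array([schedule.act_A[s] for s in traj.stage])
    aP = np.array([schedule.act_P[s] for s in traj.stage])
    if schedule.smoothing_s > 0:
        aA = _slew_limit(aA, dt, schedule.smoothing_s)
        aP = _slew_limit(aP, dt, schedule.smoothing_s)

    sA = init_state(params_A, float(LA[0]))
    sP = init_state(params_P, float(LP[0]))
    stA = (sA.t, sA.Xce, sA.Xp, sA.Xts)
    stP = (sP.t, sP.Xce, sP.Xp, sP.Xts)
    FA = np.zeros(n)
    FP = np.zeros(n)
    for i in range(1, n):
        h = float(dt_all[i - 1])
        try:
            tA, xceA, xpA, xtsA, _, _ = _step(*stA, float(LA[i]), float(aA[i]), h, params_A)
            tP, xceP, xpP, xtsP, _, _ = _step(*stP, float(LP[i]), float(aP[i]), h, params_P)
        except Exception as exc:  # pragma: no cover - defensive wrapper
            raise type(exc)(f"sample {i}: {exc}") from exc
        stA = (tA, xceA, xpA, xtsA)
        stP = (tP, xceP, xpP, xtsP)
        FA[i] = params_A.kss * (LA[i] - xpA)
        FP[i] = params_P.kss * (LP[i] - xpP)
        if not (np.isfinite(FA[i]) and np.isfinite(FP[i])):
            side = "anterior" if not np.isfinite(FA[i]) else "posterior"
            raise ArithmeticError(f"non-finite series force in {side} muscle at sample {i}")
    FA = np.maximum(FA, 0.0)
    FP = np.maximum(FP, 0.0)
    mA = -FA * rA / 100.0
    mP = FP * rP / 100.0
    moment = mA + mP
    if resistance_gain != 0.0:
        theta_dot = np.gradient(theta, traj.time_s)
        moment = moment + resistance_gain * theta_dot
    return MomentTrace(time_s=traj.time_s.copy(), theta_deg=theta.copy(),
                       stage=traj.stage.copy(), moment_Nm=moment,
                       moment_A_Nm=mA, moment_P_Nm=mP, Fss_A_N=FA, Fss_P_N=FP,
                       mass_kg=traj.mass_kg)
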