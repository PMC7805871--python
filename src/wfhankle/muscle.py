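"""Winding-filament muscle-tendon unit.

A lumped muscle model in which the giant protein titin acts as an
activation-tunable spring. The contractile element (CE, the cross-bridge
ensemble) pulls on a massless pulley (the thin filaments); activation winds
the titin spring (``kts``) onto the pulley, while applied length changes
translate the pulley against a linear series spring (``kss``, the
tendon/aponeurosis). A viscous damper in parallel with the CE, with distinct
lengthening and shortening coefficients, stands in for the force-velocity
relation. Because titin strain is carried as state, the unit exhibits the
history dependence of real muscle: force enhancement after active stretch and
force depression after active shortening.

State update runs as explicit Euler at a fixed 500 Hz control rate. The
contractile force is

    Fce = act(t) * fl(Xm) * P0

with ``fl`` a parabola equal to 1 at optimal length L0. The CE velocity
follows from superposing the rotational and translational force balances
about the pulley:

    vce = [kts*Xts - Fce]/Cce + [kss*(Xm - Xp) - Fce - kts*Xts]/Cce

The internal closure advances the pulley position and titin strain with the
rates ``vp = (Fss - Fce - Fts)/Cce`` (translational balance) and
``vts = (Fss - 2*Fts)/Cce`` (pulley translation plus winding); at equilibrium
these recover ``kts*Xts = Fce`` and ``Fss = 2*Fce``.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

DEFAULT_RATE_HZ = 500.0
DEFAULT_DT = 1.0 / DEFAULT_RATE_HZ

__all__ = [
    "MuscleParams",
    "MuscleState",
    "InputDomainError",
    "ParameterError",
    "NumericalFailure",
    "force_length",
    "contractile_force",
    "ce_velocity",
    "select_damping",
    "init_state",
    "advance_state",
    "oracle_advance",
    "run_isometric",
    "run_ramp_hold",
    "history_dependence",
    "trace_to_csv",
    "TRACE_COLUMNS",
]


class InputDomainError(ValueError):
    """An input lies outside the operation's physical domain."""


class ParameterError(ValueError):
    """A model parameter is invalid."""


class NumericalFailure(ArithmeticError):
    """A state quantity became non-finite during integration."""


@dataclass(frozen=True)
class MuscleParams:
    """Constants of one virtual muscle.

    Parameters
    ----------
    name : text label (e.g. ``"anterior"``).
    P0 : peak isometric force, N.
    kts : titin spring constant, N/cm.
    kss : series (tendon) spring constant, N/cm.
    Cce_l : CE damping coefficient during lengthening, N*s/cm.
    Cce_s : CE damping coefficient during shortening, N*s/cm.
    L0 : optimal muscle-tendon length, cm.
    fl_width : half-width of the force-length parabola as a fraction of L0.
    """

    name: str
    P0: float
    kts: float
    kss: float
    Cce_l: float
    Cce_s: float
    L0: float
    fl_width: float = 0.5

    def __post_init__(self) -> None:
        for field in ("P0", "kts", "kss", "Cce_l", "Cce_s", "L0"):
            if not getattr(self, field) > 0:
                raise ParameterError(f"{self.name}.{field} must be > 0, got {getattr(self, field)}")
        if not 0 < self.fl_width <= 1:
            raise ParameterError(f"{self.name}.fl_width must be in (0, 1], got {self.fl_width}")


@dataclass(frozen=True)
class MuscleState:
    """Evolving internal state of one muscle-tendon unit.

    ``Fts = kts*Xts`` and ``Fss = kss*(Xm - Xp)`` hold exactly at all times;
    ``Xts >= 0`` (the titin spring cannot be wound below slack).
    """

    t: float        # time, s
    Xm: float       # muscle-tendon length input, cm
    Xce: float      # contractile-element displacement, cm
    Xp: float       # pulley translation, cm
    Xts: float      # titin spring elongation, cm
    vce: float      # CE velocity, cm/s
    Fce: float      # contractile force, N
    Fts: float      # titin force, N
    Fss: float      # series-spring (output) force, N
    act: float      # activation in [0, 1]


def force_length(Xm: float, params: MuscleParams) -> float:
    """Active force-length factor in [0, 1].

    A symmetric parabola with its plateau value 1 at ``L0``, reaching zero at
    a strain of ``fl_width`` on either side, clipped at zero beyond.
    """
    if not Xm > 0:
        raise InputDomainError(f"muscle length must be positive, got {Xm}")
    z = (Xm - params.L0) / (params.fl_width * params.L0)
    return max(0.0, 1.0 - z * z)


def contractile_force(act: float, Xm: float, params: MuscleParams) -> float:
    """Contractile-element force ``Fce = act * fl(Xm) * P0`` in N."""
    if not 0.0 <= act <= 1.0:
        raise ParameterError(f"activation must be in [0, 1], got {act}")
    return act * force_length(Xm, params) * params.P0


def ce_velocity(state: MuscleState, Fce: float, Cce: float, params: MuscleParams) -> float:
    """CE velocity from superposition of the rotational and translational balances.

    ``[kts*Xts - Fce]/Cce + [kss*(Xm - Xp) - Fce - kts*Xts]/Cce``; the titin
    terms cancel, so this equals ``(kss*(Xm - Xp) - 2*Fce)/Cce``.
    """
    if not Cce > 0:
        raise ParameterError(f"damping coefficient must be > 0, got {Cce}")
    Fts = params.kts * state.Xts
    Fss = params.kss * (state.Xm - state.Xp)
    return (Fts - Fce) / Cce + (Fss - Fce - Fts) / Cce


def select_damping(vce: float, params: MuscleParams) -> float:
    """Directional damping coefficient: lengthening for ``vce >= 0``, else shortening.

    Any velocity-signed quantity may be passed; the caller in
    :func:`advance_state` supplies the current-step superposition numerator
    ``kss*(Xm - Xp) - 2*Fce``, whose sign equals the sign of the current CE
    velocity and does not depend on the coefficient being selected.
    """
    return params.Cce_l if vce >= 0 else params.Cce_s


def init_state(params: MuscleParams, Xm0: float) -> MuscleState:
    """Passive rest state at length ``Xm0``: all springs slack, all forces zero."""
    if not Xm0 > 0:
        raise InputDomainError(f"initial length must be positive, got {Xm0}")
    return MuscleState(t=0.0, Xm=Xm0, Xce=0.0, Xp=Xm0, Xts=0.0,
                       vce=0.0, Fce=0.0, Fts=0.0, Fss=0.0, act=0.0)


def _rates(Xts: float, Xp: float, Xm: float, act: float, params: MuscleParams):
    """Force set and state rates at a given configuration.

    Returns ``(Fce, Fss_pre, vce, vp, vts)`` where ``Fss_pre`` is the series
    force before the pulley moves. The titin rate is the sum of the pulley
    translation rate and the winding rate ``(Fce - Fts)/Cce`` (the negative
    of the rotational-balance CE velocity): activation winds titin on, a
    force drop lets it unwind, and no extra rate constant is introduced.
    """
    Fce = act * max(0.0, 1.0 - ((Xm - params.L0) / (params.fl_width * params.L0)) ** 2) * params.P0
    Fss = params.kss * (Xm - Xp)
    Fts = params.kts * Xts
    numerator = Fss - 2.0 * Fce  # = Cce * vce, sign-equivalent to vce
    Cce = params.Cce_l if numerator >= 0 else params.Cce_s
    vce = (Fts - Fce) / Cce + (Fss - Fce - Fts) / Cce
    vp = (Fss - Fce - Fts) / Cce
    vts = (Fss - 2.0 * Fts) / Cce
    return Fce, Fss, vce, vp, vts


def _step(t, Xce, Xp, Xts, Xm_next, act_next, dt, params):
    """One explicit Euler step on the raw state tuple (no dataclass overhead)."""
    Fce, _, vce, vp, vts = _rates(Xts, Xp, Xm_next, act_next, params)
    Xce += vce * dt
    Xp += vp * dt
    Xts = max(0.0, Xts + vts * dt)
    return t + dt, Xce, Xp, Xts, vce, Fce


def advance_state(state: MuscleState, Xm_next: float, act_next: float,
                  dt: float = DEFAULT_DT, params: MuscleParams = None) -> MuscleState:
    """One explicit Euler step of the muscle unit.

    The interval rates are evaluated at the new length/activation input and
    the previous internal state: contractile force from the force-length
    relation at ``Xm_next``; the damping coefficient from the sign of the
    current superposition numerator; then pulley translation, titin strain
    (clipped at slack) and CE displacement are advanced, and the derived
    forces recomputed.
    """
    if params is None:
        raise ParameterError("params is required")
    if not dt > 0:
        raise ParameterError(f"dt must be > 0, got {dt}")
    if not 0.0 <= act_next <= 1.0:
        raise ParameterError(f"activation must be in [0, 1], got {act_next}")
    if not Xm_next > 0:
        raise InputDomainError(f"muscle length must be positive, got {Xm_next}")

    t, Xce, Xp, Xts, vce, Fce = _step(state.t, state.Xce, state.Xp, state.Xts,
                                      Xm_next, act_next, dt, params)
    new = MuscleState(t=t, Xm=Xm_next, Xce=Xce, Xp=Xp, Xts=Xts, vce=vce,
                      Fce=Fce, Fts=params.kts * Xts,
                      Fss=params.kss * (Xm_next - Xp), act=act_next)
    for name in ("Xce", "Xp", "Xts", "vce", "Fce", "Fts", "Fss"):
        if not math.isfinite(getattr(new, name)):
            raise NumericalFailure(f"state quantity {name!r} became non-finite at t={t:.6f} s")
    return new


def oracle_advance(state: MuscleState, Xm_next: float, act_next: float,
                   dt: float = DEFAULT_DT, params: MuscleParams = None,
                   refinement: int = 1) -> MuscleState:
    """Sub-stepped reference update for verifying the 500 Hz Euler step.

    The interval is divided into ``refinement`` sub-steps with the length
    input interpolated linearly from ``state.Xm`` to ``Xm_next``; activation
    is a piecewise-constant command and is held at ``act_next`` throughout.
    ``refinement=1`` reproduces :func:`advance_state` bit-for-bit.
    """
    if refinement < 1:
        raise ParameterError(f"refinement must be >= 1, got {refinement}")
    if refinement == 1:
        return advance_state(state, Xm_next, act_next, dt, params)
    sub = dt / refinement
    out = state
    x0 = state.Xm
    for j in range(1, refinement + 1):
        xm = Xm_next if j == refinement else x0 + (Xm_next - x0) * j / refinement
        out = advance_state(out, xm, act_next, sub, params)
    return dataclasses.replace(out, t=state.t + dt)


TRACE_COLUMNS = ["time_s", "Xm_cm", "act", "Fce_N", "Fts_N", "Fss_N",
                 "Xce_cm", "Xp_cm", "Xts_cm"]


def _run_protocol(params: MuscleParams, Xm_of_i, act_of_i, n_steps: int,
                  dt: float = DEFAULT_DT) -> pd.DataFrame:
    """Drive a muscle from rest with per-sample length/activation callables."""
    t, Xce, Xp, Xts = 0.0, 0.0, float(Xm_of_i(0)), 0.0
    rows = np.empty((n_steps + 1, 9))
    rows[0] = (0.0, Xp, act_of_i(0), 0.0, 0.0, 0.0, 0.0, Xp, 0.0)
    for i in range(1, n_steps + 1):
        xm, a = float(Xm_of_i(i)), float(act_of_i(i))
        t, Xce, Xp, Xts, vce, Fce = _step(t, Xce, Xp, Xts, xm, a, dt, params)
        rows[i] = (t, xm, a, Fce, params.kts * Xts, params.kss * (xm - Xp), Xce, Xp, Xts)
    if not np.isfinite(rows).all():
        bad = [c for c, ok in zip(TRACE_COLUMNS, np.isfinite(rows).all(axis=0)) if not ok]
        raise NumericalFailure(f"non-finite trace quantities: {bad}")
    return pd.DataFrame(rows, columns=TRACE_COLUMNS)


def run_isometric(params: MuscleParams, act: float, Xm: float,
                  duration: float, dt: float = DEFAULT_DT) -> pd.DataFrame:
    """Fixed-end contraction from rest: constant activation at constant length.

    Returns the full 500 Hz force trace; ``Fss`` develops monotonically to
    its steady value ``2*Fce``.
    """
    if not duration > 0:
        raise ParameterError(f"duration must be > 0, got {duration}")
    if not 0.0 <= act <= 1.0:
        raise ParameterError(f"activation must be in [0, 1], got {act}")
    if not Xm > 0:
        raise InputDomainError(f"muscle length must be positive, got {Xm}")
    n = int(round(duration / dt))
    return _run_protocol(params, lambda i: Xm, lambda i: act, n, dt)


def run_ramp_hold(params: MuscleParams, act: float, Xm0: float, velocity: float,
                  amplitude: float, hold: float, settle: float = 2.0,
                  measure_after: float = 1.0, dt: float = DEFAULT_DT):
    """Isokinetic ramp-hold protocol probing history-dependent force.

    The muscle is activated at ``Xm0`` and allowed to develop force for
    ``settle`` seconds, then stretched (``amplitude > 0``) or shortened
    (``amplitude < 0``) at constant ``velocity`` (cm/s, magnitude) to
    ``Xm0 + amplitude``, and held there for ``hold`` seconds.

    Returns ``(trace, post_force)`` where ``post_force`` is ``Fss`` measured
    ``measure_after`` seconds after the end of the ramp (clamped to the end
    of the hold). After an active stretch this force sits above the purely
    isometric force at the same final length (residual force enhancement);
    after shortening, below it (force depression).
    """
    if amplitude == 0.0:
        trace = run_isometric(params, act, Xm0, settle + hold, dt)
        i = min(len(trace) - 1, int(round((settle + measure_after) / dt)))
        return trace, float(trace["Fss_N"].iloc[i])
    if not velocity > 0:
        raise ParameterError("a nonzero amplitude requires a positive ramp velocity")
    if not hold > 0:
        raise ParameterError(f"hold must be > 0, got {hold}")
    ramp = abs(amplitude) / velocity
    n_settle = int(round(settle / dt))
    n_ramp = int(round(ramp / dt))
    n_hold = int(round(hold / dt))

    def Xm_of_i(i):
        if i <= n_settle:
            return Xm0
        if i <= n_settle + n_ramp:
            return Xm0 + amplitude * (i - n_settle) / n_ramp
        return Xm0 + amplitude

    trace = _run_protocol(params, Xm_of_i, lambda i: act, n_settle + n_ramp + n_hold, dt)
    i_meas = min(len(trace) - 1, n_settle + n_ramp + int(round(measure_after / dt)))
    return trace, float(trace["Fss_N"].iloc[i_meas])


def history_dependence(params: MuscleParams, act: float = 0.5,
                       amplitude_fracs=(0.02, 0.05, 0.10), ramp_duration: float = 0.5,
                       settle: float = 2.0, measure_after: float = 1.0) -> pd.DataFrame:
    """Stretch/shorten grid with a common final length ``L0``.

    Every ramp ends at the optimal length so that a single isometric
    contraction at ``L0`` serves as the reference; ramps share a fixed
    duration (velocity scales with amplitude) so the amplitudes are probed
    over the same recent-history window. Returns one row per protocol with
    the post-hold force and the isometric reference.
    """
    iso = run_isometric(params, act, params.L0, settle + ramp_duration + measure_after + 0.5)
    ref = float(iso["Fss_N"].iloc[-1])
    rows = []
    for frac in amplitude_fracs:
        for sign, label in ((+1, "stretch"), (-1, "shorten")):
            amp = sign * frac * params.L0
            _, post = run_ramp_hold(params, act, Xm0=params.L0 - amp,
                                    velocity=abs(amp) / ramp_duration, amplitude=amp,
                                    hold=measure_after + 0.5, settle=settle,
                                    measure_after=measure_after)
            rows.append((label, frac, post, ref, post - ref))
    return pd.DataFrame(rows, columns=["protocol", "amplitude_frac", "post_force_N",
                                       "isometric_N", "delta_N"])


def trace_to_csv(trace: pd.DataFrame, path) -> None:
    """Write a force trace CSV with the canonical column order."""
    trace.loc[:, TRACE_COLUMNS].to_csv(path, index=False)
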