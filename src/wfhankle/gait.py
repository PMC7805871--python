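"""Seeded synthetic ankle-angle trajectories with gait-stage labels.

The generator emulates the qualitative sagittal ankle kinematics of level
walking and step-over-step stair ascent so that the controller can be
exercised without recorded data. Waveforms are shape-preserving piecewise
cubics (PCHIP) through named control points per gait cycle; because PCHIP is
monotone between knots, a control point placed at a peak IS the peak - the
configured plantarflexion extremum is hit exactly when noise is off.

Level walking (heel strike at 0% cycle): a small controlled-plantarflexion
dip in early stance, dorsiflexion building through mid-stance as the shank
rolls over the foot, a plantarflexion peak around toe-off (defaults -8, -13
and -19 degrees for the slow/medium/fast speed classes), then a gradual
dorsiflexing swing return for toe clearance.

Stair ascent: two controlled-dorsiflexion/plantarflexion excursions per step
cycle - the first pair pulls the body up from the previous step, the second
pushes it up to the next one - with an overall plantarflexion peak that is
larger (default -17 degrees) and later in the cycle than in level walking.

Stage labels follow cycle fraction, not torque thresholds: 4 (early stance),
5 (late stance), 6 (powered plantarflexion), 2 (early swing), 3 (late
swing), with stance ending at the stance fraction (default 60%) and the
4->5, 5->6 boundaries at 50% and 75% of stance.

Stride-to-stride variability is seeded Gaussian jitter on the interior
control-point angles; heel-strike samples stay at the nominal angle so that
cycle joins remain continuous. Noise SD 0 gives strictly periodic output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import PchipInterpolator

from .ankle import GaitTrajectory
from .muscle import DEFAULT_RATE_HZ, ParameterError

__all__ = [
    "GaitShapeParams",
    "LEVEL_CLASSES",
    "make_level_walking",
    "make_stair_ascent",
    "make_transition_bout",
]

#: default body mass, kg (adult male wearing the prosthesis)
DEFAULT_MASS_KG = 82.0


@dataclass(frozen=True)
class GaitShapeParams:
    """Control points of one synthetic gait cycle.

    ``control_fracs``/``control_degs`` are the interior knots (cycle
    fraction, ankle angle in degrees) between the heel-strike anchors at 0%
    and 100% (both at ``hs_deg``). ``peak_plantarflexion_deg`` must be the
    minimum of the control angles; it is exposed separately because it is
    the headline kinematic parameter. ``stair`` flags the double
    pull-up/push-off shape.
    """

    cycle_s: float
    control_fracs: tuple
    control_degs: tuple
    peak_plantarflexion_deg: float
    stance_fraction: float = 0.60
    hs_deg: float = 0.0
    stair: bool = False
    noise_sd_deg: float = 0.3

    def __post_init__(self) -> None:
        if not 0 < self.stance_fraction < 1:
            raise ParameterError(f"stance_fraction must be in (0, 1), got {self.stance_fraction}")
        if not -30.0 <= self.peak_plantarflexion_deg <= 0.0:
            raise ParameterError(
                f"peak plantarflexion must be in [-30, 0] deg, got {self.peak_plantarflexion_deg}")
        if self.noise_sd_deg < 0:
            raise ParameterError(f"noise SD must be >= 0, got {self.noise_sd_deg}")
        if len(self.control_fracs) != len(self.control_degs):
            raise ParameterError("control_fracs and control_degs must pair up")
        if not all(0 < f < 1 for f in self.control_fracs):
            raise ParameterError("interior control fractions must lie in (0, 1)")
        if list(self.control_fracs) != sorted(self.control_fracs):
            raise ParameterError("control fractions must be increasing")
        if min(self.control_degs) != self.peak_plantarflexion_deg:
            raise ParameterError("peak_plantarflexion_deg must equal the most negative control angle")
        if not self.cycle_s > 0:
            raise ParameterError(f"cycle duration must be > 0, got {self.cycle_s}")


def _level_shape(peak_pf: float, cycle_s: float, dorsi_peak: float,
                 early_dip: float, noise_sd: float) -> GaitShapeParams:
    return GaitShapeParams(
        cycle_s=cycle_s,
        control_fracs=(0.08, 0.48, 0.60, 0.85, 0.95),
        control_degs=(early_dip, dorsi_peak, peak_pf, 0.5, 0.2),
        peak_plantarflexion_deg=peak_pf,
        noise_sd_deg=noise_sd,
    )


#: speed-class presets for level walking (nominal 0.75/1.25/1.65 m/s)
LEVEL_CLASSES = {
    "slow": dict(peak_pf=-8.0, cycle_s=1.40, dorsi_peak=8.0, early_dip=-3.0),
    "medium": dict(peak_pf=-13.0, cycle_s=1.15, dorsi_peak=10.0, early_dip=-5.0),
    "fast": dict(peak_pf=-19.0, cycle_s=0.95, dorsi_peak=11.0, early_dip=-6.0),
}


def _stair_shape(cadence: float, peak_pf: float = -17.0, pullup_dorsi: float = 9.0,
                 pullup_pf: float = -5.0, dorsi_peak: float = 12.0,
                 noise_sd: float = 0.3) -> GaitShapeParams:
    # step-over-step: one full cycle of the instrumented leg spans two steps
    cycle_s = 2.0 * 60.0 / cadence
    return GaitShapeParams(
        cycle_s=cycle_s,
        control_fracs=(0.10, 0.24, 0.50, 0.70, 0.90),
        control_degs=(pullup_dorsi, pullup_pf, dorsi_peak, peak_pf, 0.5),
        peak_plantarflexion_deg=peak_pf,
        stair=True,
        noise_sd_deg=noise_sd,
    )


def _stage_labels(frac: np.ndarray, stance_fraction: float) -> np.ndarray:
    """Stage per cycle fraction: 4,5,6 split stance at 50%/75%, 2,3 halve swing."""
    sf = stance_fraction
    bounds = (0.0, 0.50 * sf, 0.75 * sf, sf, sf + 0.5 * (1 - sf), 1.0)
    labels = (4, 5, 6, 2, 3)
    stage = np.empty(len(frac), dtype=int)
    for lab, lo, hi in zip(labels, bounds, bounds[1:]):
        stage[(frac >= lo) & (frac < hi)] = lab
    return stage


def _cycle_spline(shape: GaitShapeParams, jitter: np.ndarray) -> PchipInterpolator:
    """Periodic PCHIP over one cycle: knots tiled to [-1, 2] so the
    interpolant is C1 across the heel-strike wrap."""
    fr = np.asarray((0.0,) + shape.control_fracs, dtype=float)
    th = np.asarray((shape.hs_deg,) + tuple(
        d + j for d, j in zip(shape.control_degs, jitter)), dtype=float)
    f3 = np.concatenate([fr - 1.0, fr, fr + 1.0])
    t3 = np.tile(th, 3)
    return PchipInterpolator(f3, t3)


def _synthesize(shape: GaitShapeParams, n_cycles: int, rng: np.random.Generator,
                rate_hz: float = DEFAULT_RATE_HZ, mass_kg: float = DEFAULT_MASS_KG,
                t0: float = 0.0) -> GaitTrajectory:
    n = int(round(shape.cycle_s * rate_hz))
    frac = np.arange(n) / n
    theta = np.empty(n_cycles * n)
    for c in range(n_cycles):
        jitter = rng.normal(0.0, shape.noise_sd_deg, size=len(shape.control_degs)) \
            if shape.noise_sd_deg > 0 else np.zeros(len(shape.control_degs))
        theta[c * n:(c + 1) * n] = _cycle_spline(shape, jitter)(frac)
    stage = np.tile(_stage_labels(frac, shape.stance_fraction), n_cycles)
    time = t0 + np.arange(n_cycles * n) / rate_hz
    return GaitTrajectory(time_s=time, theta_deg=theta, stage=stage, mass_kg=mass_kg)


def make_level_walking(speed_class: str = "medium", n_strides: int = 8,
                       shape: GaitShapeParams | None = None, seed: int = 0,
                       mass_kg: float = DEFAULT_MASS_KG) -> GaitTrajectory:
    """Synthetic level-walking bout at one of three nominal speed classes.

    The plantarflexion peak deepens and the stride shortens with speed
    (defaults -8/-13/-19 degrees at 1.40/1.15/0.95 s per stride). Fixed
    ``seed`` gives byte-identical output.
    """
    if n_strides < 1:
        raise ParameterError(f"n_strides must be >= 1, got {n_strides}")
    if shape is None:
        if speed_class not in LEVEL_CLASSES:
            raise ParameterError(f"unknown speed class {speed_class!r}; "
                                 f"choose from {sorted(LEVEL_CLASSES)}")
        kw = LEVEL_CLASSES[speed_class]
        shape = _level_shape(kw["peak_pf"], kw["cycle_s"], kw["dorsi_peak"],
                             kw["early_dip"], noise_sd=0.3)
    rng = np.random.default_rng(seed)
    return _synthesize(shape, n_strides, rng, mass_kg=mass_kg)


def make_stair_ascent(cadence: float = 80.0, n_steps: int = 6,
                      shape: GaitShapeParams | None = None, seed: int = 0,
                      mass_kg: float = DEFAULT_MASS_KG) -> GaitTrajectory:
    """Synthetic step-over-step stair-ascent bout.

    Each step cycle carries two dorsiflexion/plantarflexion excursions (pull
    up from the previous step, push up to the next) and a plantarflexion
    peak that is deeper and later in the cycle than in level walking.
    ``cadence`` is in steps/min; one cycle of the instrumented leg spans two
    steps.
    """
    if n_steps < 1:
        raise ParameterError(f"n_steps must be >= 1, got {n_steps}")
    if not cadence > 0:
        raise ParameterError(f"cadence must be > 0, got {cadence}")
    if shape is None:
        shape = _stair_shape(cadence)
    elif not shape.stair:
        raise ParameterError("shape for make_stair_ascent must have stair=True")
    rng = np.random.default_rng(seed)
    return _synthesize(shape, n_steps, rng, mass_kg=mass_kg)


def make_transition_bout(seed: int = 0, level_class: str = "medium",
                         cadence: float = 80.0,
                         mass_kg: float = DEFAULT_MASS_KG) -> GaitTrajectory:
    """Level-to-stairs-to-level bout: 2 level strides, 4 stair steps, 2 level strides.

    All eight cycles run under one configuration; every cycle starts and
    ends at the heel-strike angle, so the concatenated angle signal is
    continuous at the segment joins.
    """
    rng = np.random.default_rng(seed)
    kw = LEVEL_CLASSES[level_class]
    level = _level_shape(kw["peak_pf"], kw["cycle_s"], kw["dorsi_peak"],
                         kw["early_dip"], noise_sd=0.3)
    stair = _stair_shape(cadence)
    parts = []
    t0 = 0.0
    for shape, n_cycles in ((level, 2), (stair, 4), (level, 2)):
        seg = _synthesize(shape, n_cycles, rng, mass_kg=mass_kg, t0=t0)
        t0 = seg.time_s[-1] + 1.0 / DEFAULT_RATE_HZ
        parts.append(seg)
    return GaitTrajectory(
        time_s=np.concatenate([p.time_s for p in parts]),
        theta_deg=np.concatenate([p.theta_deg for p in parts]),
        stage=np.concatenate([p.stage for p in parts]),
        mass_kg=mass_kg,
    )
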