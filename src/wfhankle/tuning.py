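"""Parameter fitting and one-at-a-time sensitivity analysis.

The controller's free constants (peak isometric forces, spring and damping
constants) are fitted to a reference ankle-moment trace by bounded local
optimization of R-squared, mirroring how such controllers are tuned against
recorded ankle torque. Since no recorded torque ships with the package, the
reference used in tests is self-generated (the controller with known
parameters), which turns fitting into a parameter-recovery exercise with an
exact oracle.

The sensitivity scan perturbs every controller constant one at a time over a
wide multiplicative grid (default 0.5% to 250% of nominal) and reports the
R-squared of the perturbed output against the reference, quantifying which
constants the torque profile actually depends on.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import optimize

from .ankle import (ActivationSchedule, AnkleGeometry, GaitTrajectory,
                    MomentTrace, run_controller)
from .muscle import MuscleParams, ParameterError

__all__ = ["FitResult", "rsquared", "fit_parameters", "sensitivity_scan",
           "MUSCLE_PARAM_NAMES", "SCAN_GRID"]

#: tunable per-muscle constants, addressed as e.g. "P0_P" or "Cce_s_A"
MUSCLE_PARAM_NAMES = ("P0", "kts", "kss", "Cce_l", "Cce_s")

#: default one-at-a-time grid, 0.5% to 250% of nominal (1.0 = self-comparison)
SCAN_GRID = (0.005, 0.25, 0.5, 0.75, 1.0, 1.25, 1.5, 2.0, 2.5)


@dataclass(frozen=True)
class FitResult:
    params_A: MuscleParams
    params_P: MuscleParams
    r_squared: float
    n_iter: int
    converged: bool
    seed: int
    fitted: dict


def rsquared(predicted, reference) -> float:
    """Coefficient of determination ``1 - SSE/SST`` of a moment prediction.

    SST is taken about the reference mean; a constant reference leaves the
    statistic undefined and raises.
    """
    predicted = np.asarray(predicted, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if predicted.shape != reference.shape or predicted.ndim != 1 or len(predicted) < 2:
        raise ParameterError("predicted and reference must be equal-length 1-D series (n >= 2)")
    sst = float(np.sum((reference - reference.mean()) ** 2))
    if sst == 0.0:
        raise ParameterError("R^2 is undefined for a constant reference series")
    sse = float(np.sum((predicted - reference) ** 2))
    return 1.0 - sse / sst


def _split_name(name: str):
    stem, _, side = name.rpartition("_")
    if side not in ("A", "P") or stem not in MUSCLE_PARAM_NAMES:
        raise ParameterError(
            f"unknown free parameter {name!r}; use <{'|'.join(MUSCLE_PARAM_NAMES)}>_<A|P>")
    return stem, side


def _apply(params_A: MuscleParams, params_P: MuscleParams, names, values):
    for name, value in zip(names, values):
        stem, side = _split_name(name)
        if side == "A":
            params_A = replace(params_A, **{stem: float(value)})
        else:
            params_P = replace(params_P, **{stem: float(value)})
    return params_A, params_P


def fit_parameters(reference: MomentTrace, traj: GaitTrajectory,
                   free: list[str], bounds: dict, start_A: MuscleParams,
                   start_P: MuscleParams, geom: AnkleGeometry,
                   schedule: ActivationSchedule, seed: int = 0,
                   xtol: float = 1e-6) -> FitResult:
    """Bounded local fit of selected muscle constants to a reference moment trace.

    ``free`` lists parameter names like ``"P0_P"``; ``bounds`` maps each to a
    finite ``(lo, hi)`` interval. The objective is the R-squared of
    :func:`run_controller` output against ``reference.moment_Nm``, maximized
    with a derivative-free bounded local search (Powell) from the supplied
    start; the result is deterministic given the start point. An empty free
    list returns the start unchanged with its R-squared.
    """
    ref = np.asarray(reference.moment_Nm, dtype=float)
    names = list(free)
    for name in names:
        _split_name(name)
        lo, hi = bounds[name]
        if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
            raise ParameterError(f"bounds for {name!r} must be a finite (lo, hi) interval")

    def simulate(values):
        pA, pP = _apply(start_A, start_P, names, values)
        return run_controller(traj, pA, pP, geom, schedule).moment_Nm

    def objective(values):
        try:
            r2 = rsquared(simulate(values), ref)
        except (ArithmeticError, ParameterError, FloatingPointError) as exc:
            warnings.warn(f"objective failed at {dict(zip(names, values))}: {exc}",
                          stacklevel=2)
            return 1e6
        if not np.isfinite(r2):
            return 1e6
        return 1.0 - r2

    if not names:
        r2 = rsquared(run_controller(traj, start_A, start_P, geom, schedule).moment_Nm, ref)
        return FitResult(start_A, start_P, r2, 0, True, seed, {})

    x0 = np.array([getattr(start_A if s == "A" else start_P, stem)
                   for stem, s in map(_split_name, names)])
    res = optimize.minimize(objective, x0, method="Powell",
                            bounds=[tuple(bounds[n]) for n in names],
                            options={"xtol": xtol, "ftol": 1e-12, "maxiter": 200})
    x = np.clip(res.x, [bounds[n][0] for n in names], [bounds[n][1] for n in names])
    best = min((objective(x0), tuple(x0)), (float(res.fun), tuple(x)))[1]
    pA, pP = _apply(start_A, start_P, names, best)
    return FitResult(pA, pP, 1.0 - objective(np.array(best)), int(res.nit),
                     bool(res.success), seed, dict(zip(names, best)))


def _schedule_entries(schedule: ActivationSchedule):
    out = []
    for side, table in (("A", schedule.act_A), ("P", schedule.act_P)):
        for stage in sorted(table):
            if table[stage] > 0:
                out.append((f"Act_{side}{stage}", side, stage, table[stage]))
    return out


def sensitivity_scan(params_A: MuscleParams, params_P: MuscleParams,
                     geom: AnkleGeometry, schedule: ActivationSchedule,
                     traj: GaitTrajectory, reference: MomentTrace | None = None,
                     grid=SCAN_GRID) -> pd.DataFrame:
    """One-at-a-time sensitivity of the moment output to every controller constant.

    Each of the ten muscle constants and each nonzero stage activation is
    scaled by every grid fraction in turn (all else nominal) and the
    controller re-run; rows hold ``(parameter, fraction, r_squared)`` against
    the reference (the nominal output itself when ``reference`` is None, so
    fraction 1.0 scores exactly 1). Perturbations that violate a parameter's
    domain - e.g. an activation scaled above 1 - are recorded with NaN and
    the scan continues.
    """
    grid = sorted(grid)
    if not all(0 < g <= 2.5 for g in grid) or 1.0 not in grid:
        raise ParameterError("grid fractions must lie in (0, 2.5] and include 1.0")
    if reference is None:
        reference = run_controller(traj, params_A, params_P, geom, schedule)
    ref = np.asarray(reference.moment_Nm, dtype=float)

    targets = [(f"{stem}_{side}", stem, side) for side in ("A", "P")
               for stem in MUSCLE_PARAM_NAMES]
    act_targets = _schedule_entries(schedule)
    rows = []
    for name, stem, side in targets:
        nominal = getattr(params_A if side == "A" else params_P, stem)
        for frac in grid:
            try:
                pA, pP = _apply(params_A, params_P, [name], [nominal * frac])
                r2 = rsquared(run_controller(traj, pA, pP, geom, schedule).moment_Nm, ref)
            except (ParameterError, ArithmeticError) as exc:
                warnings.warn(f"{name} x{frac}: {exc}", stacklevel=2)
                r2 = float("nan")
            rows.append((name, frac, r2))
    for name, side, stage, nominal in act_targets:
        for frac in grid:
            try:
                table = dict(schedule.act_A if side == "A" else schedule.act_P)
                table[stage] = nominal * frac
                sched = replace(schedule, **{f"act_{side}": table})
                r2 = rsquared(run_controller(traj, params_A, params_P, geom, sched).moment_Nm, ref)
            except (ParameterError, ArithmeticError) as exc:
                warnings.warn(f"{name} x{frac}: {exc}", stacklevel=2)
                r2 = float("nan")
            rows.append((name, frac, r2))
    return pd.DataFrame(rows, columns=["parameter", "fraction", "r_squared"])
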