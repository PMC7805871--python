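"""Stride segmentation, gait-cycle normalization and per-stride summaries.

Strides run heel strike to heel strike. Since the artifact does not model
ground contact, heel strike is taken at the late-swing to early-stance label
transition (3 -> 4). Each stride is linearly resampled onto 100 equally
spaced points of the gait cycle, and summarized by the peak net ankle moment
(N*m/kg), the peak plantarflexion angle during stance (degrees, negative)
and the peak ankle power (W/kg, signed maximum).

Power uses plantarflexion-positive conventions throughout: the angular
velocity entering ``P = M * omega`` is ``-d(theta)/dt`` in rad/s (theta is
dorsiflexion-positive while the moment is plantarflexion-positive), so the
powered push-off appears as positive (generated) power and controlled
dorsiflexion as negative (absorbed) power.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .ankle import MomentTrace
from .muscle import InputDomainError, ParameterError

__all__ = [
    "StrideMetrics",
    "segment_strides",
    "resample_stride",
    "ankle_power",
    "stride_summary",
    "count_moment_peaks",
]

STANCE_STAGES = (4, 5, 6)


@dataclass(frozen=True)
class StrideMetrics:
    """Per-stride summary of the controller output."""

    stride: int
    peak_moment_Nm_per_kg: float
    peak_plantarflexion_deg: float
    peak_power_W_per_kg: float
    duration_s: float
    sem_flag: bool = False  # set on aggregates computed from a single stride


def segment_strides(trace) -> list[slice]:
    """Heel-strike (3->4 label transition) stride slices of a trajectory or trace.

    Partial leading and trailing cycles are dropped; a trajectory without a
    complete stride yields an empty list with a warning rather than an error.
    """
    stage = np.asarray(trace.stage)
    bounds = list(np.flatnonzero((stage[1:] == 4) & (stage[:-1] == 3)) + 1)
    # a trace that starts in early stance starts at a heel strike, and one
    # that ends in late swing ends exactly one sample before the next one
    if stage[0] == 4:
        bounds = [0] + bounds
    if stage[-1] == 3:
        bounds = bounds + [len(stage)]
    strides = [slice(a, b) for a, b in zip(bounds, bounds[1:])]
    if not strides:
        warnings.warn("no complete heel-strike (3->4) stride found", stacklevel=2)
    return strides


def resample_stride(time_s: np.ndarray, values: np.ndarray, n_points: int = 100) -> np.ndarray:
    """Linear interpolation of one stride onto ``n_points`` equal cycle fractions.

    Endpoints are preserved exactly; affine signals pass through unchanged.
    """
    time_s = np.asarray(time_s, dtype=float)
    values = np.asarray(values, dtype=float)
    if len(time_s) < 2:
        raise InputDomainError("a stride needs at least two samples to resample")
    target = np.linspace(time_s[0], time_s[-1], n_points)
    return np.interp(target, time_s, values)


def ankle_power(trace: MomentTrace) -> np.ndarray:
    """Mass-normalized ankle power, W/kg.

    ``P = (M/mass) * omega_pf`` with the plantarflexion-positive angular
    velocity ``omega_pf = -d(theta)/dt`` (rad/s) from central finite
    differences (one-sided at the ends).
    """
    if trace.mass_kg is None:
        raise ParameterError("ankle power needs the body mass (mass_kg)")
    omega_pf = -np.gradient(np.radians(trace.theta_deg), trace.time_s)
    return trace.moment_Nm / trace.mass_kg * omega_pf


def stride_summary(trace: MomentTrace, mass_kg: float | None = None,
                   strides: list[slice] | None = None):
    """Per-stride metrics plus the aggregate mean and SEM.

    Returns ``(metrics, aggregate)`` where ``metrics`` is a list of
    :class:`StrideMetrics` and ``aggregate`` a DataFrame with ``mean`` and
    ``sem`` rows. With a single stride the SEM is reported as 0 and flagged.
    """
    mass = mass_kg if mass_kg is not None else trace.mass_kg
    if mass is None:
        raise ParameterError("stride summary needs the body mass (mass_kg)")
    if strides is None:
        strides = segment_strides(trace)
    if not strides:
        raise InputDomainError("no complete stride to summarize")
    omega_pf = -np.gradient(np.radians(trace.theta_deg), trace.time_s)
    power = trace.moment_Nm / mass * omega_pf
    metrics = []
    for k, sl in enumerate(strides):
        theta = trace.theta_deg[sl]
        stance = np.isin(trace.stage[sl], STANCE_STAGES)
        metrics.append(StrideMetrics(
            stride=k,
            peak_moment_Nm_per_kg=float(np.max(trace.moment_Nm[sl]) / mass),
            peak_plantarflexion_deg=float(np.min(theta[stance])) if stance.any() else float("nan"),
            peak_power_W_per_kg=float(np.max(power[sl])),
            duration_s=float(trace.time_s[sl.stop - 1] - trace.time_s[sl.start]),
        ))
    cols = ["peak_moment_Nm_per_kg", "peak_plantarflexion_deg",
            "peak_power_W_per_kg", "duration_s"]
    table = pd.DataFrame([[getattr(m, c) for c in cols] for m in metrics], columns=cols)
    mean = table.mean()
    if len(metrics) > 1:
        sem = table.std(ddof=1) / np.sqrt(len(metrics))
        flag = False
    else:
        sem = pd.Series(0.0, index=table.columns)
        flag = True
        warnings.warn("SEM of a single stride reported as 0", stacklevel=2)
    aggregate = pd.DataFrame({"mean": mean, "sem": sem}).T
    aggregate.attrs["single_stride"] = flag
    return metrics, aggregate


def count_moment_peaks(trace: MomentTrace, strides: list[slice] | None = None,
                       rel_threshold: float = 0.20) -> list[int]:
    """Dominant plantarflexion-moment peaks per stride.

    A peak counts when both its height and its prominence reach
    ``rel_threshold`` of the bout's maximum net moment, which separates the
    functional pull-up/push-off peaks from small activation-switching
    ripples. Level walking shows one dominant peak per stride; stair ascent
    shows two.
    """
    if strides is None:
        strides = segment_strides(trace)
    m = trace.moment_Nm
    floor = rel_threshold * float(np.max(m))
    peaks, _ = find_peaks(m, height=floor, prominence=floor)
    return [int(np.sum((peaks >= sl.start) & (peaks < sl.stop))) for sl in strides]
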