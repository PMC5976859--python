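"""Loaded countermovement-jump kinetics from vertical ground reaction force.

The force-plate signal is turned into centre-of-mass (COM) kinematics
by the impulse-momentum route: net GRF (system weight subtracted) over
system mass gives acceleration, integrated (trapezoid) from a
stationary sample to give instantaneous COM velocity.  The concentric
phase runs from the onset of upward motion (first v > 0 after the
countermovement minimum) to take-off (GRF < 5 N).  Per-load concentric
means of force and velocity feed a linear force-velocity (FV) profile
(F0, V0, slope, P0 = F0*V0/4); propulsive means (the sub-phase with
acceleration >= -g) feed the load-velocity model used to prescribe the
training load at a mean propulsive velocity of 1 m/s, and the
15-repetition repeated-jump outcome (mean propulsive power averaged
over the reps).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy import integrate as _integrate
from scipy import stats as _stats

from .errors import (
    DegeneratePhaseError,
    InvalidParameterError,
    InvalidProfileError,
    NoTakeoffError,
    NotQuietError,
)
from .signal import Trace

__all__ = [
    "G",
    "QuietStance",
    "JumpTrial",
    "LoadVelocityModel",
    "FVProfile",
    "system_weight",
    "com_velocity",
    "movement_onset",
    "concentric_phase",
    "concentric_means",
    "propulsive_means",
    "propulsive_from_velocity",
    "analyze_jump",
    "select_best_rep",
    "fit_fv_profile",
    "fit_load_velocity",
    "load_at_velocity",
    "cmj15_summary",
]

#: gravitational acceleration, m/s^2
G = 9.81


class QuietStance(NamedTuple):
    weight_n: float
    sd_n: float


class ExtrapolationWarning(UserWarning):
    """Prescribed load lies outside the range supported by the fit."""


def system_weight(grf: Trace, quiet_window_s: tuple = (0.0, 0.4), max_sd_n: float = 5.0) -> QuietStance:
    """Mean GRF over a quiet-stance window, with a stillness gate.

    Raises :class:`NotQuietError` when the window SD exceeds
    ``max_sd_n`` (the subject was moving).
    """
    i0 = grf.index_at(grf.t0 + quiet_window_s[0])
    i1 = grf.index_at(grf.t0 + quiet_window_s[1])
    if i1 - i0 < 2:
        raise InvalidParameterError("quiet window must span at least two samples")
    seg = grf.samples[i0:i1]
    sd = float(np.std(seg, ddof=1))
    if sd > max_sd_n:
        raise NotQuietError(f"quiet-window SD {sd:.1f} N exceeds {max_sd_n} N")
    return QuietStance(weight_n=float(np.mean(seg)), sd_n=sd)


def com_velocity(grf: Trace, system_mass_kg: float, weight_n: float, start_index: int = 0) -> Trace:
    """COM velocity by trapezoidal integration of net GRF / mass.

    Velocity is zero up to ``start_index`` (the last stationary sample
    before movement).  Adding the same constant to the GRF and to
    ``weight_n`` leaves the result unchanged.
    """
    if system_mass_kg <= 0:
        raise InvalidParameterError("system mass must be positive")
    a = (grf.samples - weight_n) / system_mass_kg
    v = np.zeros_like(a)
    if start_index < grf.n - 1:
        v[start_index:] = _integrate.cumulative_trapezoid(
            a[start_index:], dx=1.0 / grf.fs, initial=0.0
        )
    return grf.with_samples(v, label="com_velocity")


def movement_onset(
    grf: Trace,
    weight_n: float,
    threshold_n: float = 10.0,
    sustain_ms: float = 50.0,
) -> int:
    """Last stationary sample before movement: index just before the
    first |net GRF| > threshold sustained for ``sustain_ms``."""
    dev = np.abs(grf.samples - weight_n) > threshold_n
    ns = max(int(round(sustain_ms / 1000.0 * grf.fs)), 1)
    run = np.convolve(dev.astype(int), np.ones(ns, dtype=int), mode="valid")
    hits = np.nonzero(run == ns)[0]
    if hits.size == 0:
        return 0
    return max(int(hits[0]) - 1, 0)


def concentric_phase(
    grf: Trace,
    velocity: Trace,
    takeoff_threshold_n: float = 5.0,
    search_from: int = 0,
) -> tuple[int, int]:
    """(start, end) indices of the concentric phase.

    Start: first sample after the countermovement minimum velocity
    where v > 0.  End: first subsequent sample with GRF at or below the
    take-off threshold.
    """
    v = velocity.samples
    low = np.nonzero(grf.samples[search_from:] <= takeoff_threshold_n)[0]
    if low.size == 0:
        raise NoTakeoffError("GRF never drops below the take-off threshold")
    takeoff_bound = search_from + int(low[0])
    imin = search_from + int(np.argmin(v[search_from:takeoff_bound]))
    if v[imin] >= 0:
        warnings.warn("no countermovement detected (velocity never negative)")
        imin = search_from
    pos = np.nonzero(v[imin:takeoff_bound] > 0)[0]
    if pos.size == 0:
        raise DegeneratePhaseError("velocity never becomes positive before take-off")
    start = imin + int(pos[0])
    end_rel = np.nonzero(grf.samples[start:] <= takeoff_threshold_n)[0]
    if end_rel.size == 0:
        raise NoTakeoffError("GRF never drops below the take-off threshold after v > 0")
    end = start + int(end_rel[0])
    return start, end


def _phase_guard(start: int, end: int, min_samples: int = 10) -> None:
    if end - start < min_samples:
        raise DegeneratePhaseError(f"phase of {end - start} samples is too short")


def concentric_means(grf: Trace, velocity: Trace, phase: tuple[int, int]):
    """Arithmetic means of force, velocity and instantaneous power
    (force x velocity) over [start, end)."""
    start, end = phase
    _phase_guard(start, end)
    f = grf.samples[start:end]
    v = velocity.samples[start:end]
    return float(np.mean(f)), float(np.mean(v)), float(np.mean(f * v))


def propulsive_means(
    grf: Trace,
    velocity: Trace,
    phase: tuple[int, int],
    system_mass_kg: float,
    g: float = G,
):
    """Means of velocity and power over the propulsive sub-phase
    (acceleration >= -g).  For a force-plate signal this spans the
    whole concentric phase because GRF >= 0 implies a >= -g."""
    start, end = phase
    _phase_guard(start, end)
    a = grf.samples[start:end] / system_mass_kg - g
    mask = a >= -g
    if not np.any(mask):
        raise DegeneratePhaseError("empty propulsive sub-phase")
    f = grf.samples[start:end][mask]
    v = velocity.samples[start:end][mask]
    return float(np.mean(v)), float(np.mean(f * v))


def propulsive_from_velocity(velocity: Trace, moved_mass_kg: float, g: float = G):
    """Propulsive means from a barbell-velocity signal (linear
    transducer): concentric = first contiguous run of v > 0, truncated
    at the first sample where the derived acceleration drops below -g
    (bar release / free fall)."""
    v = velocity.samples
    a = np.gradient(v) * velocity.fs
    pos = np.nonzero(v > 0)[0]
    if pos.size == 0:
        raise DegeneratePhaseError("velocity never positive")
    start = int(pos[0])
    end = velocity.n
    below = np.nonzero(a[start:] < -g)[0]
    if below.size > 0:
        end = start + int(below[0])
    neg = np.nonzero(v[start:end] <= 0)[0]
    if neg.size > 0:
        end = start + int(neg[0])
    _phase_guard(start, end, min_samples=2)
    force = moved_mass_kg * (a[start:end] + g)
    vv = v[start:end]
    return float(np.mean(vv)), float(np.mean(force * vv))


@dataclass(frozen=True)
class JumpTrial:
    """A fully analyzed loaded-jump trial."""

    grf: Trace
    external_load_kg: float
    body_mass_kg: float
    system_mass_kg: float
    weight_n: float
    com_velocity: Trace
    concentric: tuple[int, int]
    mean_force_n: float
    mean_velocity_ms: float
    mean_power_w: float
    mpv_ms: float
    mpp_w: float
    displacement_m: float


def analyze_jump(
    grf: Trace,
    body_mass_kg: float,
    external_load_kg: float,
    quiet_window_s: tuple = (0.0, 0.4),
    takeoff_threshold_n: float = 5.0,
) -> JumpTrial:
    """Run the full per-trial chain: quiet stance -> weight -> COM
    velocity -> concentric phase -> concentric and propulsive means."""
    if body_mass_kg <= 0 or external_load_kg < 0:
        raise InvalidParameterError("non-physical masses")
    quiet = system_weight(grf, quiet_window_s)
    mass = body_mass_kg + external_load_kg
    start = movement_onset(grf, quiet.weight_n)
    vel = com_velocity(grf, mass, quiet.weight_n, start_index=start)
    phase = concentric_phase(grf, vel, takeoff_threshold_n, search_from=start)
    mf, mv, mp = concentric_means(grf, vel, phase)
    mpv, mpp = propulsive_means(grf, vel, phase, mass)
    disp = float(np.trapezoid(vel.samples[phase[0]:phase[1]], dx=1.0 / grf.fs))
    return JumpTrial(
        grf=grf,
        external_load_kg=external_load_kg,
        body_mass_kg=body_mass_kg,
        system_mass_kg=mass,
        weight_n=quiet.weight_n,
        com_velocity=vel,
        concentric=phase,
        mean_force_n=mf,
        mean_velocity_ms=mv,
        mean_power_w=mp,
        mpv_ms=mpv,
        mpp_w=mpp,
        displacement_m=disp,
    )


def select_best_rep(
    reps: Sequence[JumpTrial],
    displacement_bounds_m: tuple = (0.15, 0.60),
) -> JumpTrial:
    """Repetition with the highest mean concentric velocity among those
    with a plausible concentric COM displacement.  Ties go to the
    earlier repetition."""
    lo, hi = displacement_bounds_m
    valid = [r for r in reps if lo <= r.displacement_m <= hi]
    if not valid:
        raise DegeneratePhaseError(
            f"no repetition with concentric displacement in [{lo}, {hi}] m"
        )
    best = valid[0]
    for r in valid[1:]:
        if r.mean_velocity_ms > best.mean_velocity_ms:
            best = r
    return best


# ---------------------------------------------------------------------------
# Force-velocity profile and load prescription
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FVProfile:
    """Linear force-velocity profile, force normalized to body mass.

    ``v0`` and ``p0`` are derived from the stored intercept and slope,
    so the identities v0 = -f0/slope and p0 = f0*v0/4 hold exactly.
    """

    f0: float                 # N/kg, force-axis intercept
    slope_fv: float           # N*s/m/kg, negative
    r2: float
    body_mass_kg: float
    points: tuple             # ((force_nkg, velocity_ms), ...)

    @property
    def v0(self) -> float:
        """Velocity-axis intercept, m/s."""
        return -self.f0 / self.slope_fv

    @property
    def p0(self) -> float:
        """Maximal theoretical power, W/kg: F0*V0/4."""
        return self.f0 * self.v0 / 4.0


def _ols_line(x: np.ndarray, y: np.ndarray):
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    sstot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if sstot == 0 else 1.0 - float(np.sum(resid**2)) / sstot
    return float(slope), float(intercept), r2


def fit_fv_profile(per_load, body_mass_kg: float) -> FVProfile:
    """OLS of body-mass-normalized concentric force on concentric
    velocity across loads.

    ``per_load`` is a sequence of (mean_force_n, mean_velocity_ms)
    pairs, one per loading condition.
    """
    if body_mass_kg <= 0:
        raise InvalidParameterError("body mass must be positive")
    pts = [(f / body_mass_kg, v) for f, v in per_load]
    v = np.array([p[1] for p in pts])
    fn = np.array([p[0] for p in pts])
    if len(pts) < 2 or np.unique(v).size < 2:
        raise InvalidParameterError("need at least two distinct velocities")
    slope, intercept, r2 = _ols_line(v, fn)
    if slope >= 0:
        raise InvalidProfileError("non-negative FV slope: V0 undefined")
    return FVProfile(f0=intercept, slope_fv=slope, r2=r2,
                     body_mass_kg=body_mass_kg, points=tuple(pts))


@dataclass(frozen=True)
class LoadVelocityModel:
    """Linear model of mean propulsive velocity against external load."""

    slope: float              # (m/s)/kg, expected negative
    intercept: float          # m/s
    r2: float
    points: tuple             # ((load_kg, mpv_ms), ...)

    def predict(self, load_kg: float) -> float:
        return self.intercept + self.slope * load_kg


def fit_load_velocity(points) -> LoadVelocityModel:
    """OLS of mean propulsive velocity on external load (kg)."""
    loads = np.array([p[0] for p in points], dtype=float)
    mpv = np.array([p[1] for p in points], dtype=float)
    if loads.size < 2 or np.unique(loads).size < 2:
        raise InvalidParameterError("need at least two distinct loads")
    res = _stats.linregress(loads, mpv)
    return LoadVelocityModel(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue**2),
        points=tuple((float(l), float(v)) for l, v in points),
    )


def load_at_velocity(model: LoadVelocityModel, target_v: float = 1.0) -> float:
    """External load (kg) at a target mean propulsive velocity, by
    inverting the load-velocity line.

    Warns when the prescription extrapolates beyond the fitted load
    range by more than 25% of its span, or when the target velocity is
    outside the observed velocity range.
    """
    if model.slope >= 0:
        raise InvalidProfileError("load-velocity slope must be negative")
    load = (target_v - model.intercept) / model.slope
    if load < 0:
        raise InvalidProfileError(f"prescribed load is negative ({load:.1f} kg)")
    loads = [p[0] for p in model.points]
    vels = [p[1] for p in model.points]
    span = max(loads) - min(loads)
    if load < min(loads) - 0.25 * span or load > max(loads) + 0.25 * span:
        warnings.warn(
            f"load {load:.1f} kg extrapolates >25% beyond the fitted range "
            f"[{min(loads)}, {max(loads)}] kg",
            ExtrapolationWarning,
        )
    elif not min(vels) <= target_v <= max(vels):
        warnings.warn(
            f"target velocity {target_v} m/s outside the observed range "
            f"[{min(vels):.2f}, {max(vels):.2f}] m/s",
            ExtrapolationWarning,
        )
    return float(load)


def cmj15_summary(reps, expected: int = 15, body_mass_kg: float | None = None) -> float:
    """Mean propulsive power averaged across the repeated-jump reps.

    ``reps`` may be :class:`JumpTrial` objects or raw per-rep MPP
    values (W).  When ``body_mass_kg`` is given the result is W/kg.
    """
    mpps = [r.mpp_w if isinstance(r, JumpTrial) else float(r) for r in reps]
    if len(mpps) == 0:
        raise InvalidParameterError("no repetitions supplied")
    if len(mpps) != expected:
        warnings.warn(f"expected {expected} repetitions, got {len(mpps)}")
    out = float(np.mean(mpps))
    if body_mass_kg is not None:
        if body_mass_kg <= 0:
            raise InvalidParameterError("body mass must be positive")
        out /= body_mass_kg
    return out
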