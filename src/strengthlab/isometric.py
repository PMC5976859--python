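"""Maximal and explosive isometric knee-extension strength.

Maximal voluntary force (MVF) is the highest instantaneous force over
the maximal-contraction trials.  Explosive strength is read as the
force 50, 100 and 150 ms after the contraction onset (F50/F100/F150),
with two screening rules: attempts with an absolute pre-onset baseline
slope above 1.5 signal-units/s (pre-tension or countermovement) and
attempts peaking below 75% of MVF (sub-maximal effort) are discarded.
Of the surviving attempts, the three with the highest F100 are
averaged.

Note on units: the screening slope threshold is expressed in the units
of the recorded signal per second.  For a force transducer that is
N/s; lever-arm torque conversion is intentionally out of scope, so the
same numeric threshold applies to whichever signal is recorded.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass

import numpy as np

from .errors import AllRejectedError, InvalidParameterError, TruncatedTrialError
from .signal import OnsetResult, Trace, baseline_slope

__all__ = [
    "RejectionReason",
    "MvcResult",
    "ExplosiveResult",
    "ExplosiveSummary",
    "gravity_correct",
    "compute_mvf",
    "screen_explosive",
    "summarize_explosive",
]


class RejectionReason(enum.Enum):
    NONE = "none"
    BASELINE_SLOPE = "baseline_slope"
    LOW_PEAK = "low_peak"
    NO_ONSET = "no_onset"


@dataclass(frozen=True)
class MvcResult:
    """Maximal voluntary force over a set of MVC trials."""

    mvf: float
    trial_index: int  # 1-based index of the winning trial
    per_trial_peaks: tuple[float, ...]


@dataclass(frozen=True)
class ExplosiveResult:
    """One explosive attempt after screening.

    ``f50/f100/f150`` are NaN when the attempt was rejected.
    """

    f50: float
    f100: float
    f150: float
    onset: OnsetResult
    accepted: bool
    rejection_reason: RejectionReason
    peak_n: float
    baseline_slope: float


@dataclass(frozen=True)
class ExplosiveSummary:
    f50_mean: float
    f100_mean: float
    f150_mean: float
    n_selected: int
    n_rejected: int
    rejection_tally: dict


def gravity_correct(trace: Trace, offset_n: float) -> Trace:
    """Remove the resting limb-weight reading from every sample."""
    if not np.isfinite(offset_n):
        raise InvalidParameterError("gravity offset must be finite")
    return trace.with_samples(trace.samples - offset_n)


def compute_mvf(mvc_traces: list[Trace]) -> MvcResult:
    """Peak instantaneous force over the maximal-contraction trials."""
    if not mvc_traces:
        raise InvalidParameterError("need at least one MVC trace")
    peaks = [float(np.max(t.samples)) for t in mvc_traces]
    best = int(np.argmax(peaks))
    mvf = peaks[best]
    if mvf <= 0:
        warnings.warn("MVF is non-positive; check gravity correction and polarity")
    return MvcResult(mvf=mvf, trial_index=best + 1, per_trial_peaks=tuple(peaks))


def _force_at(trace: Trace, onset_index: int, latency_ms: float) -> float:
    """Force at a latency after onset: exact sample at 1 kHz, linear
    interpolation otherwise."""
    pos = onset_index + latency_ms / 1000.0 * trace.fs
    i = int(np.floor(pos))
    frac = pos - i
    if i + 1 >= trace.n:
        raise TruncatedTrialError("trace ends before the 150 ms analysis window")
    if frac < 1e-9:
        return float(trace.samples[i])
    if frac > 1 - 1e-9:
        return float(trace.samples[i + 1])
    return float((1 - frac) * trace.samples[i] + frac * trace.samples[i + 1])


def screen_explosive(
    trace: Trace,
    onset: OnsetResult,
    mvf: float,
    slope_limit: float = 1.5,
    peak_frac: float = 0.75,
    slope_window_ms: float = 100.0,
) -> ExplosiveResult:
    """Apply the contraction screening rules and read F50/F100/F150.

    Rejection order: baseline slope first (pre-tension /
    countermovement), then low peak (< ``peak_frac`` x MVF).
    """
    if mvf <= 0:
        raise InvalidParameterError("mvf must be positive")
    if onset.index + 0.150 * trace.fs >= trace.n:
        raise TruncatedTrialError("onset + 150 ms extends beyond the trace")
    slope = baseline_slope(trace, onset, window_ms=slope_window_ms)
    peak = float(np.max(trace.samples))
    nan = float("nan")
    if abs(slope) > slope_limit:
        return ExplosiveResult(nan, nan, nan, onset, False,
                               RejectionReason.BASELINE_SLOPE, peak, slope)
    if peak < peak_frac * mvf:
        return ExplosiveResult(nan, nan, nan, onset, False,
                               RejectionReason.LOW_PEAK, peak, slope)
    f50 = _force_at(trace, onset.index, 50.0)
    f100 = _force_at(trace, onset.index, 100.0)
    f150 = _force_at(trace, onset.index, 150.0)
    return ExplosiveResult(f50, f100, f150, onset, True,
                           RejectionReason.NONE, peak, slope)


def summarize_explosive(results: list[ExplosiveResult], n_best: int = 3) -> ExplosiveSummary:
    """Average F50/F100/F150 over the ``n_best`` accepted attempts with
    the highest F100 (ties broken in favour of the earlier attempt)."""
    accepted = [r for r in results if r.accepted]
    tally: dict[str, int] = {}
    for r in results:
        if not r.accepted:
            key = r.rejection_reason.value
            tally[key] = tally.get(key, 0) + 1
    if not accepted:
        raise AllRejectedError(tally)
    # stable sort keeps the earlier trial first among equal F100
    ranked = sorted(accepted, key=lambda r: -r.f100)
    sel = ranked[: min(n_best, len(ranked))]
    return ExplosiveSummary(
        f50_mean=float(np.mean([r.f50 for r in sel])),
        f100_mean=float(np.mean([r.f100 for r in sel])),
        f150_mean=float(np.mean([r.f150 for r in sel])),
        n_selected=len(sel),
        n_rejected=len(results) - len(accepted),
        rejection_tally=tally,
    )
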