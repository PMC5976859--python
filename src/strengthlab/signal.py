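"""Digital-signal primitives shared by the force and EMG stages.

The analogue chain of a strength laboratory (strain gauge at 1 kHz,
surface EMG at 2 kHz, force plate at 1 kHz) delivers uniformly sampled
traces.  This module provides the :class:`Trace` container, zero-phase
Butterworth filtering, contraction-onset detection on the first
derivative of the filtered force, and the pre-onset baseline
regression used to screen contaminated trials.

Filtering is applied forward-backward (zero phase) so that onset
latencies are not biased by group delay; the effective filter order is
therefore twice the design order.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import signal as _sps

__all__ = [
    "Trace",
    "OnsetMethod",
    "OnsetResult",
    "read_trace",
    "write_trace",
    "butterworth_lowpass",
    "butterworth_bandpass",
    "detect_force_onset",
    "baseline_slope",
]

from .errors import (
    InsufficientBaselineError,
    InvalidParameterError,
    NoOnsetError,
    SuspiciousBaselineError,
    TooShortError,
)


@dataclass(frozen=True)
class Trace:
    """A uniformly sampled real-valued signal.

    Parameters
    ----------
    samples : array-like
        Signal values (N for force/GRF, mV for EMG).
    fs : float
        Sampling rate in Hz, strictly positive.
    t0 : float
        Time of the first sample in seconds.
    label : str
        Channel identifier (e.g. ``"force"``, ``"VL"``).
    """

    samples: np.ndarray
    fs: float
    t0: float = 0.0
    label: str = ""

    def __post_init__(self) -> None:
        x = np.asarray(self.samples, dtype=float)
        if x.ndim != 1:
            raise InvalidParameterError("trace samples must be one-dimensional")
        if x.size < 2:
            raise TooShortError("a trace needs at least two samples")
        if not np.all(np.isfinite(x)):
            raise InvalidParameterError("trace contains non-finite samples")
        if not (self.fs > 0 and np.isfinite(self.fs)):
            raise InvalidParameterError("sampling rate must be positive and finite")
        object.__setattr__(self, "samples", x)

    @property
    def n(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        return (self.n - 1) / self.fs

    def times(self) -> np.ndarray:
        """Time stamps of every sample in seconds."""
        return self.t0 + np.arange(self.n) / self.fs

    def index_at(self, time_s: float) -> int:
        """Nearest sample index for an absolute time."""
        i = int(round((time_s - self.t0) * self.fs))
        return min(max(i, 0), self.n - 1)

    def with_samples(self, samples: np.ndarray, label: str | None = None) -> "Trace":
        return replace(self, samples=samples, label=self.label if label is None else label)


class OnsetMethod(enum.Enum):
    DERIVATIVE_ZERO_CROSSING = "derivative_zero_crossing"
    EMG_DEFLECTION = "emg_deflection"


@dataclass(frozen=True)
class OnsetResult:
    """Location of a contraction or activation onset.

    ``baseline_slope`` and ``baseline_sd`` describe the pre-onset
    baseline (units per second and signal units respectively) and are
    kept as diagnostics for the screening rules downstream.
    """

    index: int
    time_s: float
    method: OnsetMethod
    baseline_slope: float = 0.0
    baseline_sd: float = 0.0

    def shifted(self, k: int, fs: float) -> "OnsetResult":
        return replace(self, index=self.index + k, time_s=self.time_s + k / fs)


# ---------------------------------------------------------------------------
# File I/O: delimited text, header row, columns time_s,value
# ---------------------------------------------------------------------------

def read_trace(path, label: str = "", uniformity_tol: float = 0.01) -> Trace:
    """Read a trace from a comma- or tab-delimited text file.

    The file must carry a header row with columns ``time_s`` and
    ``value``.  The sampling rate is inferred from the median sample
    interval and each interval must agree with it to within
    ``uniformity_tol`` (relative).
    """
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if "\t" in header else ","
    df = pd.read_csv(path, sep=sep)
    if not {"time_s", "value"}.issubset(df.columns):
        raise InvalidParameterError(f"{path}: expected columns time_s,value")
    t = df["time_s"].to_numpy(dtype=float)
    dt = np.diff(t)
    if dt.size == 0 or np.any(dt <= 0):
        raise InvalidParameterError(f"{path}: time stamps must be strictly increasing")
    med = float(np.median(dt))
    if np.max(np.abs(dt - med)) > uniformity_tol * med:
        raise InvalidParameterError(f"{path}: sampling is not uniform within {uniformity_tol:.0%}")
    return Trace(df["value"].to_numpy(dtype=float), fs=1.0 / med, t0=float(t[0]), label=label)


def write_trace(trace: Trace, path, float_format: str = "%.6g") -> None:
    """Write a trace as ``time_s,value`` delimited text."""
    df = pd.DataFrame({"time_s": trace.times(), "value": trace.samples})
    df.to_csv(path, index=False, float_format=float_format)


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

def _zero_phase(trace: Trace, sos: np.ndarray) -> Trace:
    # sosfiltfilt needs more than 3 * (2 * n_sections + 1) samples for its
    # default edge padding; shorter traces cannot be filtered meaningfully.
    padlen = 3 * (2 * sos.shape[0] + 1)
    if trace.n <= padlen:
        raise TooShortError(
            f"trace of {trace.n} samples is shorter than the filter warm-up ({padlen})"
        )
    return trace.with_samples(_sps.sosfiltfilt(sos, trace.samples))


def butterworth_lowpass(trace: Trace, cutoff_hz: float, order: int = 4) -> Trace:
    """Zero-phase low-pass Butterworth filter (forward-backward)."""
    if order < 1:
        raise InvalidParameterError("filter order must be >= 1")
    if not 0 < cutoff_hz < trace.fs / 2:
        raise InvalidParameterError(
            f"cutoff {cutoff_hz} Hz must lie in (0, Nyquist={trace.fs / 2} Hz)"
        )
    sos = _sps.butter(order, cutoff_hz, btype="low", fs=trace.fs, output="sos")
    return _zero_phase(trace, sos)


def butterworth_bandpass(trace: Trace, low_hz: float, high_hz: float, order: int = 4) -> Trace:
    """Zero-phase band-pass Butterworth filter (forward-backward)."""
    if order < 1:
        raise InvalidParameterError("filter order must be >= 1")
    if not 0 < low_hz < high_hz < trace.fs / 2:
        raise InvalidParameterError(
            f"band ({low_hz}, {high_hz}) Hz must satisfy 0 < low < high < Nyquist"
        )
    sos = _sps.butter(order, [low_hz, high_hz], btype="band", fs=trace.fs, output="sos")
    return _zero_phase(trace, sos)


# ---------------------------------------------------------------------------
# Onset detection and baseline characterisation
# ---------------------------------------------------------------------------

def detect_force_onset(
    trace: Trace,
    trigger_sd_mult: float = 8.0,
    baseline_ms: float = 200.0,
    band_sd_mult: float = 1.0,
) -> OnsetResult:
    """Locate the force onset on an already low-pass-filtered trace.

    The first ``baseline_ms`` of the trial are taken as pre-contraction
    baseline.  A trigger is the first sample exceeding baseline mean +
    ``trigger_sd_mult`` baseline SDs; the onset is the last
    zero-crossing of the first derivative (central differences) walking
    backwards from the trigger, resolved to the later sample of the
    crossing pair.

    On noisy signals the candidate crossing is then advanced to the
    last sample still inside the baseline noise band (mean +
    ``band_sd_mult`` SDs), which removes the early bias that zero-phase
    filtering smears into the derivative.  For noiseless signals the
    baseline SD is zero and this refinement is a no-op, so noiseless
    ramps are located exactly.
    """
    x = trace.samples
    nb = int(round(baseline_ms / 1000.0 * trace.fs))
    if nb < 2 or nb >= trace.n:
        raise TooShortError("trace too short for the baseline window")
    base = x[:nb]
    mu = float(np.mean(base))
    sd = float(np.std(base, ddof=1))
    above = np.nonzero(x > mu + trigger_sd_mult * sd)[0]
    if above.size == 0:
        raise NoOnsetError("no sample exceeds the trigger threshold")
    trig = int(above[0])
    if trig < nb:
        raise SuspiciousBaselineError(
            f"trigger at sample {trig} lies inside the {nb}-sample baseline window"
        )
    d = np.gradient(x)
    onset = 0
    for i in range(trig, 0, -1):
        if d[i] > 0 and d[i - 1] <= 0:
            onset = i
            break
    if sd > 0:
        inside = np.nonzero(x[onset:trig] <= mu + band_sd_mult * sd)[0]
        if inside.size:
            onset = onset + int(inside[-1]) + 1
    # baseline diagnostics over the window immediately preceding onset
    slope = _ols_slope(x[:nb], trace.fs) if onset >= nb else 0.0
    return OnsetResult(
        index=onset,
        time_s=trace.t0 + onset / trace.fs,
        method=OnsetMethod.DERIVATIVE_ZERO_CROSSING,
        baseline_slope=slope,
        baseline_sd=sd,
    )


def _ols_slope(y: np.ndarray, fs: float) -> float:
    t = np.arange(y.size) / fs
    t = t - t.mean()
    return float(np.dot(t, y - y.mean()) / np.dot(t, t))


def baseline_slope(trace: Trace, onset: OnsetResult, window_ms: float = 100.0) -> float:
    """Least-squares slope (signal units per second) of the baseline
    over the ``window_ms`` immediately preceding the onset."""
    w = int(round(window_ms / 1000.0 * trace.fs))
    if w < 2:
        raise InvalidParameterError("baseline window must span at least two samples")
    if onset.index < w:
        raise InsufficientBaselineError(
            f"need {w} pre-onset samples, onset is at index {onset.index}"
        )
    seg = trace.samples[onset.index - w : onset.index]
    return _ols_slope(seg, trace.fs)
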