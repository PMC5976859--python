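"""Voluntary activation from surface EMG of the knee extensors.

Three channels (vastus medialis, vastus lateralis, rectus femoris) are
band-pass filtered, the maximal activation (EMG_MVC) is the RMS over a
500 ms epoch centred on the peak of the maximal contraction, and
explosive-contraction activation is the windowed RMS over 0-50, 50-100
and 100-150 ms after the EMG onset, normalized per muscle to its
EMG_MVC and then averaged across muscles.

The EMG onset in the original protocol was picked manually; here a
deterministic deflection detector stands in: the first sample whose
moving-RMS envelope (window ``sustain_ms``) exceeds ``k_sd`` baseline
SDs, walked back to the last crossing of the baseline mean on the raw
signal.  The overall onset is the earliest channel onset
(the first muscle to be activated).  A manual override can be supplied
wherever an :class:`~strengthlab.signal.OnsetResult` is accepted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import (
    InvalidParameterError,
    NoOnsetError,
    NormalizationError,
    TooShortError,
    TruncatedTrialError,
)
from .signal import OnsetMethod, OnsetResult, Trace

__all__ = [
    "MUSCLES",
    "EmgChannelSet",
    "ActivationResult",
    "emg_mvc_rms",
    "detect_emg_onset",
    "windowed_activation",
]

MUSCLES = ("VM", "VL", "RF")

#: activation windows after EMG onset, half-open, in ms
WINDOWS_MS = ((0.0, 50.0), (50.0, 100.0), (100.0, 150.0))


@dataclass(frozen=True)
class EmgChannelSet:
    """The three quadriceps EMG channels of one trial, aligned in time."""

    channels: dict

    def __post_init__(self) -> None:
        if set(self.channels) != set(MUSCLES):
            raise InvalidParameterError(f"expected channels {MUSCLES}")
        ref = self.channels[MUSCLES[0]]
        for m in MUSCLES:
            ch = self.channels[m]
            if ch.n != ref.n or ch.fs != ref.fs or ch.t0 != ref.t0:
                raise InvalidParameterError("EMG channels must share length, fs and t0")

    @property
    def fs(self) -> float:
        return self.channels[MUSCLES[0]].fs

    @property
    def n(self) -> int:
        return self.channels[MUSCLES[0]].n


@dataclass(frozen=True)
class ActivationResult:
    """Normalized windowed activation of one explosive contraction."""

    emg_mvc_mv: dict          # per-muscle MVC RMS, mV
    emg_mvc_mean_mv: float    # across-muscle mean, mV
    rms_0_50: float           # % of EMG_MVC, across-muscle mean
    rms_50_100: float
    rms_100_150: float
    per_muscle_pct: dict      # muscle -> (w1, w2, w3) in %
    emg_onset: OnsetResult


def _rms(x: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.square(x))))


def emg_mvc_rms(emg: Trace, epoch_ms: float = 500.0) -> float:
    """RMS over an epoch centred on the peak rectified EMG of an MVC."""
    n_epoch = int(round(epoch_ms / 1000.0 * emg.fs))
    if emg.n < n_epoch:
        raise TooShortError(f"MVC EMG trace shorter than the {epoch_ms:.0f} ms epoch")
    peak = int(np.argmax(np.abs(emg.samples)))
    start = peak - n_epoch // 2
    clipped = min(max(start, 0), emg.n - n_epoch)
    if clipped != start:
        warnings.warn("MVC RMS epoch clipped at the trace edge")
    return _rms(emg.samples[clipped : clipped + n_epoch])


def _moving_rms(x: np.ndarray, w: int) -> np.ndarray:
    sq = np.convolve(np.square(x), np.ones(w) / w, mode="same")
    return np.sqrt(np.maximum(sq, 0.0))


def _channel_onset(ch: Trace, k_sd: float, sustain_ms: float, baseline_ms: float):
    """Deflection onset of one channel.

    Because raw EMG oscillates through zero, the sustained-deviation
    criterion runs on a moving-RMS envelope (window = ``sustain_ms``):
    the trigger is the first post-baseline sample whose envelope
    exceeds ``k_sd`` baseline SDs of the raw signal.  The onset is the
    last crossing of the baseline mean on the raw signal before the
    trigger.
    """
    x = ch.samples
    nb = int(round(baseline_ms / 1000.0 * ch.fs))
    if nb < 2 or nb >= ch.n:
        raise TooShortError("EMG trace too short for the baseline window")
    mu = float(np.mean(x[:nb]))
    sd = float(np.std(x[:nb], ddof=1))
    w = max(int(round(sustain_ms / 1000.0 * ch.fs)), 1)
    if sd == 0:
        # noiseless: any deviation from the baseline mean is the burst
        hits = np.nonzero(x[nb:] != mu)[0] + nb
    else:
        env = _moving_rms(x - mu, w)
        hits = np.nonzero(env > k_sd * sd)[0]
        hits = hits[hits >= nb]
    if hits.size == 0:
        return None
    trig = int(hits[0])
    # walk back to the last crossing of the baseline mean on the raw signal
    r = x - mu
    onset = trig
    for i in range(trig, 0, -1):
        if r[i] == 0 or (r[i - 1] == 0 and r[i] != 0) or (r[i - 1] > 0) != (r[i] > 0):
            onset = i
            break
    return onset, mu, sd


def detect_emg_onset(
    channels: EmgChannelSet,
    k_sd: float = 3.0,
    sustain_ms: float = 10.0,
    baseline_ms: float = 100.0,
) -> OnsetResult:
    """Earliest deflection onset across the three muscles."""
    best = None
    for m in MUSCLES:
        res = _channel_onset(channels.channels[m], k_sd, sustain_ms, baseline_ms)
        if res is None:
            continue
        onset, mu, sd = res
        if best is None or onset < best[0]:
            best = (onset, sd)
    if best is None:
        raise NoOnsetError("no EMG channel deflected from baseline")
    onset, sd = best
    ref = channels.channels[MUSCLES[0]]
    return OnsetResult(
        index=onset,
        time_s=ref.t0 + onset / ref.fs,
        method=OnsetMethod.EMG_DEFLECTION,
        baseline_sd=sd,
    )


def windowed_activation(
    channels: EmgChannelSet,
    onset: OnsetResult,
    emg_mvc: dict,
) -> ActivationResult:
    """Windowed RMS normalized per muscle, averaged across muscles.

    Windows are half-open sample ranges so they tile [onset,
    onset + 150 ms) without double counting.
    """
    fs = channels.fs
    end_needed = onset.index + int(round(0.150 * fs))
    if end_needed > channels.n:
        raise TruncatedTrialError("onset + 150 ms extends beyond the EMG trace")
    for m in MUSCLES:
        if not emg_mvc.get(m, 0) > 0:
            raise NormalizationError(f"EMG_MVC for {m} must be positive")
    per_muscle = {}
    for m in MUSCLES:
        x = channels.channels[m].samples
        vals = []
        for w0, w1 in WINDOWS_MS:
            i0 = onset.index + int(round(w0 / 1000.0 * fs))
            i1 = onset.index + int(round(w1 / 1000.0 * fs))
            vals.append(100.0 * _rms(x[i0:i1]) / emg_mvc[m])
        per_muscle[m] = tuple(vals)
    means = [float(np.mean([per_muscle[m][k] for m in MUSCLES])) for k in range(3)]
    return ActivationResult(
        emg_mvc_mv=dict(emg_mvc),
        emg_mvc_mean_mv=float(np.mean([emg_mvc[m] for m in MUSCLES])),
        rms_0_50=means[0],
        rms_50_100=means[1],
        rms_100_150=means[2],
        per_muscle_pct=per_muscle,
        emg_onset=onset,
    )
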