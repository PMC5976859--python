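"""Synthetic raw-data generator with ground-truth event logs.

Every pipeline stage can be exercised against generated recordings
whose true onsets, phases, take-off velocities and physiological
parameters are known.  Defaults are centred on descriptive statistics
typical of physically active young men on a knee-extension dynamometer
and Smith-machine loaded jumps: MVF ~ 890 N, body mass ~ 76 kg, VL
pennation ~ 11.7 deg, F0 ~ 35.6 N/kg, V0 ~ 3.38 m/s.

The models are phenomenological, not physiological: the explosive
force rise is an offset-subtracted logistic sigmoid, EMG is
amplitude-modulated band-limited Gaussian noise, and the jump is built
from half-sine acceleration segments calibrated per load so the
concentric means lie on the subject's true force-velocity line.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .emg import MUSCLES, EmgChannelSet
from .errors import InvalidParameterError
from .jumps import G
from .signal import Trace, butterworth_bandpass

__all__ = [
    "SubjectParams",
    "EventLog",
    "isometric_force_value",
    "gen_isometric_trial",
    "gen_mvc_trial",
    "gen_emg_trial",
    "gen_mvc_emg",
    "gen_cmj_trial",
    "gen_fv_points",
    "gen_study",
    "STUDY_MEASURES",
]


@dataclass(frozen=True)
class SubjectParams:
    """Ground-truth physiological parameters of one synthetic subject."""

    body_mass_kg: float = 76.1
    mvf_true_n: float = 890.0
    explosive_plateau_frac: float = 0.90   # plateau of explosive efforts, x MVF
    rise_mid_ms: float = 80.0              # logistic midpoint of the force rise
    rise_scale_ms: float = 30.0            # logistic scale of the force rise
    onset_time_s: float = 0.35             # true onset within isometric trials
    f0_true_nkg: float = 35.6
    v0_true_ms: float = 3.38
    lv_slope: float = -0.02                # (m/s)/kg of external load
    lv_intercept: float = 2.0              # m/s at zero external load
    emg_mvc_mv: float = 0.24
    pennation_deg: float = 11.7
    thickness_vl_mm: float = 25.7
    noise_force_sd_n: float = 0.1
    noise_grf_sd_n: float = 3.0
    noise_emg_sd_mv: float = 0.008

    def __post_init__(self):
        if min(self.body_mass_kg, self.mvf_true_n, self.f0_true_nkg,
               self.v0_true_ms, self.rise_scale_ms) <= 0:
            raise InvalidParameterError("physical parameters must be positive")
        if self.lv_slope >= 0:
            raise InvalidParameterError("load-velocity slope must be negative")


@dataclass(frozen=True)
class EventLog:
    """Ground truth of one generated trace."""

    true_onset_index: Optional[int] = None
    true_onset_time_s: Optional[float] = None
    plateau_n: Optional[float] = None
    baseline_offset_n: float = 0.0
    pretension_slope: float = 0.0
    artifact: str = "clean"
    concentric_start_index: Optional[int] = None
    takeoff_index: Optional[int] = None
    takeoff_velocity_ms: Optional[float] = None
    apex_m: Optional[float] = None
    mean_force_n: Optional[float] = None
    mean_velocity_ms: Optional[float] = None
    channel_onsets: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Isometric trials
# ---------------------------------------------------------------------------

def isometric_force_value(
    plateau_n: float,
    dt_ms: float,
    mid_ms: float = 80.0,
    scale_ms: float = 30.0,
) -> float:
    """Closed-form noiseless force ``dt_ms`` after onset.

    The rise is an offset-subtracted logistic,
    plateau * (s(dt) - s(0)) / (1 - s(0)) with
    s(t) = 1 / (1 + exp(-(t - mid)/scale)), which starts exactly at
    zero at the onset with a finite (non-zero) rate of force
    development, saturates sigmoidally, and reaches ~22% / 64% / 90%
    of the plateau at 50 / 100 / 150 ms with the default shape.
    """
    if dt_ms <= 0:
        return 0.0
    s0 = 1.0 / (1.0 + math.exp(mid_ms / scale_ms))
    s = 1.0 / (1.0 + math.exp(-(dt_ms - mid_ms) / scale_ms))
    return plateau_n * (s - s0) / (1.0 - s0)


def _sigmoid_rise(
    n: int, fs: float, onset_idx: int, plateau: float,
    mid_ms: float = 80.0, scale_ms: float = 30.0,
) -> np.ndarray:
    t_ms = (np.arange(n) - onset_idx) / fs * 1000.0
    x = np.zeros(n)
    up = t_ms > 0
    s0 = 1.0 / (1.0 + np.exp(mid_ms / scale_ms))
    s = 1.0 / (1.0 + np.exp(-(t_ms[up] - mid_ms) / scale_ms))
    x[up] = plateau * (s - s0) / (1.0 - s0)
    return x


def gen_isometric_trial(
    params: SubjectParams,
    artifact: str = "clean",
    rng: Optional[np.random.Generator] = None,
    fs: float = 1000.0,
    duration_s: float = 1.0,
    noise_sd_n: Optional[float] = None,
    gravity_offset_n: float = 0.0,
) -> tuple[Trace, EventLog]:
    """One explosive knee-extension trial.

    ``artifact`` is ``"clean"``, ``"pretension"`` (baseline drift of
    2.5 N/s, above the 1.5 N/s screening limit) or ``"low_effort"``
    (plateau at 60% MVF, below the 75% screening limit).
    """
    rng = np.random.default_rng() if rng is None else rng
    if artifact not in ("clean", "pretension", "low_effort"):
        raise InvalidParameterError(f"unknown artifact {artifact!r}")
    noise = params.noise_force_sd_n if noise_sd_n is None else noise_sd_n
    n = int(round(duration_s * fs))
    onset_idx = int(round(params.onset_time_s * fs))
    frac = 0.60 if artifact == "low_effort" else params.explosive_plateau_frac
    plateau = frac * params.mvf_true_n
    x = _sigmoid_rise(n, fs, onset_idx, plateau,
                      params.rise_mid_ms, params.rise_scale_ms)
    slope = 0.0
    if artifact == "pretension":
        slope = 2.5
        t = np.arange(n) / fs
        x = x + slope * np.minimum(t, onset_idx / fs)
    x = x + gravity_offset_n
    if noise > 0:
        x = x + rng.normal(0.0, noise, n)
    trace = Trace(x, fs=fs, label="force")
    log = EventLog(
        true_onset_index=onset_idx,
        true_onset_time_s=onset_idx / fs,
        plateau_n=plateau,
        baseline_offset_n=gravity_offset_n,
        pretension_slope=slope,
        artifact=artifact,
    )
    return trace, log


def gen_mvc_trial(
    params: SubjectParams,
    rng: Optional[np.random.Generator] = None,
    fs: float = 1000.0,
    duration_s: float = 1.5,
    noise_sd_n: Optional[float] = None,
    gravity_offset_n: float = 0.0,
) -> tuple[Trace, EventLog]:
    """One maximal voluntary contraction: slower ramp to a plateau at
    the subject's true MVF."""
    rng = np.random.default_rng() if rng is None else rng
    noise = params.noise_force_sd_n if noise_sd_n is None else noise_sd_n
    n = int(round(duration_s * fs))
    onset_idx = int(round(0.3 * fs))
    x = _sigmoid_rise(n, fs, onset_idx, params.mvf_true_n,
                      mid_ms=350.0, scale_ms=130.0)
    x = x + gravity_offset_n
    if noise > 0:
        x = x + rng.normal(0.0, noise, n)
    trace = Trace(x, fs=fs, label="force")
    log = EventLog(true_onset_index=onset_idx, true_onset_time_s=onset_idx / fs,
                   plateau_n=params.mvf_true_n, baseline_offset_n=gravity_offset_n)
    return trace, log


# ---------------------------------------------------------------------------
# EMG trials
# ---------------------------------------------------------------------------

def _band_limited_noise(rng, n, fs, sd):
    white = rng.normal(0.0, 1.0, n + 400)
    tr = Trace(white, fs=fs)
    shaped = butterworth_bandpass(tr, 6.0, min(450.0, fs / 2 * 0.9), order=4).samples
    shaped = shaped[200:200 + n]
    s = np.std(shaped)
    return shaped / s * sd if s > 0 else shaped


def gen_emg_trial(
    params: SubjectParams,
    rng: Optional[np.random.Generator] = None,
    fs: float = 2000.0,
    duration_s: float = 0.8,
    onset_time_s: float = 0.3,
    burst_rms_mv: Optional[float] = None,
    stagger_ms: tuple = (0.0, 6.0, 12.0),
    ramp_ms: float = 30.0,
) -> tuple[EmgChannelSet, EventLog]:
    """Three-channel explosive-contraction EMG with a known onset.

    Channels switch on in the ``stagger_ms`` order (VM first by
    default), so the true overall onset is ``onset_time_s``.
    """
    rng = np.random.default_rng() if rng is None else rng
    burst = params.emg_mvc_mv if burst_rms_mv is None else burst_rms_mv
    n = int(round(duration_s * fs))
    channels = {}
    onsets = {}
    for m, lag in zip(MUSCLES, stagger_ms):
        onset_idx = int(round((onset_time_s + lag / 1000.0) * fs))
        onsets[m] = onset_idx
        base = _band_limited_noise(rng, n, fs, params.noise_emg_sd_mv)
        env = np.zeros(n)
        t_post = np.arange(n) - onset_idx
        ramp_n = max(int(round(ramp_ms / 1000.0 * fs)), 1)
        env[t_post >= 0] = np.clip(t_post[t_post >= 0] / ramp_n, 0.0, 1.0)
        act = _band_limited_noise(rng, n, fs, burst) * env
        channels[m] = Trace(base + act, fs=fs, label=m)
    first = min(onsets.values())
    log = EventLog(true_onset_index=first, true_onset_time_s=first / fs,
                   channel_onsets=onsets)
    return EmgChannelSet(channels=channels), log


def gen_mvc_emg(
    params: SubjectParams,
    rng: Optional[np.random.Generator] = None,
    fs: float = 2000.0,
    duration_s: float = 1.2,
) -> EmgChannelSet:
    """Sustained maximal EMG burst (for the MVC RMS epoch)."""
    rng = np.random.default_rng() if rng is None else rng
    n = int(round(duration_s * fs))
    channels = {}
    for m in MUSCLES:
        base = _band_limited_noise(rng, n, fs, params.noise_emg_sd_mv)
        act = _band_limited_noise(rng, n, fs, params.emg_mvc_mv)
        env = np.minimum(np.arange(n) / (0.1 * fs), 1.0)
        channels[m] = Trace(base + act * env, fs=fs, label=m)
    return EmgChannelSet(channels=channels)


# ---------------------------------------------------------------------------
# Countermovement jumps
# ---------------------------------------------------------------------------

def _jump_accel_profile(n_quiet, n_unw, n_push, n_rel, a1, a2, fs):
    """Net COM acceleration: quiet, unweighting half-sine (down),
    push half-sine (up), release from 0 to -g (takeoff at its end)."""
    seg_q = np.zeros(n_quiet)
    u = np.arange(n_unw) / n_unw
    seg_u = -a1 * np.sin(np.pi * u)
    p = np.arange(n_push) / n_push
    seg_p = a2 * np.sin(np.pi * p)
    r = np.arange(n_rel) / n_rel
    seg_r = -G * np.sin(np.pi * r / 2.0)
    return np.concatenate([seg_q, seg_u, seg_p, seg_r])


def _analytic_velocity(t_s, t_quiet, t_unw, t_push, t_rel, a1, a2):
    """Closed-form velocity of the piecewise-sine profile at time t."""
    v = 0.0
    t = t_s - t_quiet
    if t <= 0:
        return 0.0
    seg = min(t, t_unw)
    v += -a1 * (t_unw / np.pi) * (1 - np.cos(np.pi * seg / t_unw))
    t -= t_unw
    if t <= 0:
        return v
    seg = min(t, t_push)
    v += a2 * (t_push / np.pi) * (1 - np.cos(np.pi * seg / t_push))
    t -= t_push
    if t <= 0:
        return v
    seg = min(t, t_rel)
    v += -G * (2 * t_rel / np.pi) * (1 - np.cos(np.pi * seg / (2 * t_rel)))
    return v


def gen_cmj_trial(
    params: SubjectParams,
    external_load_kg: float,
    rng: Optional[np.random.Generator] = None,
    fs: float = 1000.0,
    noise_sd_n: Optional[float] = None,
    quiet_s: float = 0.45,
    unweight_s: float = 0.35,
    push_s: float = 0.30,
    release_s: float = 0.05,
    takeoff_threshold_n: float = 5.0,
    velocity_jitter_sd: float = 0.0,
    target_displacement_m: float | None = 0.32,
) -> tuple[Trace, EventLog]:
    """One loaded countermovement jump on a force plate.

    The push amplitude is calibrated (bisection) so the concentric
    means lie on the subject's true force-velocity line F/m_body =
    f0 - (f0/v0) * v.  When ``target_displacement_m`` is given, the
    push duration is additionally calibrated so the concentric COM
    displacement matches it, emulating the constant jump depth real
    protocols instruct across loading conditions; otherwise ``push_s``
    is used as-is.  ``velocity_jitter_sd`` (m/s) perturbs the targeted
    line point before calibration to emulate between-trial biological
    variability, and ``noise_sd_n`` adds white measurement noise to
    the GRF during ground contact.
    """
    if external_load_kg < 0:
        raise InvalidParameterError("external load must be >= 0")
    rng = np.random.default_rng() if rng is None else rng
    noise = params.noise_grf_sd_n if noise_sd_n is None else noise_sd_n
    m_sys = params.body_mass_kg + external_load_kg
    m_body = params.body_mass_kg
    f0, v0 = params.f0_true_nkg, params.v0_true_ms
    jitter = rng.normal(0.0, velocity_jitter_sd) if velocity_jitter_sd > 0 else 0.0

    n_q = int(round(quiet_s * fs))
    n_u = int(round(unweight_s * fs))
    n_r = int(round(release_s * fs))
    a1 = 0.9 * np.pi / (2 * unweight_s)  # countermovement peak ~0.9 m/s downward

    def concentric_stats(a2, n_p):
        a = _jump_accel_profile(n_q, n_u, n_p, n_r, a1, a2, fs)
        v = np.concatenate([[0.0], np.cumsum((a[1:] + a[:-1]) / 2.0) / fs])
        grf = m_sys * (a + G)
        imin = int(np.argmin(v))
        pos = np.nonzero(v[imin:] > 0)[0]
        if pos.size == 0:
            return None
        start = imin + int(pos[0])
        low = np.nonzero(grf[start:] <= takeoff_threshold_n)[0]
        if low.size == 0:
            return None
        end = start + int(low[0])
        if end - start < 10:
            return None
        return a, v, grf, start, end

    def solve_a2(n_p):
        def mismatch(a2):
            st = concentric_stats(a2, n_p)
            if st is None:
                return -1e6
            _, v, grf, start, end = st
            mean_f = grf[start:end].mean() / m_body
            mean_v = v[start:end].mean()
            return mean_f - (f0 - (f0 / v0) * (mean_v - jitter))

        lo, hi = 1.0, 120.0
        if not (mismatch(lo) < 0 < mismatch(hi)):
            return None
        for _ in range(40):
            mid = 0.5 * (lo + hi)
            if mismatch(mid) < 0:
                lo = mid
            else:
                hi = mid
        return 0.5 * (lo + hi)

    def displacement(n_p, a2):
        st = concentric_stats(a2, n_p)
        _, v, _, start, end = st
        return float(np.trapezoid(v[start:end], dx=1.0 / fs))

    if target_displacement_m is None:
        n_p = int(round(push_s * fs))
        a2 = solve_a2(n_p)
        if a2 is None:
            raise InvalidParameterError("jump calibration failed for these parameters")
    else:
        # outer bisection on the push duration to hold the jump depth
        np_lo, np_hi = int(round(0.16 * fs)), int(round(0.70 * fs))
        best = None
        for _ in range(12):
            n_p = (np_lo + np_hi) // 2
            a2 = solve_a2(n_p)
            if a2 is None:
                np_lo = n_p + 1
                continue
            disp = displacement(n_p, a2)
            best = (n_p, a2)
            if abs(disp - target_displacement_m) < 0.005 or np_hi - np_lo <= 1:
                break
            if disp < target_displacement_m:
                np_lo = n_p + 1
            else:
                np_hi = n_p - 1
        if best is None:
            raise InvalidParameterError("jump calibration failed for these parameters")
        n_p, a2 = best
    push_s = n_p / fs

    a, v, grf_clean, start, end = concentric_stats(a2, n_p)
    takeoff = end
    t_take = takeoff / fs
    v_true = _analytic_velocity(t_take, quiet_s, unweight_s, push_s, release_s, a1, a2)
    apex = v_true**2 / (2 * G)
    # flight: a = -g until shortly past apex
    n_f = int(round((v_true / G + 0.05) * fs))
    grf = np.concatenate([grf_clean, np.zeros(n_f)])
    mean_f = float(grf_clean[start:end].mean())
    mean_v = float(v[start:end].mean())
    if noise > 0:
        contact = grf > 0
        grf = grf + np.where(contact, rng.normal(0.0, noise, grf.size), 0.0)
        grf = np.maximum(grf, 0.0)
    trace = Trace(grf, fs=fs, label="grf")
    log = EventLog(
        true_onset_index=n_q,
        concentric_start_index=start,
        takeoff_index=takeoff,
        takeoff_velocity_ms=float(v_true),
        apex_m=float(apex),
        mean_force_n=mean_f,
        mean_velocity_ms=mean_v,
    )
    return trace, log


def gen_fv_points(
    params: SubjectParams,
    loads_kg=(17, 30, 45, 60, 75),
    rng: Optional[np.random.Generator] = None,
    force_noise_sd_nkg: float = 0.7,
    velocity_noise_sd_ms: float = 0.02,
    v_range=(1.55, 0.70),
):
    """Per-load (mean force N, mean velocity m/s) pairs on the true FV
    line plus measurement noise (noise mostly on force, ~2% of F0; the
    small velocity noise keeps regression-attenuation bias negligible,
    and the moderate force noise keeps the Jensen inflation of the
    V0 = -F0/slope ratio estimator well below 2%).

    Returns (points, truth) where truth carries the noiseless pairs.
    """
    rng = np.random.default_rng() if rng is None else rng
    loads = np.asarray(loads_kg, dtype=float)
    v_true = np.linspace(v_range[0], v_range[1], loads.size)
    f_true = params.body_mass_kg * (params.f0_true_nkg
                                    - params.f0_true_nkg / params.v0_true_ms * v_true)
    v_obs = v_true + rng.normal(0.0, velocity_noise_sd_ms, loads.size)
    f_obs = f_true + params.body_mass_kg * rng.normal(0.0, force_noise_sd_nkg, loads.size)
    points = list(zip(f_obs.tolist(), v_obs.tolist()))
    truth = {"force_n": f_true.tolist(), "velocity_ms": v_true.tolist(),
             "loads_kg": loads.tolist()}
    return points, truth


# ---------------------------------------------------------------------------
# Two-group pre/post study tables
# ---------------------------------------------------------------------------

#: measure -> (baseline mean, between-subject SD, within-subject SD)
STUDY_MEASURES = {
    "mvf_n": (890.0, 185.0, 35.0),
    "f50_n": (151.4, 65.0, 25.0),
    "f100_n": (459.4, 130.0, 40.0),
    "f150_n": (621.1, 160.0, 40.0),
    "f0_nkg": (35.6, 5.4, 1.5),
    "v0_ms": (3.38, 0.51, 0.15),
    "p0_wkg": (29.8, 4.1, 1.2),
    "cmj15_wkg": (9.5, 1.8, 0.5),
    "pennation_vl_deg": (11.7, 1.6, 0.5),
    "fascicle_vl_mm": (124.2, 22.3, 6.0),
}


def gen_study(
    n_per_group: int = 12,
    effects: Optional[dict] = None,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    measures: Optional[dict] = None,
    time_effects: Optional[dict] = None,
    groups=("IHRT", "NT"),
):
    """Long-format two-group pre/post study table.

    ``effects`` maps measure name to a standardized group-by-time
    interaction (d, in between-subject SD units, added to the
    first-listed group at post); ``time_effects`` maps measure name to
    a standardized shift applied to everyone at post.  Returns
    ``(table, truths)``; the table has columns ``subject, group, time,
    measure, value``.
    """
    if n_per_group < 2:
        raise InvalidParameterError("need at least two subjects per group")
    if rng is None:
        rng = np.random.default_rng(seed)
    effects = effects or {}
    time_effects = time_effects or {}
    measures = measures or STUDY_MEASURES
    rows = []
    truths = {"effects": dict(effects), "time_effects": dict(time_effects)}
    subjects = [(f"S{k + 1:02d}", groups[0] if k < n_per_group else groups[1])
                for k in range(2 * n_per_group)]
    for name, (mu, sd_b, sd_w) in measures.items():
        d_gt = effects.get(name, 0.0)
        d_t = time_effects.get(name, 0.0)
        for subj, grp in subjects:
            base = mu + rng.normal(0.0, sd_b)
            pre = base + rng.normal(0.0, sd_w)
            post = base + d_t * sd_b + (d_gt * sd_b if grp == groups[0] else 0.0) \
                + rng.normal(0.0, sd_w)
            rows.append((subj, grp, "pre", name, pre))
            rows.append((subj, grp, "post", name, post))
    table = pd.DataFrame(rows, columns=["subject", "group", "time", "measure", "value"])
    return table, truths
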