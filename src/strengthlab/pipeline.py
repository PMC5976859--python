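"""End-to-end orchestration: synthetic study simulation and the full
analysis chain (isometric -> EMG -> jumps -> architecture -> stats).

``simulate_study`` writes a complete study directory (delimited trace
files plus manifests and a ground-truth sidecar) in exactly the layout
``run_study`` consumes:

    study_dir/
      subjects.csv                subject,group,body_mass_kg
      architecture.csv            tabulated ultrasound measurements
      truth.csv                   generator ground truth (not read by
                                  run_study; kept for validation)
      raw/<subject>/<session>/    session in {pre, pre2, post}
        isometric_manifest.csv    trial_id,trial_type,file,gravity_offset_n
        emg_manifest.csv          trial_id,kind,file
        jumps_manifest.csv        trial_id,kind,load_kg,attempt,file
        *.csv                     trace files (time_s,value / time_s,vm,vl,rf)

Day-2 repeats (session ``pre2``) exist for the isometric, EMG and
architecture assessments only, mirroring a between-day reliability
design; jumps are assessed once pre and once post.

``run_study`` emits tidy result tables (measures, reliability, ANOVA
effects, standardized differences) plus a run log carrying the config
hash and seed; reruns with the same config and data are byte-identical.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import architecture as arch
from . import emg as emg_mod
from . import isometric as iso
from . import jumps as jmp
from . import signal as sig
from . import stats as st
from . import synth
from .config import StudyConfig
from .errors import ManifestError, NoOnsetError, StrengthLabError

__all__ = ["simulate_study", "run_study"]

FLOAT_FMT = "%.6g"
ISO_SESSIONS = ("pre", "pre2", "post")
JUMP_SESSIONS = ("pre", "post")

#: pre -> post multiplicative change of the true parameters,
#: (first group, second group); modest, training-plausible responses
TRAINING_RESPONSE = {
    "mvf_true_n": (1.06, 1.06),
    "f0_true_nkg": (1.08, 1.08),
    "v0_true_ms": (0.98, 0.98),
    "emg_mvc_mv": (1.02, 1.02),
    "pennation_deg": (0.96, 1.02),
    "thickness_vl_mm": (1.03, 1.01),
}

#: day-to-day multiplicative jitter SD of the true parameters
DAY_JITTER_SD = {
    "mvf_true_n": 0.03,
    "emg_mvc_mv": 0.08,
    "pennation_deg": 0.05,
    "thickness_vl_mm": 0.02,
}

#: (muscle, site %) -> typical thickness in mm
THICKNESS_SITES = {
    ("VL", 20): 17.4, ("VL", 50): 25.7, ("VL", 60): 27.7,
    ("RF", 50): 23.8, ("RF", 60): 25.3,
    ("VI", 50): 21.5, ("VI", 60): 22.2,
    ("VM", 20): 20.7,
}


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

def _draw_subject(rng: np.random.Generator) -> synth.SubjectParams:
    body_mass = float(np.clip(rng.normal(76.1, 8.5), 55.0, 110.0))
    # every participant must be able to jump the heaviest load with a
    # plausible depth (a completing cohort is implicitly jump-capable)
    f0_floor = 1.45 * 9.81 * (1.0 + 75.0 / body_mass)
    return synth.SubjectParams(
        body_mass_kg=body_mass,
        mvf_true_n=float(np.clip(rng.normal(890.0, 187.0), 400.0, 1500.0)),
        f0_true_nkg=float(np.clip(rng.normal(35.6, 5.4), f0_floor, 55.0)),
        v0_true_ms=float(np.clip(rng.normal(3.38, 0.51), 2.0, 5.0)),
        lv_intercept=float(np.clip(rng.normal(2.0, 0.15), 1.5, 2.5)),
        lv_slope=float(np.clip(rng.normal(-0.02, 0.0025), -0.03, -0.012)),
        emg_mvc_mv=float(np.clip(rng.normal(0.24, 0.10), 0.08, 0.60)),
        pennation_deg=float(np.clip(rng.normal(11.7, 1.7), 7.0, 18.0)),
        thickness_vl_mm=float(np.clip(rng.normal(25.7, 2.6), 18.0, 34.0)),
    )


def _scaled(params: synth.SubjectParams, rng, group_idx: int, post: bool,
            day_jitter: bool) -> synth.SubjectParams:
    """Apply training response (post) and day-to-day jitter."""
    changes = {}
    for name, (a, b) in TRAINING_RESPONSE.items():
        mult = (a if group_idx == 0 else b) if post else 1.0
        changes[name] = getattr(params, name) * mult
    if day_jitter:
        for name, sd in DAY_JITTER_SD.items():
            changes[name] = changes.get(name, getattr(params, name)) \
                * float(np.exp(rng.normal(0.0, sd)))
    from dataclasses import replace
    return replace(params, **changes)


def _write_multichannel(path, traces: dict, fs: float) -> None:
    n = next(iter(traces.values())).n
    df = pd.DataFrame({"time_s": np.arange(n) / fs})
    for name, tr in traces.items():
        df[name] = tr.samples
    df.to_csv(path, index=False, float_format="%.5g")


def _simulate_isometric_session(cfg, params, rng, sdir: Path) -> None:
    rows = []
    gravity = 28.0  # resting limb-weight reading, N
    for k in range(cfg.n_mvc_trials):
        tr, _ = synth.gen_mvc_trial(params, rng, fs=cfg.force_fs_hz,
                                    gravity_offset_n=gravity)
        fname = f"mvc{k + 1:02d}.csv"
        sig.write_trace(tr, sdir / fname, float_format="%.5g")
        rows.append((f"mvc{k + 1:02d}", "mvc", fname, gravity))
    # two contaminated attempts exercise the screening rules
    artifacts = ["pretension", "low_effort"] + ["clean"] * (cfg.n_explosive_trials - 2)
    for k, artifact in enumerate(artifacts[: cfg.n_explosive_trials]):
        tr, _ = synth.gen_isometric_trial(params, artifact, rng, fs=cfg.force_fs_hz,
                                          gravity_offset_n=gravity)
        fname = f"exp{k + 1:02d}.csv"
        sig.write_trace(tr, sdir / fname, float_format="%.5g")
        rows.append((f"exp{k + 1:02d}", "explosive", fname, gravity))
    pd.DataFrame(rows, columns=["trial_id", "trial_type", "file", "gravity_offset_n"]) \
        .to_csv(sdir / "isometric_manifest.csv", index=False)


def _simulate_emg_session(cfg, params, rng, sdir: Path) -> None:
    rows = []
    mvc = synth.gen_mvc_emg(params, rng, fs=cfg.emg_fs_hz)
    _write_multichannel(sdir / "emg_mvc.csv",
                        {m.lower(): mvc.channels[m] for m in emg_mod.MUSCLES},
                        cfg.emg_fs_hz)
    rows.append(("emg_mvc", "mvc", "emg_mvc.csv"))
    for k in range(cfg.n_explosive_trials):
        ch, _ = synth.gen_emg_trial(params, rng, fs=cfg.emg_fs_hz)
        fname = f"emg_exp{k + 1:02d}.csv"
        _write_multichannel(sdir / fname,
                            {m.lower(): ch.channels[m] for m in emg_mod.MUSCLES},
                            cfg.emg_fs_hz)
        rows.append((f"emg_exp{k + 1:02d}", "explosive", fname))
    pd.DataFrame(rows, columns=["trial_id", "kind", "file"]) \
        .to_csv(sdir / "emg_manifest.csv", index=False)


def _true_prescribed_load(params, rng, cfg) -> float:
    """Load at the target velocity from noiseless prescription jumps."""
    pts = []
    for load in cfg.prescription_loads_kg:
        tr, log = synth.gen_cmj_trial(params, load, rng, fs=cfg.force_fs_hz,
                                      noise_sd_n=0.0)
        pts.append((load, log.mean_velocity_ms))
    model = jmp.fit_load_velocity(pts)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return jmp.load_at_velocity(model, cfg.target_velocity_ms)


def _simulate_jump_session(cfg, params, rng, sdir: Path) -> None:
    rows = []
    idx = 0

    def emit(kind, load, attempt):
        nonlocal idx
        idx += 1
        tr, _ = synth.gen_cmj_trial(params, load, rng, fs=cfg.force_fs_hz,
                                    velocity_jitter_sd=0.04)
        fname = f"jump{idx:03d}.csv"
        sig.write_trace(tr, sdir / fname, float_format="%.5g")
        rows.append((f"jump{idx:03d}", kind, load, attempt, fname))

    for load in cfg.incremental_loads_kg:
        for attempt in (1, 2):
            emit("incremental", load, attempt)
    for load in cfg.prescription_loads_kg:
        for attempt in (1, 2):
            emit("prescription", load, attempt)
    load15 = round(_true_prescribed_load(params, rng, cfg), 1)
    for rep in range(1, cfg.n_cmj15 + 1):
        emit("cmj15", load15, rep)
    pd.DataFrame(rows, columns=["trial_id", "kind", "load_kg", "attempt", "file"]) \
        .to_csv(sdir / "jumps_manifest.csv", index=False)


def _simulate_architecture(cfg, subjects, subject_params, rng) -> pd.DataFrame:
    rows = []
    for subj, group_idx in subjects:
        base = subject_params[subj]
        scale = base.thickness_vl_mm / THICKNESS_SITES[("VL", 50)]
        for session in ISO_SESSIONS:
            p = _scaled(base, rng, group_idx, post=(session == "post"), day_jitter=True)
            sess_scale = scale * p.thickness_vl_mm / base.thickness_vl_mm
            for (muscle, site), thick0 in sorted(THICKNESS_SITES.items()):
                true_thick = thick0 * sess_scale
                for image in (1, 2):
                    pts = np.maximum(true_thick + rng.normal(0.0, 0.4, 3), 1.0)
                    pen = ""
                    if muscle == "VL":
                        pen = round(float(np.clip(
                            p.pennation_deg + rng.normal(0.0, 0.5), 4.0, 35.0)), 2)
                    rows.append((subj, session, muscle, site, image,
                                 round(pts[0], 2), round(pts[1], 2), round(pts[2], 2),
                                 pen))
    return pd.DataFrame(rows, columns=[
        "subject", "timepoint", "muscle", "site_pct", "image_id",
        "point1_mm", "point2_mm", "point3_mm", "pennation_deg"])


def simulate_study(config: StudyConfig, out_dir) -> Path:
    """Write a complete synthetic two-group pre/post study directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    root_rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    groups = ("IHRT", "NT")
    n = config.n_per_group
    subjects = [(f"S{k + 1:02d}", 0 if k < n else 1) for k in range(2 * n)]

    subject_params = {}
    truth_rows = []
    sub_rows = []
    for subj, gi in subjects:
        p = _draw_subject(root_rng)
        subject_params[subj] = p
        sub_rows.append((subj, groups[gi], round(p.body_mass_kg, 2)))
        for fld in ("body_mass_kg", "mvf_true_n", "f0_true_nkg", "v0_true_ms",
                    "emg_mvc_mv", "pennation_deg", "thickness_vl_mm"):
            truth_rows.append((subj, fld, getattr(p, fld)))
    pd.DataFrame(sub_rows, columns=["subject", "group", "body_mass_kg"]) \
        .to_csv(out / "subjects.csv", index=False)
    pd.DataFrame(truth_rows, columns=["subject", "param", "value"]) \
        .to_csv(out / "truth.csv", index=False, float_format=FLOAT_FMT)

    for subj, gi in subjects:
        base = subject_params[subj]
        for session in ISO_SESSIONS:
            sdir = out / "raw" / subj / session
            sdir.mkdir(parents=True, exist_ok=True)
            p = _scaled(base, root_rng, gi, post=(session == "post"), day_jitter=True)
            _simulate_isometric_session(config, p, root_rng, sdir)
            _simulate_emg_session(config, p, root_rng, sdir)
        for session in JUMP_SESSIONS:
            sdir = out / "raw" / subj / session
            sdir.mkdir(parents=True, exist_ok=True)
            p = _scaled(base, root_rng, gi, post=(session == "post"), day_jitter=False)
            _simulate_jump_session(config, p, root_rng, sdir)

    arch_table = _simulate_architecture(config, subjects, subject_params, root_rng)
    arch_table.to_csv(out / "architecture.csv", index=False)
    config.to_yaml(out / "config.yaml")
    return out


# ---------------------------------------------------------------------------
# Analysis
# ---------------------------------------------------------------------------

def _ctx(stage, subject, trial, err):
    return StrengthLabError(f"stage={stage} subject={subject} trial={trial}: {err}")


def analyze_isometric_session(cfg: StudyConfig, sdir: Path, subject="?") -> dict:
    """Measures from one isometric session directory."""
    man_path = sdir / "isometric_manifest.csv"
    if not man_path.exists():
        raise ManifestError(f"missing manifest {man_path}")
    man = pd.read_csv(man_path)
    mvcs, explosive = [], []
    for rec in man.itertuples(index=False):
        tr = sig.read_trace(sdir / rec.file, label=str(rec.trial_id))
        tr = sig.butterworth_lowpass(tr, cfg.lowpass_cutoff_hz, cfg.filter_order)
        tr = iso.gravity_correct(tr, float(rec.gravity_offset_n))
        (mvcs if rec.trial_type == "mvc" else explosive).append((rec.trial_id, tr))
    if not mvcs:
        raise ManifestError(f"{sdir}: no MVC trials")
    mvc = iso.compute_mvf([t for _, t in mvcs])
    results = []
    for trial_id, tr in explosive:
        try:
            onset = sig.detect_force_onset(tr, cfg.trigger_sd_mult,
                                           cfg.baseline_window_ms)
        except NoOnsetError:
            nan = float("nan")
            results.append(iso.ExplosiveResult(
                nan, nan, nan, sig.OnsetResult(0, 0.0, sig.OnsetMethod.DERIVATIVE_ZERO_CROSSING),
                False, iso.RejectionReason.NO_ONSET, nan, nan))
            continue
        except StrengthLabError as err:
            raise _ctx("isometric", subject, trial_id, err) from err
        results.append(iso.screen_explosive(
            tr, onset, mvc.mvf, cfg.slope_limit, cfg.peak_fraction,
            cfg.slope_window_ms))
    summary = iso.summarize_explosive(results)
    tally = summary.rejection_tally
    return {
        "mvf_n": mvc.mvf,
        "f50_n": summary.f50_mean,
        "f100_n": summary.f100_mean,
        "f150_n": summary.f150_mean,
        "n_rejected_slope": tally.get("baseline_slope", 0),
        "n_rejected_peak": tally.get("low_peak", 0),
    }


def _read_emg_channels(cfg, path) -> emg_mod.EmgChannelSet:
    df = pd.read_csv(path)
    channels = {}
    for m in emg_mod.MUSCLES:
        col = m.lower()
        if col not in df.columns:
            raise ManifestError(f"{path}: missing EMG column {col}")
        tr = sig.Trace(df[col].to_numpy(dtype=float), fs=cfg.emg_fs_hz, label=m)
        channels[m] = sig.butterworth_bandpass(tr, *cfg.emg_band_hz, cfg.filter_order)
    return emg_mod.EmgChannelSet(channels=channels)


def analyze_emg_session(cfg: StudyConfig, sdir: Path, subject="?") -> dict:
    man_path = sdir / "emg_manifest.csv"
    if not man_path.exists():
        raise ManifestError(f"missing manifest {man_path}")
    man = pd.read_csv(man_path)
    mvc_rows = man[man["kind"] == "mvc"]
    if mvc_rows.empty:
        raise ManifestError(f"{sdir}: no MVC EMG trial")
    mvc_set = _read_emg_channels(cfg, sdir / mvc_rows.iloc[0]["file"])
    emg_mvc = {m: emg_mod.emg_mvc_rms(mvc_set.channels[m]) for m in emg_mod.MUSCLES}
    acts = []
    for rec in man[man["kind"] == "explosive"].itertuples(index=False):
        ch = _read_emg_channels(cfg, sdir / rec.file)
        try:
            onset = emg_mod.detect_emg_onset(ch, cfg.emg_k_sd, cfg.emg_sustain_ms,
                                             cfg.emg_baseline_ms)
            acts.append(emg_mod.windowed_activation(ch, onset, emg_mvc))
        except NoOnsetError:
            continue
        except StrengthLabError as err:
            raise _ctx("emg", subject, rec.trial_id, err) from err
    if not acts:
        raise ManifestError(f"{sdir}: no explosive EMG trial produced an onset")
    return {
        "emg_mvc_mv": float(np.mean([a.emg_mvc_mean_mv for a in acts])),
        "emg_0_50_pct": float(np.mean([a.rms_0_50 for a in acts])),
        "emg_50_100_pct": float(np.mean([a.rms_50_100 for a in acts])),
        "emg_100_150_pct": float(np.mean([a.rms_100_150 for a in acts])),
    }


def analyze_jump_session(cfg: StudyConfig, sdir: Path, body_mass_kg: float,
                         subject="?") -> dict:
    man_path = sdir / "jumps_manifest.csv"
    if not man_path.exists():
        raise ManifestError(f"missing manifest {man_path}")
    man = pd.read_csv(man_path)
    trials = {}
    for rec in man.itertuples(index=False):
        tr = sig.read_trace(sdir / rec.file, label=str(rec.trial_id))
        try:
            trial = jmp.analyze_jump(tr, body_mass_kg, float(rec.load_kg),
                                     cfg.quiet_window_s, cfg.takeoff_threshold_n)
        except StrengthLabError as err:
            raise _ctx("jumps", subject, rec.trial_id, err) from err
        trials.setdefault(str(rec.kind), []).append(trial)

    out = {}
    inc = trials.get("incremental", [])
    per_load = {}
    for t in inc:
        per_load.setdefault(t.external_load_kg, []).append(t)
    fv_pts = []
    for load in sorted(per_load):
        try:
            best = jmp.select_best_rep(per_load[load], cfg.displacement_bounds_m)
        except StrengthLabError:
            warnings.warn(f"{subject}: no valid repetition at {load:g} kg; "
                          "load dropped from the profile")
            continue
        fv_pts.append((best.mean_force_n, best.mean_velocity_ms))
        out[f"power_wkg_{load:g}"] = best.mean_power_w / body_mass_kg
    if len(fv_pts) >= 2:
        prof = jmp.fit_fv_profile(fv_pts, body_mass_kg)
        out.update({"f0_nkg": prof.f0, "v0_ms": prof.v0, "p0_wkg": prof.p0,
                    "slope_fv": prof.slope_fv, "fv_r2": prof.r2})

    pres = trials.get("prescription", [])
    by_load = {}
    for t in pres:
        by_load.setdefault(t.external_load_kg, []).append(t)
    if len(by_load) >= 2:
        pts = [(load, max(t.mpv_ms for t in reps))
               for load, reps in sorted(by_load.items())]
        model = jmp.fit_load_velocity(pts)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out["load_1ms_kg"] = jmp.load_at_velocity(model, cfg.target_velocity_ms)

    reps15 = trials.get("cmj15", [])
    if reps15:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out["cmj15_wkg"] = jmp.cmj15_summary(reps15, expected=cfg.n_cmj15,
                                                 body_mass_kg=body_mass_kg)
    return out


TWO_FACTOR_DVS = ("mvf_n", "f0_nkg", "v0_ms", "p0_wkg", "slope_fv", "cmj15_wkg",
                  "emg_mvc_mv", "load_1ms_kg", "pennation_vl", "fascicle_vl")

THREE_FACTOR = {
    "power_wkg": "load",
    "explosive_force": "window",
    "emg_activation": "window",
}


def _effects_frame(dv, effects):
    return pd.DataFrame([{
        "dv": dv, "term": e.term, "F": e.F, "p": e.p, "ges": e.ges,
        "magnitude": e.magnitude.value, "df1": e.df1, "df2": e.df2,
    } for e in effects])


def run_study(config: StudyConfig, data_dir, out_dir) -> dict:
    """Execute the full analysis chain on a study directory.

    Returns a dict of the output DataFrames, which are also written to
    ``out_dir`` as delimited text with a run log.
    """
    data = Path(data_dir)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    subj_path = data / "subjects.csv"
    if not subj_path.exists():
        raise ManifestError(f"missing subject table {subj_path}")
    subjects = pd.read_csv(subj_path).sort_values("subject")

    rows = []
    for rec in subjects.itertuples(index=False):
        subj, group, mass = rec.subject, rec.group, float(rec.body_mass_kg)
        for session in ISO_SESSIONS:
            sdir = data / "raw" / subj / session
            for name, val in analyze_isometric_session(config, sdir, subj).items():
                rows.append((subj, group, session, name, float(val)))
            for name, val in analyze_emg_session(config, sdir, subj).items():
                rows.append((subj, group, session, name, float(val)))
        for session in JUMP_SESSIONS:
            sdir = data / "raw" / subj / session
            for name, val in analyze_jump_session(config, sdir, mass, subj).items():
                rows.append((subj, group, session, name, float(val)))
    measures = pd.DataFrame(rows, columns=["subject", "group", "session",
                                           "measure", "value"])

    arch_path = data / "architecture.csv"
    if arch_path.exists():
        arch_long = arch.summarize_architecture(pd.read_csv(arch_path))
        arch_long = arch_long.merge(subjects[["subject", "group"]], on="subject")
        arch_long = arch_long.rename(columns={"timepoint": "session"})
        measures = pd.concat([measures, arch_long[["subject", "group", "session",
                                                   "measure", "value"]]],
                             ignore_index=True)
    measures = measures.sort_values(["measure", "subject", "session"],
                                    kind="stable").reset_index(drop=True)

    # ---- reliability: day 1 vs day 2 of the pre-training assessments
    rel_rows = []
    wide = measures.pivot_table(index=["subject", "measure"], columns="session",
                                values="value", observed=True)
    for measure in sorted(measures["measure"].unique()):
        if measure.startswith("n_rejected"):
            continue  # screening tallies, not physiological measures
        try:
            sub = wide.xs(measure, level="measure")[["pre", "pre2"]].dropna()
        except KeyError:
            continue
        if len(sub) < 3:
            continue
        r = st.reliability(sub["pre"].to_numpy(), sub["pre2"].to_numpy(),
                           config.icc_form, config.cv_mode)
        rel_rows.append({
            "measure": measure, "n": r.n,
            "test1_mean": sub["pre"].mean(), "test1_sd": sub["pre"].std(ddof=1),
            "test2_mean": sub["pre2"].mean(), "test2_sd": sub["pre2"].std(ddof=1),
            "cv_pct": r.cv_pct, "cv_lo": r.cv_ci95[0], "cv_hi": r.cv_ci95[1],
            "icc": r.icc, "icc_lo": r.icc_ci95[0], "icc_hi": r.icc_ci95[1],
        })
    reliability_tab = pd.DataFrame(rel_rows)

    # ---- pre/post long table for inference
    pp = measures[measures["session"].isin(["pre", "post"])].rename(
        columns={"session": "time"})

    anova_frames = []
    for dv in TWO_FACTOR_DVS:
        sub = pp[pp["measure"] == dv]
        if sub.empty:
            continue
        anova_frames.append(_effects_frame(
            dv, st.mixed_anova(sub, dv="value", within=["time"])))

    # three-factor: power across loads, force and EMG across latency windows
    def three_factor(dv_label, prefix_map):
        sub = pp[pp["measure"].isin(prefix_map)].copy()
        if sub.empty:
            return
        # keep only levels every subject has at both time points
        n_full = sub["subject"].nunique() * 2
        counts = sub.groupby("measure", observed=True).size()
        complete = counts[counts == n_full].index
        sub = sub[sub["measure"].isin(complete)]
        if sub.empty or sub["measure"].nunique() < 2:
            return
        sub["level"] = sub["measure"].map(prefix_map)
        anova_frames.append(_effects_frame(
            dv_label, st.mixed_anova(sub, dv="value",
                                     within=["time", "level"])))

    power_measures = {m: m.split("_")[-1] for m in pp["measure"].unique()
                      if m.startswith("power_wkg_")}
    three_factor("power_wkg", power_measures)
    three_factor("explosive_force", {"f50_n": "50", "f100_n": "100", "f150_n": "150"})
    three_factor("emg_activation", {"emg_0_50_pct": "0_50",
                                    "emg_50_100_pct": "50_100",
                                    "emg_100_150_pct": "100_150"})
    anova_tab = (pd.concat(anova_frames, ignore_index=True)
                 if anova_frames else pd.DataFrame())

    # ---- standardized differences per group plus between-group contrast
    eff_rows = []
    for dv in TWO_FACTOR_DVS:
        sub = pp[pp["measure"] == dv]
        if sub.empty:
            continue
        w = sub.pivot_table(index=["subject", "group"], columns="time",
                            values="value", observed=True).reset_index()
        changes = {}
        for grp in sorted(w["group"].unique()):
            g = w[w["group"] == grp]
            es = st.cohens_d(g["post"].to_numpy(), g["pre"].to_numpy(),
                             paired=True, ci_method=config.d_ci_method)
            changes[grp] = (g["post"] - g["pre"]).to_numpy()
            eff_rows.append({"measure": dv, "contrast": f"{grp}_post_vs_pre",
                             "d": es.d, "ci_lo": es.ci90[0], "ci_hi": es.ci90[1],
                             "magnitude": es.magnitude.value,
                             "inference": es.inference})
        if len(changes) == 2:
            (g1, c1), (g2, c2) = sorted(changes.items())
            es = st.cohens_d(c1, c2, paired=False, ci_method=config.d_ci_method)
            eff_rows.append({"measure": dv, "contrast": f"{g1}_vs_{g2}_change",
                             "d": es.d, "ci_lo": es.ci90[0], "ci_hi": es.ci90[1],
                             "magnitude": es.magnitude.value,
                             "inference": es.inference})
    effects_tab = pd.DataFrame(eff_rows)

    measures.to_csv(out / "measures.csv", index=False, float_format=FLOAT_FMT)
    reliability_tab.to_csv(out / "reliability.csv", index=False, float_format=FLOAT_FMT)
    anova_tab.to_csv(out / "anova.csv", index=False, float_format=FLOAT_FMT)
    effects_tab.to_csv(out / "effects.csv", index=False, float_format=FLOAT_FMT)
    log = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_subjects": int(len(subjects)),
        "n_measure_rows": int(len(measures)),
    }
    with open(out / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2, sort_keys=True)
    return {"measures": measures, "reliability": reliability_tab,
            "anova": anova_tab, "effects": effects_tab, "log": log}
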