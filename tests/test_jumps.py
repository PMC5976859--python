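"""Jump kinetics: COM velocity, phases, FV profile, load prescription."""

import numpy as np
import pytest

from strengthlab.errors import (
    DegeneratePhaseError,
    InvalidParameterError,
    InvalidProfileError,
    NoTakeoffError,
    NotQuietError,
)
from strengthlab.jumps import (
    G,
    ExtrapolationWarning,
    LoadVelocityModel,
    analyze_jump,
    cmj15_summary,
    com_velocity,
    concentric_means,
    concentric_phase,
    fit_fv_profile,
    fit_load_velocity,
    load_at_velocity,
    propulsive_from_velocity,
    propulsive_means,
    select_best_rep,
    system_weight,
)
from strengthlab.signal import Trace
from strengthlab.synth import gen_cmj_trial

FS = 1000.0


class TestSystemWeight:
    def test_constant(self):
        q = system_weight(Trace(np.full(1000, 750.0), fs=FS))
        assert q.weight_n == pytest.approx(750.0)
        assert q.sd_n == 0.0

    def test_noisy_standard_error(self, rng):
        x = 750.0 + rng.normal(0.0, 1.0, 1000)
        q = system_weight(Trace(x, fs=FS), quiet_window_s=(0.0, 1.0))
        # SE of the mean over ~1000 samples is ~0.032 N
        assert q.weight_n == pytest.approx(750.0, abs=0.2)

    def test_oscillating_not_quiet(self):
        t = np.arange(1000) / FS
        x = 750.0 + 50.0 * np.sin(2 * np.pi * 3 * t)
        with pytest.raises(NotQuietError):
            system_weight(Trace(x, fs=FS))


class TestComVelocity:
    def test_grf_equals_weight_gives_zero(self):
        v = com_velocity(Trace(np.full(1000, 800.0), fs=FS), 80.0, 800.0)
        assert np.allclose(v.samples, 0.0)

    def test_constant_net_force(self):
        mass = 80.0
        grf = np.full(301, 800.0 + 2.0 * mass)
        v = com_velocity(Trace(grf, fs=FS), mass, 800.0)
        assert v.samples[300] == pytest.approx(0.6, rel=1e-6)

    def test_half_sine_pulse_analytic(self):
        mass, T = 80.0, 0.4
        t = np.arange(int(T * FS) + 1) / FS
        pulse = 400.0 * np.sin(np.pi * t / T)
        v = com_velocity(Trace(800.0 + pulse, fs=FS), mass, 800.0)
        analytic = (400.0 / mass) * (T / np.pi) * (1 - np.cos(np.pi * t / T))
        assert np.max(np.abs(v.samples - analytic)) < 1e-3 * analytic.max()

    def test_gauge_invariance(self, rng):
        grf = 800.0 + rng.normal(0.0, 30.0, 2000)
        v1 = com_velocity(Trace(grf, fs=FS), 80.0, 800.0)
        v2 = com_velocity(Trace(grf + 123.0, fs=FS), 80.0, 923.0)
        assert np.array_equal(v1.samples, v2.samples)


class TestPhases:
    def test_generator_events_recovered(self, rng, subject_params):
        trace, log = gen_cmj_trial(subject_params, 30.0, rng, noise_sd_n=0.0)
        trial = analyze_jump(trace, subject_params.body_mass_kg, 30.0)
        assert abs(trial.concentric[0] - log.concentric_start_index) <= 1
        assert abs(trial.concentric[1] - log.takeoff_index) <= 1

    def test_no_takeoff(self):
        grf = Trace(np.full(1000, 800.0), fs=FS)
        v = com_velocity(grf, 80.0, 800.0)
        with pytest.raises(NoTakeoffError):
            concentric_phase(grf, v)

    def test_takeoff_threshold_zero_boundary(self):
        # GRF touches exactly 0 N: with threshold 0 the phase ends there
        grf_arr = np.concatenate([np.full(500, 800.0),
                                  np.linspace(800, 0, 300),
                                  np.zeros(100)])
        grf = Trace(grf_arr, fs=FS)
        v = grf.with_samples(np.concatenate([np.full(500, -0.1),
                                             np.full(400, 1.0)]))
        start, end = concentric_phase(grf, v, takeoff_threshold_n=0.0)
        assert grf_arr[end] == 0.0
        assert np.all(grf_arr[start:end] > 0.0)

    def test_concentric_means_linear_ramp(self):
        n = 200
        grf = Trace(np.full(n, 1000.0), fs=FS)
        v = grf.with_samples(np.linspace(0.0, 1.0, n))
        mf, mv, mp = concentric_means(grf, v, (0, n))
        assert mf == pytest.approx(1000.0)
        assert mv == pytest.approx(0.5, abs=0.01)
        assert mp == pytest.approx(500.0, rel=0.01)

    def test_degenerate_phase(self):
        grf = Trace(np.full(100, 1000.0), fs=FS)
        with pytest.raises(DegeneratePhaseError):
            concentric_means(grf, grf, (0, 5))

    def test_means_match_direct_sums(self, rng, subject_params):
        trace, _ = gen_cmj_trial(subject_params, 45.0, rng)
        trial = analyze_jump(trace, subject_params.body_mass_kg, 45.0)
        s, e = trial.concentric
        f = trace.samples[s:e]
        v = trial.com_velocity.samples[s:e]
        assert trial.mean_force_n == pytest.approx(f.sum() / f.size)
        assert trial.mean_power_w == pytest.approx((f * v).sum() / f.size)


class TestPropulsive:
    def test_on_ground_equals_concentric(self, rng, subject_params):
        trace, _ = gen_cmj_trial(subject_params, 17.0, rng, noise_sd_n=0.0)
        trial = analyze_jump(trace, subject_params.body_mass_kg, 17.0)
        # GRF >= 0 implies a >= -g, so the sub-phase is the whole phase
        assert trial.mpv_ms == pytest.approx(trial.mean_velocity_ms)
        assert trial.mpp_w == pytest.approx(trial.mean_power_w)

    def test_constant_positive_acceleration_included(self):
        mass = 80.0
        grf = Trace(np.full(300, mass * (G + 1.0)), fs=FS)
        v = grf.with_samples(np.linspace(0.1, 0.4, 300))
        mpv, _ = propulsive_means(grf, v, (0, 300), mass)
        assert mpv == pytest.approx(0.25, abs=0.01)

    def test_velocity_source_truncates_at_free_fall(self):
        # bar velocity keeps rising, then decelerates below -g (release)
        fs = 1000.0
        up = np.linspace(0.0, 2.0, 301)
        fall = 2.0 - G * 1.5 * np.arange(1, 201) / fs
        v = Trace(np.concatenate([[-0.01], up, fall]), fs=fs)
        mpv, mpp = propulsive_from_velocity(v, moved_mass_kg=50.0)
        assert mpv == pytest.approx(1.0, abs=0.02)


class TestBestRep:
    class _Rep:
        def __init__(self, mean_v, disp):
            self.mean_velocity_ms = mean_v
            self.displacement_m = disp

    def trial(self, mean_v, disp=0.3):
        return self._Rep(mean_v, disp)

    def test_highest_mean_velocity(self):
        reps = [self.trial(1.1), self.trial(1.3)]
        assert select_best_rep(reps) is reps[1]

    def test_single_rep_identity(self):
        reps = [self.trial(1.1)]
        assert select_best_rep(reps) is reps[0]

    def test_tie_prefers_earlier(self):
        reps = [self.trial(1.2), self.trial(1.2)]
        assert select_best_rep(reps) is reps[0]

    def test_displacement_gate(self):
        reps = [self.trial(2.0, disp=0.05), self.trial(1.0, disp=0.3)]
        assert select_best_rep(reps) is reps[1]
        with pytest.raises(DegeneratePhaseError):
            select_best_rep([self.trial(1.0, disp=0.05)])


class TestFvProfile:
    def test_exact_line(self):
        v = np.array([0.5, 1.0, 1.5, 2.0, 2.5])
        mass = 70.0
        force = mass * (40.0 - 10.0 * v)
        prof = fit_fv_profile(list(zip(force, v)), mass)
        assert prof.f0 == pytest.approx(40.0)
        assert prof.v0 == pytest.approx(4.0)
        assert prof.slope_fv == pytest.approx(-10.0)
        assert prof.p0 == pytest.approx(40.0)
        assert prof.r2 == pytest.approx(1.0)

    def test_two_points_exact(self):
        mass = 70.0
        pts = [(mass * 30.0, 1.0), (mass * 20.0, 2.0)]
        prof = fit_fv_profile(pts, mass)
        assert prof.f0 == pytest.approx(40.0)
        assert prof.slope_fv == pytest.approx(-10.0)

    def test_identities_hold_exactly(self, rng):
        for _ in range(20):
            v = rng.uniform(0.5, 3.0, 5)
            f = rng.uniform(500.0, 3000.0, 5) - 600.0 * v
            try:
                prof = fit_fv_profile(list(zip(f, v)), 75.0)
            except InvalidProfileError:
                continue
            assert prof.p0 == prof.f0 * prof.v0 / 4.0
            assert prof.slope_fv == pytest.approx(-prof.f0 / prof.v0, rel=1e-12)

    def test_positive_slope_rejected(self):
        pts = [(1000.0, 1.0), (2000.0, 2.0)]
        with pytest.raises(InvalidProfileError):
            fit_fv_profile(pts, 75.0)


class TestLoadVelocity:
    def test_exact_line(self):
        model = fit_load_velocity([(20, 1.6), (40, 1.2), (60, 0.8)])
        assert model.slope == pytest.approx(-0.02)
        assert model.intercept == pytest.approx(2.0)
        assert model.r2 == pytest.approx(1.0)

    def test_load_at_one_ms(self):
        model = fit_load_velocity([(20, 1.6), (40, 1.2), (60, 0.8)])
        assert load_at_velocity(model, 1.0) == pytest.approx(50.0)

    def test_target_at_intercept_flags_boundary(self):
        model = fit_load_velocity([(20, 1.6), (40, 1.2), (60, 0.8)])
        with pytest.warns(ExtrapolationWarning):
            assert load_at_velocity(model, 2.0) == pytest.approx(0.0)

    def test_target_below_observed_range_warns(self):
        model = fit_load_velocity([(20, 1.6), (40, 1.2), (60, 0.8)])
        with pytest.warns(ExtrapolationWarning):
            load_at_velocity(model, 0.75)

    def test_invalid_slope(self):
        model = LoadVelocityModel(slope=0.01, intercept=1.0, r2=1.0,
                                  points=((20, 1.2), (40, 1.4)))
        with pytest.raises(InvalidProfileError):
            load_at_velocity(model, 1.0)

    def test_identical_loads_rejected(self):
        with pytest.raises(InvalidParameterError):
            fit_load_velocity([(40, 1.2), (40, 1.3)])


class TestCmj15:
    def test_identical_reps(self):
        assert cmj15_summary([10.0] * 15) == pytest.approx(10.0)

    def test_short_series_warns_and_averages(self):
        with pytest.warns(UserWarning):
            assert cmj15_summary([8.0, 12.0]) == pytest.approx(10.0)

    def test_fatigue_decay_matches_series_oracle(self):
        # independent oracle: explicit geometric series accumulation
        reps = [12.0 * 0.98 ** (k - 1) for k in range(1, 16)]
        expect = 0.0
        for r in reps:
            expect += r
        expect /= 15.0
        assert cmj15_summary(reps) == pytest.approx(expect, abs=1e-12)
        assert expect == pytest.approx(10.457, abs=0.001)

    def test_per_kg_normalization(self):
        assert cmj15_summary([700.0] * 15, body_mass_kg=70.0) == pytest.approx(10.0)

    def test_empty_errors(self):
        with pytest.raises(InvalidParameterError):
            cmj15_summary([])
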