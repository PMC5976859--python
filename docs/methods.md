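# Methods

This note documents the models, algorithmic choices and defaults of
strengthlab, in the order the pipeline runs. Nothing here states an
empirical result the test suite or `scripts/acceptance.py` does not
itself compute.

## Signal model and filtering

All raw signals are uniformly sampled `Trace` objects (force and GRF
in newtons at 1 kHz, EMG in millivolts at 2 kHz). Filters are
Butterworth designs applied forward–backward (`sosfiltfilt`). The
zero-phase application is a deliberate choice: onset-latency analysis
requires phase fidelity, and a causal filter would delay every onset
by the group delay. The cost is that the effective order doubles (a
"4th-order 150 Hz low-pass" acts as 8th-order in magnitude), which we
accept. Traces shorter than the filter's edge-padding requirement are
rejected rather than silently padded.

## Force onset detection

The detector implements the last-zero-crossing rule on the first
derivative of the filtered force:

1. baseline mean and SD from the first 200 ms of the trial;
2. trigger = first sample above mean + 8·SD (a trigger inside the
   baseline window raises a suspicious-baseline error);
3. first derivative by central differences;
4. walking back from the trigger, the onset is the last upward
   crossing (derivative ≤ 0 then > 0, resolved to the later sample);
5. on noisy signals the candidate is then advanced to the last sample
   still inside the baseline noise band (mean + 1·SD).

Step 5 exists because zero-phase filtering smears a fraction of the
rising edge backward in time, which biases the raw derivative crossing
a few milliseconds early; the band refinement removes that bias. For
noiseless signals the baseline SD is zero and step 5 is a no-op, so
noiseless ramps are located exactly at the first rising sample. The
trigger multiplier (8 SD) and band multiplier (1 SD) are exposed in
`StudyConfig`.

Manual-override workflows are supported implicitly: every consumer
takes an `OnsetResult`, which can be constructed by hand at a visually
confirmed index.

## Contraction screening

The pre-onset baseline (100 ms immediately before the onset) is fit by
least squares; attempts with |slope| > 1.5 signal-units/s are
discarded (pre-tension / countermovement), then attempts peaking below
75% of the session MVF (sub-maximal effort). The slope threshold is
expressed in the recorded signal's units per second; no lever-arm
conversion between force and torque is attempted, since the moment arm
is an acquisition property. Note the statistics of this rule: with
baseline noise of SD σ over a 100-sample window at 1 kHz the OLS slope
estimate has an SD of roughly 7σ per second after 150 Hz filtering
(noise correlation included), so the 1.5 N/s criterion is only
meaningful on quiet baselines (σ well below ~0.3 N). The synthetic
strain-gauge noise default (0.1 N RMS) reflects that; force-onset
*detection* is separately stress-tested at 1–3 N noise.

F50/F100/F150 are read at exact samples at 1 kHz and by linear
interpolation at other rates. Of the accepted attempts, the three with
the highest F100 are averaged; ties are broken in favour of the
earlier attempt (stable sort), making the selection deterministic.

## EMG activation

EMG_MVC is the RMS over a 500 ms epoch centred on the peak rectified
sample of the maximal contraction (clipped at trace edges with a
warning). The explosive-contraction onset, manual in typical
laboratory practice, is automated as a deflection detector: because
raw EMG oscillates through zero, a sustained-deviation test on the raw
signal would reset at every zero crossing, so the trigger runs on a
moving-RMS envelope (window = the 10 ms sustain parameter) exceeding
3 baseline SDs, and the onset is the last crossing of the baseline
mean on the raw signal before the trigger. The overall onset is the
earliest channel (the first muscle activated). Windowed activation
uses half-open sample windows tiling [onset, onset + 150 ms), is
normalized per muscle by that muscle's EMG_MVC and only then averaged
across muscles, making the result invariant to per-channel gain.

## Jump kinetics

System weight comes from a quiet-stance window (default the first
0.4 s) guarded by a 5 N stillness gate. Integration starts at the last
stationary sample before movement (|net GRF| > 10 N sustained 50 ms),
using the cumulative trapezoid at the sampling interval. Velocity is
invariant to adding the same constant to GRF and weight (gauge
invariance), which the tests assert to 1e-12.

The concentric phase starts at the first sample with v > 0 after the
countermovement velocity minimum and ends at the first subsequent
sample with GRF at or below the 5 N take-off threshold (boundary
semantics: a sample exactly at the threshold counts as take-off).
Repetition selection requires a concentric COM displacement inside
[0.15, 0.60] m (configurable) and then takes the highest mean
concentric velocity, earlier repetition on ties.

The propulsive sub-phase is defined as the concentric samples with
acceleration ≥ −g, the standard velocity-based-training convention.
For a force-plate signal GRF ≥ 0 implies a ≥ −g, so the sub-phase
equals the whole concentric phase; the definition matters for
barbell-transducer signals, where `propulsive_from_velocity`
differentiates the velocity and truncates at free fall. The pipeline
itself analyzes all jumps (including the 15-repetition test) from GRF,
one consistent measurement model; transducer input is supported at the
library level but cross-device equivalence is not asserted.

The force–velocity profile is an OLS fit of body-mass-normalized
concentric force on concentric velocity. `FVProfile` stores the
intercept (F0) and slope; V0 = −F0/slope and P0 = F0·V0/4 are derived
properties, so the documented identities hold exactly for every fit by
construction. The velocity-axis intercept is computed from the fitted
coefficients, never by re-fitting v on F. A non-negative slope raises
an invalid-profile error. Load prescription inverts the load–velocity
line at the 1 m/s target and warns when the prescribed load
extrapolates more than 25% beyond the fitted load range or the target
velocity lies outside the observed velocities.

## Muscle architecture

Inputs are measured distances and angles, not images. Site thickness
is the arithmetic mean of the three evenly spaced inter-aponeurosis
distances. Fascicle length is computed per measurement entry as
thickness / sin(θ) and then averaged — a flat mean over site × image ×
repeat with equal weights, chosen because no nesting is implied by the
measurement protocol (a hierarchical mean is a one-line change in
`aggregate_vl` consumers if needed). Missing sites reduce the
averaging pool with a warning rather than failing.

## Statistics

**Reliability.** ICC defaults to the two-way random, absolute
agreement, single-measure form — the appropriate form for test–retest
with the same rater and device — computed via pingouin, with the
consistency form (ICC3) available by configuration; the ANOVA-based
estimator can legitimately go negative on noisy variables. CV defaults
to the typical-error convention, 100·(SD of within-pair
differences/√2)/grand mean, with a chi-squared CI on the typical-error
variance (df = n−1); a per-subject-CV mean is available by
configuration. Degenerate perfect agreement short-circuits to
ICC = 1, CV = 0 with point CIs.

**Mixed ANOVA.** One between-subject factor plus one or two
within-subject factors, computed from the classical sums-of-squares
partition with subject-level error strata (the univariate
repeated-measures approach): the between effect is tested against
subjects-within-groups, each within effect and its group interaction
against its own factor × subjects-within-groups stratum. Marginal
means are observed (weighted) means; with a single between factor and
complete within-cells the frequencies are proportional and the
partition is exact, which the tests assert at machine precision.
Generalized eta-squared divides each effect SS by itself plus *all*
subject-related error SS, the definition that makes the index
comparable across designs; it is invariant to affine rescaling of the
dependent variable. No sphericity correction is applied by default.
No installed package computes this design with ηG² (pingouin's
mixed ANOVA is limited to one within factor and reports partial
eta-squared), so the partition is implemented here and cross-checked
against pingouin's F and p on the two-factor case and against
hand-computed sums of squares on toy data. A constant dependent
variable yields F = 0, ηG² = 0 rather than 0/0.

**Effect sizes.** Independent samples use the pooled-SD Cohen's d;
paired samples standardize the mean change by the *pre-test* SD, which
avoids the inflation the change-score SD suffers when pre and post are
correlated (the pre-SD is also the scale on which smallest worthwhile
changes are defined). 90% CIs use the noncentral-t pivot by default
(for the paired case the exact pivot on the change-score metric,
rescaled to the pre-SD metric — an approximation we document rather
than hide); a normal approximation is available. Magnitude thresholds:
|d| > 0.2 small, > 0.6 moderate, > 1.2 large, > 2 very large.

**Magnitude-based inference.** The sampling distribution of the true
standardized effect is approximated as normal with SE recovered from
the 90% CI. Probabilities that the effect exceeds +0.2, lies within
±0.2, or is below −0.2 (the smallest worthwhile change) are mapped to
confidence words at 25 / 75 / 95 / 99.5% — the conventional cut-points
for possibly / likely / most likely / almost certainly — combined with
the magnitude of the point estimate; when both substantive directions
exceed 5% the verdict is "unclear". These labels are descriptive
conveniences layered on the CI, not a replacement for it.

## Synthetic data

The generator emulates the *structure* of the laboratory signals, not
muscle physiology:

- **Explosive force rise**: an offset-subtracted logistic,
  plateau·(s(t)−s(0))/(1−s(0)) with midpoint 80 ms and scale 30 ms,
  which starts exactly at zero with a finite rate of force development
  (~1.7 kN/s at the default 801 N plateau) and reaches ~22/64/90% of
  the plateau at 50/100/150 ms — proportions in the range reported for
  explosive knee extensions. The closed form is exported so tests can
  compare pipeline output against it. Artifacts: pre-tension adds a
  2.5 N/s baseline drift (beyond the 1.5 N/s limit); low effort caps
  the plateau at 60% MVF (below the 75% rule).
- **EMG**: amplitude-modulated band-limited (6–450 Hz) Gaussian noise
  with a 30 ms onset ramp and per-muscle onset stagger; a
  phenomenological, not physiological, model — it has realistic
  bandwidth and envelope but no motor-unit structure.
- **Jumps**: piecewise half-sine net-acceleration segments (quiet →
  unweighting → push → release to −g), with the push amplitude solved
  by bisection so the concentric means lie exactly on the subject's
  true force–velocity line, and the push duration solved so the
  concentric displacement matches a constant target depth (0.32 m),
  mirroring the constant-depth instruction of real protocols. Take-off
  velocity and flight apex are logged from the closed-form velocity at
  the sampled take-off instant, so impulse–momentum closure can be
  tested non-circularly. Generated GRF is non-negative everywhere.
- **Per-load FV points** (`gen_fv_points`): noise mostly on force
  (0.7 N/kg, ~2% of F0) with small velocity noise (0.02 m/s). The
  asymmetry is deliberate: velocity noise attenuates the OLS slope
  (errors-in-variables), and slope noise inflates V0 = −F0/slope by
  Jensen's inequality; at these levels both biases stay well under the
  2% recovery tolerance the tests assert.
- **Study tables** (`gen_study`): subject intercepts (between-SD) plus
  pre/post within-SD errors, with optional standardized time and
  group×time shifts in between-SD units. Used for the type-I-error and
  power calibration of the mixed ANOVA.
- **Simulated cohorts** (`simulate_study`): subject parameters drawn
  around the descriptive statistics above (MVF 890 ± 187 N, F0 35.6 ±
  5.4 N/kg, V0 3.38 ± 0.51 m/s, pennation 11.7°, VL thickness
  25.7 mm, body mass 76.1 ± 8.5 kg), with F0 floored so every subject
  can jump the heaviest (75 kg) load at a plausible depth — a
  completing cohort is implicitly jump-capable. Day-to-day
  log-normal jitter (3% strength, 8% EMG amplitude, 2% thickness, 5%
  pennation) produces realistic between-day reliability; pre→post
  multiplicative training responses are modest and group-specific
  (e.g. +6% MVF in both groups, opposite small pennation trends).

What passing tests therefore show: the pipeline recovers what the
generator put in — onsets, phases, FV intercepts, injected effects —
under the stated noise models. They do not show robustness to
artifacts the generator does not produce (electrode movement, plate
drift, partial foot contact, non-linear load–velocity relationships).

## Determinism and sizes

All randomness flows from one seed through `numpy` `SeedSequence`
spawning. `simulate_study` writes delimited text traces with fixed
float formatting, and `run_study` sorts every table before writing, so
reruns with the same seed and configuration are byte-identical (the
run log records the configuration hash). Default problem sizes — 24
subjects (12 per group), 3 MVC + 10 explosive trials per session, two
attempts per load, 15 repeated jumps, 500 replicates for the
calibration simulations — keep a full simulate → analyze round trip in
the low minutes on one core.

## Known limitations

- The 75%-MVF screening rule uses the same-session MVF; session-best
  versus day-best is not distinguished.
- The paired effect-size CI rescales an exact pivot between SD
  metrics; coverage is approximate when pre and change SDs differ
  greatly.
- Mixed-ANOVA marginal means are weighted; with very unequal group
  sizes the between-subject main effects correspond to Type-I-style
  weighted contrasts, not unweighted means.
- MBI confidence wording follows fixed conventional cut-points; users
  who reject the MBI framework can read the d ± CI columns directly.
- The EMG and jump generators are phenomenological; parameters were
  chosen for realistic first- and second-order statistics, not
  mechanism.
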