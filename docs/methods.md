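# Methods

This note documents the models, numerical choices and limitations behind the
package, in the order the pipeline runs them.

## Synthetic study model

The generator emulates the recordings of a repeated-sprint BFR study —
10-s all-out sprints, 20-s active recovery at 20 W, ridden to task failure,
one test per occlusion condition (0/45/60 % of pulse-elimination pressure),
default 11 participants — with enough physiological structure that the
downstream chain faces realistic geometry, while keeping every true value
exactly controllable.

**Crank power.** Sprint k has target mean power `peak × (1 − d)^k` (geometric
decrement `d`). Each sprint is a trapezoid: a 0.5-s linear rise from the 20-W
recovery resistance to a plateau solved so the sprint's time average hits the
target exactly; white noise (default SD 20 W) is added sample-wise. The
trapezoid makes the per-sprint mean well defined and analytically checkable.
Per-sprint decrement rates differ by condition (0.019 / 0.045 / 0.070 at
0/45/60 %) so the percent-decrement fatigue index lands in the mid-20s
regardless of set length, as observed for this protocol.

**Cadence.** ~115 rpm during sprints with a mild drift across the set,
85 rpm in recovery; in the final sprint cadence decays below the 70-rpm
threshold for its last 2 s, so the task-failure detector and the generated
sprint count agree by construction.

**NIRS.** Deoxyhemoglobin rises mono-exponentially during each sprint
(τ_rise = 3 s), holds for a 2-s reoxygenation delay after sprint end, then
relaxes mono-exponentially to baseline (τ_rec = 8 s). The excursion
amplitude per sprint is normalized so the noise-free within-sprint
max − min equals the schedule entry exactly. [O₂Hb] mirrors the shape
downward (default 0.8× the [HHb] schedule at 0 %, smaller fractions under
occlusion so that Δ[tHb] — the blood-volume surrogate — grows with cuff
pressure), TSI falls in % (0.5 %/μM of the schedule). The pedal-stroke
artifact is a sinusoid at the pedalling frequency (1.4 Hz, default 3 μM on
the chromophores, attenuated 10× into TSI), plus optional linear drift and
white noise; artifact, drift and noise are superimposed on the stored
noise-free component, never folded into it, so oracles never re-derive truth
from noisy data. The 2-s reoxygenation delay matters: muscle reoxygenation
onset lags sprint end by a couple of seconds in practice, and without that
plateau the 0.2-Hz zero-phase filter shaves ~0.6–1.0 μM off every
sprint-end peak, which would misrepresent what the filter does to real
recordings. The within-set delta schedule declines linearly (default −30 %
muscle, growing cerebral excursions), emulating progressive failure to fully
deoxygenate as the set proceeds.

**Neuromuscular assessment.** The force trace holds a raised-cosine ramp to
an exactly flat MVC plateau, a superimposed doublet delivered on the plateau
(so voluntary force at the stimulus equals MVC and the activation formula
inverts exactly: superimposed amplitude = (1 − VAL/100) × P100), then
resting P100, P10 and single-twitch responses at exactly 2-s spacing, each
an alpha-function transient whose peak equals the target amplitude on the
sample grid. The EMG trace carries 20–450-Hz band-limited Gaussian noise
enveloped by the voluntary force shape and rescaled so the RMS over the
250-ms epoch centred on the first peak-force sample equals its target
exactly, plus a biphasic (windowed single-cycle sine) M-wave of exact
peak-to-peak amplitude 5 ms after the twitch stimulus.

**Cardiorespiratory channels.** Breath-by-breath V̇O₂ uses irregular breath
intervals (uniform 0.7–1.5 s) on a saturating-exponential rise toward the
per-test target (τ = 30 s); heart rate (1 Hz) and SpO₂ (0.2 Hz) are
saturating traces toward their targets with white noise.

**Condition effects and heterogeneity.** Each endpoint has a participant
random intercept (normal, preset SD) shared across conditions, a condition
factor (multiplicative for capacity endpoints, level-setting for the
activation/ratio endpoints) and a residual draw per test. The preset factors
are patterned after the magnitudes this protocol produces in the literature
(sprint count −47.4 %/−65.8 % at 45/60 %; V̇O₂ peak −12.6 %/−18.2 %; MVC,
VAL, P10/P100 and RMS/M-wave pre/post levels of the order seen in published
group tables). They are generator presets with ground truth attached, not
reproductions of any dataset: group SDs are chosen to resemble that order of
magnitude, and passing recovery tests shows the pipeline recovers what the
generator injected, not that real muscle behaves this way.

A lightweight companion (`simulate_endpoint_table`) draws endpoint tables
directly from the additive random-intercept model the mixed-model stage
assumes; the calibration simulations (type-I error, power, coverage) use it
because signal-level generation would add runtime without changing what those
simulations test.

## NIRS processing

Filtering is `scipy.signal.filtfilt` with a 4th-order low-pass Butterworth
at 0.2 Hz: zero phase, squared magnitude (attenuation in dB doubles), odd-
reflection padding of 3 × (order + 1) samples; traces too short for the
padding are rejected rather than truncated. At the 10-Hz NIRS rate the
1.4-Hz pedal artifact is attenuated by ~140 dB (cascaded), so post-filter
noise is dominated by what leaks below ~0.2 Hz.

Segmentation finds local maxima of the filtered [HHb] with a minimum
separation of 0.7 × the expected 30-s sprint cycle and a prominence floor
(default 1 μM). Each sprint start is the last sample within 10 % of the
local rise above the preceding trough. The 10 % rise-onset convention is a
de-biased minimum estimator: the valley between sprints is nearly flat on
its decay side, so a raw argmin sits 1–2 s early, while the rise-onset
crossing is within ±0.2 s of the true sprint start on synthetic data. The
trough location itself is kept on the timeline and anchors the per-sprint
minimum search, so Δ spans the full pre-sprint trough to deoxygenation peak.
An ergometer timeline, when available, takes precedence over detection. A
flat signal yields an empty timeline and a warning, not an error.

Set-duration normalization maps fraction f to the 1-based sprint index
f × n; fractional indices interpolate linearly between neighbouring sprints,
f = 1 returns the final sprint exactly, and indices below 1 clamp to the
first sprint. With n a multiple of 5 the operation is pure indexing.

Differential pathlength factors (4.0 muscle, 6.0 cerebral) are metadata:
inputs are already chromophore concentration changes.

## Performance metrics

Sprint means and total work use trapezoidal integration with linear
interpolation at interval boundaries, so partial samples count and the
noise-free generator shapes integrate exactly. "Lowest stable SpO₂" has no
universal definition; it is operationalized as the minimum mean over runs of
≥ 3 consecutive samples with range ≤ 2 %, falling back to the plain minimum
(with a warning) when no run qualifies. The 30-s V̇O₂ window treats the
irregular breath series as sample-and-hold and slides continuously; because
the windowed mean is piecewise linear in the window start, the maximum is
attained with a window edge on a breath time and only those candidates are
scanned — equivalent to brute force over all placements, which the tests
verify. Task failure requires cadence below threshold for a 1-s dwell so a
single dropped sample cannot end a test.

## Neuromuscular metrics

Baselines: rest = mean of the first 0.5 s; evoked responses use the mean of
the 100 ms before the stimulus; the superimposed doublet uses the voluntary
force over the 50 ms before the stimulus. Evoked peaks are searched in a
0.5-s post-stimulus window (twitch and doublet force peaks arrive well
within 200 ms, so ±50 ms of marker jitter is harmless — tested). The
activation formula applies the voluntary/MVC correction factor by default
(appropriate when the stimulation is not guaranteed to land on the force
peak); the uncorrected classical form is a flag away. The potentiated
resting doublet is the P100 response — the assessment order (MVC first,
rest stimulations after) makes it post-contraction. VAL estimates above
100 % (negative superimposed amplitude under noise, or a submaximal MVC) are
clamped to 100 with a warning and flagged in the output rather than
corrected, since no algorithmic fix is defensible. The single-twitch M-wave
normalizes the voluntary RMS by default (configurable).

## Mixed-model inference

Endpoint tables carry one row per participant × condition (× phase or ×
set-duration fraction). Models have the experimental fixed factors (with
interaction when two are present, set-duration treated as categorical) and a
participant random intercept, fitted with statsmodels MixedLM. ML fits feed
the likelihood-ratio tests; REML is used when variance components or
estimates are reported. Singular fits (zero between-participant variance)
are flagged, not fatal.

The LRT p-value defaults to an F-scaled reference: statistic/df against
F(df, ddf) with containment denominator degrees of freedom
(ddf = N − rank(X) − (g − 1)). The classical chi-square reference is
available (`reference="chisq"`) but is anticonservative at this design's
size: with 11 participants its null rejection rate at nominal 0.05 is
~0.07 (it ignores the ~20 denominator df entirely), while the F scaling is
calibrated (~0.05 in 1000-replicate null simulations) and converges to the
chi-square as ddf grows. Tukey contrasts use least-squares means built from
the fixed-effect design averaged over a balanced grid of the other factors,
with the studentized-range distribution at the same containment df — an
approximation (exact denominator df are not identified in mixed models)
that degenerates to the unadjusted t-test for two levels. Percent changes
are computed per subject and then averaged (mean ± SD), which is not the
ratio of group means; participants with a zero reference value are excluded
with a warning.

## Calibration and recovery checks — problem sizes

The statistical acceptance checks run at the study design point (11
participants, between-participant SD 12 and residual SD 3 on the
sprint-count scale): 1000 null replicates for the type-I rate, 200 for power
at the preset effect sizes, 4000 for fixed-effect recovery (checked against
the generator's exact sampling SE, √(2σ²/n) — the estimator is exactly
normal in this balanced design, keeping the oracle independent of the
model's own SE estimate), and the random-intercept SD check averages three
REML fits at 50 participants, where a variance component is estimable to
~10 %.

## Known limitations

The generator's kinetics are canonical shapes, not fitted responses: no
breath-to-breath coupling with work rate, no cuff-inflation transients, no
motion artifacts beyond the stationary pedal sinusoid, no myoglobin/
hemoglobin ambiguity in the NIRS channels, and EMG as enveloped Gaussian
noise rather than motor-unit superposition. Passing the recovery tests
therefore demonstrates correctness of the analysis chain under realistic
geometry and noise, not validity of any physiological claim. The
segmentation defaults assume the 30-s sprint cycle of this protocol; other
work:rest ratios should adjust `expected_period_s` and the prominence
floor. The Tukey and F-reference degrees of freedom are containment
approximations; with richer random-effects structures a Satterthwaite or
bootstrap approach would be preferable (a parametric bootstrap is the
natural extension but is not implemented in the test path for runtime
reasons).
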