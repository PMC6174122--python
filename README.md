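# sprintox

Analysis pipeline for repeated cycling sprint tests to exhaustion performed
under bilateral blood-flow restriction (BFR), exercised end-to-end on a
synthetic study generator with known ground truth.

Repeated sprint tests (RST: 10-s all-out sprints with 20-s active recovery,
ridden until cadence falls below 70 rpm) stress both the muscle and the
central nervous system, and partial vascular occlusion (cuff pressure at a
fraction of the resting pulse-elimination pressure) sharpens the peripheral
limitation. Quantifying that requires several signal-analysis chains at once:
near-infrared spectroscopy (NIRS) oxygenation dynamics, crank-power
performance metrics, evoked-force/EMG neuromuscular fatigue markers, and
repeated-measures group inference. This package implements all four as a
tested library with a thin CLI, plus a generator that emulates the full
multi-channel recording set so every stage can be validated by parameter
recovery instead of opaque fixtures.

## What it computes

**NIRS oxygenation** (`sprintox.nirs`) — [O₂Hb], [HHb] and TSI channels are
low-pass filtered with a 4th-order zero-phase Butterworth (0.2 Hz cutoff; the
two passes square the magnitude response), [tHb] = [O₂Hb] + [HHb]; sprint and
recovery phases are identified from the filtered [HHb] (each sprint drives a
deoxygenation peak); per sprint, Δ = max − min within the sprint phase and
the absolute TSI maximum; the per-sprint series is re-expressed at
20/40/60/80/100 % of sprints completed with linear interpolation at
fractional indices.

**Sprint performance** (`sprintox.performance`) — per-sprint mean/peak power,
total work (kJ), the percent-decrement fatigue index

    S_dec(%) = [1 − S̄ / S_best] × 100,

with S̄ the mean of all sprint mean powers and S_best the better of the first
two sprints; a 95 % anti-pacing check against the warm-up sprints; the
cadence task-failure rule; the highest 30-s average of breath-by-breath V̇O₂;
the lowest stable SpO₂ of the final minute.

**Neuromuscular fatigue** (`sprintox.neuromuscular`) — MVC peak force, evoked
amplitudes of the superimposed 100-Hz doublet and resting P100 / P10 / single
twitch, the interpolated-twitch voluntary activation level

    VAL(%) = (1 − superimposed × (voluntary_at_stim / MVC) / potentiated_doublet) × 100,

the low/high-frequency ratio P10/P100, EMG RMS over a 250-ms epoch at peak
force, and the M-wave-normalized RMS.

**Group inference** (`sprintox.inference`) — linear mixed models with a
participant random intercept (statsmodels), likelihood-ratio tests of each
fixed effect (F-scaled reference by default; see `docs/methods.md`),
Tukey-adjusted least-squares-mean contrasts, and per-subject percent-change
summaries versus the no-occlusion condition.

**Synthetic study** (`sprintox.synthetic`) — generates power, cadence, NIRS
(muscle + cerebral, with 1.4-Hz pedal-stroke artifact and noise), heart rate,
SpO₂, breath-by-breath V̇O₂ and pre/post force + EMG assessments for any
number of participants × occlusion conditions, with every true parameter
stored alongside.

## Worked example

```
python analysis/01_simulate_study.py
python analysis/02_nirs_oxygenation.py
python analysis/05_mixed_model_inference.py
```

The drivers regenerate the same seeded study (11 participants × 0/45/60 %
occlusion) and print, among other things:

```
sprint count recovered in 33/33 tests; worst |delta[HHb] error| = 0.478 uM

     endpoint  condition  mean_pct_decrease  sd_pct_decrease  n
    n_sprints         45               47.4              8.4 11
    n_sprints         60               67.0              4.2 11
total_work_kJ         45               54.9              5.8 11
total_work_kJ         60               69.6              3.5 11

     endpoint     effect  statistic  df   p
    n_sprints  condition    41.9944   2 0.0
```

Reading this: the signal-driven segmentation found every sprint in all 33
tests and recovered the generator's per-sprint deoxygenation deltas to better
than 0.5 μM despite the 3-μM pedal artifact; the injected occlusion effects
(−47 %/−66 % on sprint count at 45 %/60 %) come back at 47.4 % and 67.0 %
as per-subject means; and the mixed-model likelihood-ratio test on condition
is decisive for the capacity endpoints. Tables land in `results/`
(per-sprint NIRS deltas, performance and neuromuscular summaries, effects,
contrasts, percent changes).

The same pipeline is available as a CLI:

```
sprintox generate --seed 42 --participants 11 --out results
sprintox analyze --dataset results/dataset --out results
sprintox report --out results
sprintox selftest
```

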