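"""Synthetic repeated-sprint BFR study generator with known ground truth.

Emulates the recordings of a repeated cycling sprint test (RST: 10-s all-out
sprints, 20-s active recovery, to task failure) performed under three levels of
bilateral blood-flow restriction (0, 45 and 60 % of resting pulse-elimination
pressure): crank power and cadence, muscle and cerebral NIRS, heart rate,
pulse oximetry, breath-by-breath gas exchange, and the pre/post evoked-force +
EMG neuromuscular assessment.  Every generated record stores its noise-free
components and true parameters, so downstream processing can be tested by
parameter recovery rather than against opaque fixtures.

Signal-shape choices (rise/recovery time constants, trapezoidal sprint power,
band-limited EMG interference pattern) are documented in docs/methods.md; the
condition effect sizes in :data:`DEFAULT_STUDY_PRESET` are presets patterned
after the magnitudes reported for this protocol in the literature, not claims
about any particular dataset.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import ChannelTrace, SprintTimeline

__all__ = [
    "ProtocolConfig",
    "NirsTraces",
    "NeuromuscularRecording",
    "TestRecord",
    "GroundTruth",
    "StudyDataset",
    "DEFAULT_STUDY_PRESET",
    "generate_power_profile",
    "generate_cadence_trace",
    "generate_nirs_traces",
    "generate_neuromuscular_traces",
    "generate_breath_series",
    "simulate_endpoint_table",
    "generate_study",
    "write_study",
]

# NIRS sprint-response kinetics (seconds). Deoxygenation rises with a ~3-s time
# constant during the sprint, reoxygenation starts after a short (~2-s) delay
# and relaxes back to baseline with a ~8-s time constant.
TAU_RISE = 3.0
REOX_DELAY = 2.0
TAU_RECOVERY = 8.0

RECOVERY_POWER_W = 20.0  # ergometer resistance between sprints
SPRINT_RISE_S = 0.5      # trapezoidal power rise at sprint onset


@dataclass
class ProtocolConfig:
    """Temporal structure and channel sampling rates of the RST protocol."""

    sprint_duration_s: float = 10.0
    recovery_duration_s: float = 20.0
    warmup_sprints: int = 2
    cadence_failure_rpm: float = 70.0
    conditions: tuple[int, ...] = (0, 45, 60)
    lead_in_s: float = 60.0
    fs_power: float = 4.0
    fs_nirs: float = 10.0
    fs_force: float = 1000.0
    fs_emg: float = 2000.0
    fs_hr: float = 1.0
    fs_spo2: float = 0.2

    def __post_init__(self) -> None:
        if self.sprint_duration_s <= 0 or self.recovery_duration_s <= 0:
            raise ValueError("sprint and recovery durations must be positive")
        if len(set(self.conditions)) != len(self.conditions):
            raise ValueError("conditions must be distinct")
        for name in ("fs_power", "fs_nirs", "fs_force", "fs_emg", "fs_hr", "fs_spo2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def cycle_s(self) -> float:
        return self.sprint_duration_s + self.recovery_duration_s


# ---------------------------------------------------------------------------
# power / cadence
# ---------------------------------------------------------------------------

def generate_power_profile(n_sprints: int, peak_power: float,
                           decrement_rate: float = 0.0, noise_sd: float = 0.0,
                           seed: int = 0, protocol: ProtocolConfig | None = None,
                           ) -> tuple[ChannelTrace, SprintTimeline]:
    """Crank-power trace of an RST with geometrically decaying sprint means.

    Sprint ``k`` (0-based) has time-average power ``peak_power * (1 -
    decrement_rate) ** k`` by construction: each sprint is a trapezoid rising
    linearly from the 20-W recovery resistance over 0.5 s to a plateau solved
    so the sprint mean hits its target.  Gaussian noise is added sample-wise.
    """
    protocol = protocol or ProtocolConfig()
    if n_sprints < 1:
        raise ValueError("n_sprints must be >= 1")
    if peak_power <= 0:
        raise ValueError("peak_power must be positive")
    if not 0 <= decrement_rate < 1:
        raise ValueError("decrement_rate must be in [0, 1)")

    fs = protocol.fs_power
    T = protocol.sprint_duration_s
    rise = min(SPRINT_RISE_S, T / 2)
    timeline = SprintTimeline.regular(n_sprints, T, protocol.recovery_duration_s,
                                      first_start_s=protocol.lead_in_s)
    total = protocol.lead_in_s + n_sprints * protocol.cycle_s + 10.0
    t = np.arange(0.0, total, 1.0 / fs)
    x = np.full(t.size, RECOVERY_POWER_W)

    means = peak_power * (1.0 - decrement_rate) ** np.arange(n_sprints)
    for k, (t0, t1) in enumerate(timeline.intervals()):
        # plateau level such that the trapezoid's time average equals means[k]
        plateau = (means[k] * T - rise * RECOVERY_POWER_W / 2) / (T - rise / 2)
        m_rise = (t >= t0) & (t < t0 + rise)
        x[m_rise] = RECOVERY_POWER_W + (plateau - RECOVERY_POWER_W) * (t[m_rise] - t0) / rise
        m_flat = (t >= t0 + rise) & (t <= t1 + 1e-9)  # plateau holds through the end sample
        x[m_flat] = plateau

    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        x = x + rng.normal(0.0, noise_sd, x.size)
    trace = ChannelTrace(x, fs=fs, channel="power", units="W")
    return trace, timeline


def generate_cadence_trace(timeline: SprintTimeline, protocol: ProtocolConfig | None = None,
                           sprint_cadence_rpm: float = 115.0,
                           recovery_cadence_rpm: float = 85.0,
                           fail_final_sprint: bool = True,
                           failure_cadence_rpm: float = 60.0,
                           failure_dwell_s: float = 2.0,
                           noise_sd: float = 1.0, seed: int = 0) -> ChannelTrace:
    """Cadence trace consistent with the timeline.

    When ``fail_final_sprint`` is set, cadence in the last sprint decays below
    the task-failure threshold for its final ``failure_dwell_s`` seconds,
    emulating volitional exhaustion ending the test.
    """
    protocol = protocol or ProtocolConfig()
    fs = protocol.fs_power
    total = timeline.ends[-1] + protocol.recovery_duration_s + 10.0
    t = np.arange(0.0, total, 1.0 / fs)
    x = np.full(t.size, recovery_cadence_rpm)
    n = timeline.n_sprints
    for k, (t0, t1) in enumerate(timeline.intervals()):
        m = (t >= t0) & (t <= t1 + 1e-9)
        c = sprint_cadence_rpm - 10.0 * k / max(n - 1, 1)  # mild drift across the set
        x[m] = c
        if fail_final_sprint and k == n - 1:
            m_fail = (t >= t1 - failure_dwell_s) & (t <= t1 + 1e-9)
            x[m_fail] = failure_cadence_rpm
    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        x = x + rng.normal(0.0, noise_sd, x.size)
    return ChannelTrace(x, fs=fs, channel="cadence", units="rpm")


# ---------------------------------------------------------------------------
# NIRS
# ---------------------------------------------------------------------------

@dataclass
class NirsTraces:
    """Noisy NIRS channels plus the stored noise-free components and truths."""

    o2hb: ChannelTrace
    hhb: ChannelTrace
    tsi: ChannelTrace
    clean: dict[str, np.ndarray]
    true_deltas: dict[str, np.ndarray]   # per-sprint max-min of noise-free component
    true_tsi_max: np.ndarray             # per-sprint max of noise-free TSI
    timeline: SprintTimeline


def _sprint_cycle_response(t: np.ndarray, timeline: SprintTimeline,
                           amplitudes: np.ndarray, baseline: float, sign: float,
                           tau_rise: float, reox_delay: float, tau_rec: float,
                           ) -> np.ndarray:
    """Deterministic chromophore response: mono-exponential excursion during
    each sprint (amplitude such that the within-sprint max-min equals the
    schedule entry), a short plateau after sprint end (reoxygenation delay),
    then mono-exponential relaxation to baseline."""
    x = np.full(t.size, baseline)
    cur = baseline
    n = timeline.n_sprints
    for k, (t0, t1) in enumerate(timeline.intervals()):
        T = t1 - t0
        sat = 1.0 - np.exp(-T / tau_rise)
        amp = sign * amplitudes[k] / sat
        m_s = (t >= t0) & (t < t1)
        x[m_s] = cur + amp * (1.0 - np.exp(-(t[m_s] - t0) / tau_rise))
        peak = cur + amp * sat
        next_start = timeline.starts[k + 1] if k + 1 < n else t[-1] + 1.0
        m_h = (t >= t1) & (t < min(t1 + reox_delay, next_start))
        x[m_h] = peak
        m_r = (t >= t1 + reox_delay) & (t < next_start)
        x[m_r] = baseline + (peak - baseline) * np.exp(-(t[m_r] - t1 - reox_delay) / tau_rec)
        rec_dur = next_start - t1 - reox_delay
        cur = (peak if rec_dur <= 0
               else baseline + (peak - baseline) * np.exp(-rec_dur / tau_rec))
    return x


def generate_nirs_traces(timeline: SprintTimeline, site: str = "vastus_lateralis",
                         delta_schedule: np.ndarray | list | None = None,
                         o2hb_schedule: np.ndarray | list | None = None,
                         tsi_drop_schedule: np.ndarray | list | None = None,
                         baseline_hhb: float = 5.0, baseline_o2hb: float = 15.0,
                         baseline_tsi: float = 70.0,
                         artifact_freq: float = 1.4, artifact_amp: float = 0.0,
                         drift: float = 0.0, noise_sd: float = 0.0, seed: int = 0,
                         fs: float = 10.0,
                         tau_rise: float = TAU_RISE, reox_delay: float = REOX_DELAY,
                         tau_rec: float = TAU_RECOVERY) -> NirsTraces:
    """NIRS chromophore traces for one site over one RST.

    ``delta_schedule`` fixes, per sprint, the max-min excursion of the
    noise-free [HHb] component within that sprint's interval (uM); [O2Hb]
    falls with a mirrored shape (``o2hb_schedule``, default 0.8x) and TSI
    falls in % (``tsi_drop_schedule``, default 0.5 %/uM of the HHb schedule).
    A pedal-stroke artifact (sinusoid at ``artifact_freq``), a linear drift
    (uM/min) and white noise are superimposed on the noisy outputs only; the
    noise-free components are stored.  [tHb] is not generated: it is derived
    downstream as the sum of the two chromophores.
    """
    if timeline.n_sprints < 1:
        raise ValueError("timeline must contain at least one sprint")
    n = timeline.n_sprints
    if delta_schedule is None:
        delta_schedule = np.full(n, 10.0)
    delta_schedule = np.asarray(delta_schedule, dtype=float)
    if delta_schedule.size != n:
        raise ValueError(f"delta_schedule has {delta_schedule.size} entries "
                         f"for {n} sprints")
    o2hb_schedule = (0.8 * delta_schedule if o2hb_schedule is None
                     else np.asarray(o2hb_schedule, dtype=float))
    tsi_drop_schedule = (0.5 * delta_schedule if tsi_drop_schedule is None
                         else np.asarray(tsi_drop_schedule, dtype=float))
    if o2hb_schedule.size != n or tsi_drop_schedule.size != n:
        raise ValueError("all schedules must have one entry per sprint")
    if artifact_amp > 0 and artifact_freq <= 0.2:
        raise ValueError("pedal artifact frequency must lie above the 0.2 Hz "
                         "analysis cutoff")

    total = timeline.ends[-1] + timeline.recovery_duration_s + 10.0
    t = np.arange(0.0, total, 1.0 / fs)
    kin = dict(tau_rise=tau_rise, reox_delay=reox_delay, tau_rec=tau_rec)
    clean = {
        "HHb": _sprint_cycle_response(t, timeline, delta_schedule, baseline_hhb, +1.0, **kin),
        "O2Hb": _sprint_cycle_response(t, timeline, o2hb_schedule, baseline_o2hb, -1.0, **kin),
        "TSI": _sprint_cycle_response(t, timeline, tsi_drop_schedule, baseline_tsi, -1.0, **kin),
    }
    clean["tHb"] = clean["O2Hb"] + clean["HHb"]

    rng = np.random.default_rng(seed)
    artifact = artifact_amp * np.sin(2 * np.pi * artifact_freq * t)
    drift_term = drift * t / 60.0
    noisy = {}
    for name in ("HHb", "O2Hb", "TSI"):
        scale = 0.1 if name == "TSI" else 1.0  # artifact couples weakly into TSI
        noisy[name] = (clean[name] + scale * artifact + scale * drift_term
                       + rng.normal(0.0, noise_sd * (0.5 if name == "TSI" else 1.0), t.size))

    # end-inclusive windows: the deoxygenation peak sits on the sprint-end sample
    true_deltas = {}
    for name in ("HHb", "O2Hb", "tHb"):
        true_deltas[name] = np.array([
            clean[name][(t >= a) & (t <= b)].max() - clean[name][(t >= a) & (t <= b)].min()
            for a, b in timeline.intervals()])
    true_tsi_max = np.array([clean["TSI"][(t >= a) & (t <= b)].max()
                             for a, b in timeline.intervals()])

    units = "uM"
    mk = lambda name, unit: ChannelTrace(noisy[name], fs=fs, site=site,
                                         channel=name, units=unit)
    return NirsTraces(o2hb=mk("O2Hb", units), hhb=mk("HHb", units),
                      tsi=mk("TSI", "%"), clean=clean, true_deltas=true_deltas,
                      true_tsi_max=true_tsi_max, timeline=timeline)


# ---------------------------------------------------------------------------
# neuromuscular assessment
# ---------------------------------------------------------------------------

# assessment schedule (seconds): MVC ramp/plateau, superimposed doublet at the
# force plateau, then resting stimulations at exactly 2-s spacing
_NM_RAMP_START, _NM_PLATEAU_START, _NM_PLATEAU_END = 1.0, 2.5, 5.5
_NM_RELEASE_END = 5.8
_NM_MARKERS = {"superimposed": 4.0, "p100": 6.0, "p10": 8.0, "twitch": 10.0}
_NM_DURATION = 11.5


@dataclass
class NeuromuscularRecording:
    """Force + EMG traces of one pre- or post-RST assessment."""

    force: ChannelTrace
    emg: ChannelTrace
    markers: dict[str, float]
    truth: dict[str, float]


def _alpha_twitch(t_rel: np.ndarray, amplitude: float, tc: float) -> np.ndarray:
    """Evoked-force transient peaking at exactly ``amplitude`` at t = tc."""
    out = np.zeros_like(t_rel)
    m = t_rel >= 0
    out[m] = amplitude * (t_rel[m] / tc) * np.exp(1.0 - t_rel[m] / tc)
    return out


def generate_neuromuscular_traces(mvc_true: float, val_true: float,
                                  p100: float, p10: float, twitch: float,
                                  noise_sd: float = 0.0, seed: int = 0,
                                  emg_rms: float = 0.6, m_wave_pp: float = 10.0,
                                  fs_force: float = 1000.0, fs_emg: float = 2000.0,
                                  ) -> NeuromuscularRecording:
    """One neuromuscular assessment with exactly controllable metrics.

    The force trace contains an MVC ramp-plateau at ``mvc_true`` with a
    superimposed doublet delivered on the plateau whose amplitude inverts the
    voluntary-activation formula (potentiated resting doublet = the P100
    response), followed by resting P100, P10 and single-twitch responses at
    2-s spacing.  The EMG trace carries a band-limited interference pattern
    whose RMS over the 250-ms peak-force epoch equals ``emg_rms`` and a
    biphasic M-wave of peak-to-peak amplitude ``m_wave_pp`` after the twitch.
    """
    if not 0.0 <= val_true <= 100.0:
        raise ValueError("val_true must lie in [0, 100]")
    if mvc_true <= 0:
        raise ValueError("mvc_true must be positive")
    for name, v in (("p100", p100), ("p10", p10), ("twitch", twitch)):
        if v < 0:
            raise ValueError(f"{name} must be non-negative")
    if p100 <= 0:
        raise ValueError("p100 (the potentiated resting doublet) must be positive")

    rng = np.random.default_rng(seed)
    t = np.arange(0.0, _NM_DURATION, 1.0 / fs_force)
    volf = np.zeros_like(t)
    m = (t >= _NM_RAMP_START) & (t < _NM_PLATEAU_START)
    volf[m] = mvc_true * 0.5 * (1 - np.cos(np.pi * (t[m] - _NM_RAMP_START)
                                           / (_NM_PLATEAU_START - _NM_RAMP_START)))
    volf[(t >= _NM_PLATEAU_START) & (t <= _NM_PLATEAU_END)] = mvc_true
    m = (t > _NM_PLATEAU_END) & (t < _NM_RELEASE_END)
    volf[m] = mvc_true * 0.5 * (1 + np.cos(np.pi * (t[m] - _NM_PLATEAU_END)
                                           / (_NM_RELEASE_END - _NM_PLATEAU_END)))

    # stimulation is delivered on the flat plateau, so voluntary force at the
    # stimulus equals MVC and the activation formula inverts exactly
    superimposed_amp = (1.0 - val_true / 100.0) * p100
    force = volf.copy()
    for label, amp, tc in (("superimposed", superimposed_amp, 0.05),
                           ("p100", p100, 0.06), ("p10", p10, 0.07),
                           ("twitch", twitch, 0.04)):
        force += _alpha_twitch(t - _NM_MARKERS[label], amp, tc)
    if noise_sd > 0:
        force = force + rng.normal(0.0, noise_sd, force.size)

    # EMG: 20-450 Hz Gaussian interference pattern, enveloped by the voluntary
    # force shape, scaled so the RMS over the 250-ms epoch centred on the
    # (first) peak-force sample equals emg_rms exactly
    from scipy.signal import butter, sosfiltfilt
    te = np.arange(0.0, _NM_DURATION, 1.0 / fs_emg)
    sos = butter(4, [20.0, 450.0], btype="bandpass", fs=fs_emg, output="sos")
    raw = sosfiltfilt(sos, rng.normal(0.0, 1.0, te.size))
    envelope = np.interp(te, t, volf / mvc_true)
    emg = raw * envelope
    t_peak = _NM_PLATEAU_START  # first sample at which voluntary force is maximal
    w = (te >= t_peak - 0.125) & (te < t_peak + 0.125)
    # same definition the analysis uses: RMS of the mean-subtracted epoch
    current_rms = float(np.sqrt(np.mean((emg[w] - emg[w].mean()) ** 2)))
    if current_rms > 0 and emg_rms > 0:
        emg *= emg_rms / current_rms
    # biphasic M-wave 5 ms after the twitch stimulus, exact peak-to-peak
    mw_start = _NM_MARKERS["twitch"] + 0.005
    mwin = (te >= mw_start) & (te < mw_start + 0.02)
    tm = te[mwin] - mw_start
    template = np.sin(2 * np.pi * tm / 0.02) * np.hanning(tm.size)
    pp = template.max() - template.min()
    if pp > 0:
        emg[mwin] += template * (m_wave_pp / pp)
    if noise_sd > 0:
        emg = emg + rng.normal(0.0, 0.01 * noise_sd, emg.size)

    truth = {
        "mvc": mvc_true, "val": val_true, "superimposed": superimposed_amp,
        "p100": p100, "p10": p10, "twitch": twitch,
        "p10_over_p100": p10 / p100, "emg_rms": emg_rms,
        "m_wave_pp": m_wave_pp,
        "rms_over_mwave": emg_rms / m_wave_pp if m_wave_pp > 0 else np.nan,
    }
    return NeuromuscularRecording(
        force=ChannelTrace(force, fs=fs_force, site="vastus_lateralis",
                           channel="force", units="N"),
        emg=ChannelTrace(emg, fs=fs_emg, site="vastus_lateralis",
                         channel="emg", units="mV"),
        markers=dict(_NM_MARKERS), truth=truth)


# ---------------------------------------------------------------------------
# cardiorespiratory channels
# ---------------------------------------------------------------------------

def generate_breath_series(duration_s: float, vo2_rest: float = 0.6,
                           vo2_peak_target: float = 2.7, tau_s: float = 30.0,
                           noise_sd: float = 0.05, seed: int = 0,
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Irregular breath-by-breath oxygen-uptake series (times s, values L/min)."""
    rng = np.random.default_rng(seed)
    times = np.cumsum(rng.uniform(0.7, 1.5, int(duration_s / 0.7) + 4))
    times = times[times < duration_s]
    values = vo2_rest + (vo2_peak_target - vo2_rest) * (1 - np.exp(-times / tau_s))
    if noise_sd > 0:
        values = values + rng.normal(0.0, noise_sd, values.size)
    return times, np.clip(values, 0.0, None)


def _saturating_trace(duration_s: float, fs: float, start: float, target: float,
                      tau_s: float, noise_sd: float, rng: np.random.Generator,
                      channel: str, units: str) -> ChannelTrace:
    t = np.arange(0.0, duration_s, 1.0 / fs)
    x = start + (target - start) * (1 - np.exp(-t / tau_s))
    if noise_sd > 0:
        x = x + rng.normal(0.0, noise_sd, x.size)
    return ChannelTrace(x, fs=fs, channel=channel, units=units)


# ---------------------------------------------------------------------------
# full study
# ---------------------------------------------------------------------------

# Condition-effect presets patterned after the magnitudes reported for this
# protocol (group means/SDs of the published tables); factors multiply the 0 %
# (no-occlusion) baseline. They are presets with ground truth attached, not
# reproductions of any measured dataset.
DEFAULT_STUDY_PRESET: dict = {
    "n_sprints": {"baseline": 30.0, "between_sd": 12.0, "resid_cv": 0.10,
                  "factors": {0: 1.0, 45: 0.526, 60: 0.342}, "min": 3},
    "peak_power": {"baseline": 600.0, "between_sd": 130.0, "resid_sd": 15.0,
                   "factors": {0: 1.0, 45: 0.91, 60: 0.98}},
    "decrement_rate": {0: 0.019, 45: 0.045, 60: 0.070},
    "power_noise_sd": 20.0,
    "muscle_hhb_delta": {"baseline": 10.0, "between_sd": 1.5,
                         "factors": {0: 1.0, 45: 0.95, 60: 0.70},
                         "set_decline": 0.3},
    "muscle_o2hb_scale": {0: 0.85, 45: 0.65, 60: 0.55},
    "cerebral_hhb_delta": {"baseline": 2.0, "between_sd": 0.4,
                           "factors": {0: 1.0, 45: 1.0, 60: 1.0},
                           "set_decline": -0.3},  # cerebral excursions grow near exhaustion
    "cerebral_o2hb_scale": {0: 0.7, 45: 0.7, 60: 0.7},
    "tsi_baseline": {"baseline": 70.0, "between_sd": 3.0,
                     "factors": {0: 1.0, 45: 0.99, 60: 0.93}},
    "nirs_artifact_amp": 3.0, "nirs_artifact_freq": 1.4, "nirs_noise_sd": 0.2,
    "mvc": {"baseline": 275.0, "between_sd": 60.0, "resid_sd": 8.0,
            "pre_factors": {0: 1.0, 45: 0.97, 60: 0.95},
            "post_factors": {0: 0.92, 45: 0.73, 60: 0.50}},
    "val": {"between_sd": 8.0, "resid_sd": 2.0,
            "pre": {0: 86.0, 45: 86.0, 60: 86.0},
            "post": {0: 88.0, 45: 81.0, 60: 72.0}},
    "p100": {"baseline": 60.0, "between_sd": 12.0, "resid_sd": 2.0},
    "twitch_over_p100": 0.5,
    "p10_ratio": {"pre": {0: 0.91, 45: 0.92, 60: 0.90},
                  "post": {0: 0.63, 45: 0.68, 60: 0.63}, "resid_sd": 0.04},
    "m_wave_pp": {"baseline": 10.0, "between_sd": 2.0, "resid_sd": 0.3},
    "rms_ratio": {"pre": {0: 0.059, 45: 0.059, 60: 0.058},
                  "post": {0: 0.064, 45: 0.054, 60: 0.037}, "resid_sd": 0.004},
    "nm_noise_sd": 0.0,
    "vo2_peak": {"baseline": 2.72, "between_sd": 0.55, "resid_sd": 0.08,
                 "factors": {0: 1.0, 45: 0.874, 60: 0.818}},
    "hr_max": {"baseline": 185.0, "between_sd": 9.0, "resid_sd": 2.0,
               "factors": {0: 1.0, 45: 0.957, 60: 0.924}},
    "spo2": {"baseline": 93.8, "between_sd": 3.0, "resid_sd": 0.8,
             "factors": {0: 1.0, 45: 0.966, 60: 0.980}},
    "scalars": {
        "lactate": {"means": {0: 9.5, 45: 7.2, 60: 8.6}, "between_sd": 3.0, "resid_sd": 1.0},
        "rpe_legs": {"means": {0: 17.7, 45: 19.5, 60: 19.5}, "between_sd": 1.0, "resid_sd": 0.5},
        "rpe_breathing": {"means": {0: 18.3, 45: 17.7, 60: 15.5}, "between_sd": 1.0, "resid_sd": 0.5},
        "ve": {"means": {0: 137.0, 45: 133.0, 60: 121.0}, "between_sd": 25.0, "resid_sd": 5.0},
        "rr": {"means": {0: 66.9, 45: 69.0, 60: 64.8}, "between_sd": 6.0, "resid_sd": 2.0},
        "rer": {"means": {0: 1.11, 45: 1.15, 60: 1.13}, "between_sd": 0.05, "resid_sd": 0.02},
    },
}


@dataclass
class TestRecord:
    """All channels of one participant x condition RST plus its assessments."""

    participant: str
    condition: int
    timeline: SprintTimeline
    power: ChannelTrace
    cadence: ChannelTrace
    nirs_muscle: NirsTraces
    nirs_cerebral: NirsTraces
    hr: ChannelTrace
    spo2: ChannelTrace
    breath_times: np.ndarray
    breath_vo2: np.ndarray
    scalars: dict[str, float]
    nm_pre: NeuromuscularRecording
    nm_post: NeuromuscularRecording


@dataclass
class GroundTruth:
    """True generating parameters per participant x condition."""

    entries: dict[tuple[str, int], dict] = field(default_factory=dict)

    def get(self, participant: str, condition: int) -> dict:
        return self.entries[(participant, condition)]

    def endpoint_frame(self) -> pd.DataFrame:
        """Long table of the scalar true endpoints (one row per cell)."""
        rows = []
        for (pid, cond), tr in self.entries.items():
            for key, val in tr.items():
                if np.isscalar(val):
                    rows.append({"participant": pid, "condition": cond,
                                 "endpoint": key, "value": float(val)})
        return pd.DataFrame(rows)


@dataclass
class StudyDataset:
    protocol: ProtocolConfig
    records: list[TestRecord]
    ground_truth: GroundTruth
    seed: int

    def get(self, participant: str, condition: int) -> TestRecord:
        for r in self.records:
            if r.participant == participant and r.condition == condition:
                return r
        raise KeyError((participant, condition))

    @property
    def participants(self) -> list[str]:
        return sorted({r.participant for r in self.records})


def _draw_positive(rng, mean, sd, minimum):
    v = rng.normal(mean, sd)
    return max(v, minimum)


def generate_study(protocol: ProtocolConfig | None = None, n_participants: int = 11,
                   effects: dict | None = None, seed: int = 0) -> StudyDataset:
    """Generate a full synthetic study: every participant rides one RST per
    occlusion condition and performs pre/post neuromuscular assessments.

    ``effects`` entries override :data:`DEFAULT_STUDY_PRESET`.  Participant
    heterogeneity enters as a per-endpoint random intercept (normal, SD from
    the preset) shared across conditions; condition effects multiply (or, for
    the activation/ratio endpoints, set the level of) the participant's
    baseline.  Identical seeds yield bit-identical datasets.
    """
    protocol = protocol or ProtocolConfig()
    if n_participants < 2:
        raise ValueError("need at least 2 participants")
    preset = {**DEFAULT_STUDY_PRESET, **(effects or {})}
    root = np.random.SeedSequence(seed)
    part_seeds = root.spawn(n_participants)

    records: list[TestRecord] = []
    truth = GroundTruth()
    for i in range(n_participants):
        pid = f"P{i + 1:02d}"
        prng = np.random.default_rng(part_seeds[i])
        # participant-level baselines (random intercepts)
        base = {
            "n_sprints": _draw_positive(prng, preset["n_sprints"]["baseline"],
                                        preset["n_sprints"]["between_sd"], 8.0),
            "peak_power": _draw_positive(prng, preset["peak_power"]["baseline"],
                                         preset["peak_power"]["between_sd"], 200.0),
            "hhb_m": _draw_positive(prng, preset["muscle_hhb_delta"]["baseline"],
                                    preset["muscle_hhb_delta"]["between_sd"], 3.0),
            "hhb_c": _draw_positive(prng, preset["cerebral_hhb_delta"]["baseline"],
                                    preset["cerebral_hhb_delta"]["between_sd"], 0.5),
            "tsi": _draw_positive(prng, preset["tsi_baseline"]["baseline"],
                                  preset["tsi_baseline"]["between_sd"], 50.0),
            "mvc": _draw_positive(prng, preset["mvc"]["baseline"],
                                  preset["mvc"]["between_sd"], 100.0),
            "val_shift": prng.normal(0.0, preset["val"]["between_sd"]),
            "p100": _draw_positive(prng, preset["p100"]["baseline"],
                                   preset["p100"]["between_sd"], 20.0),
            "m_wave": _draw_positive(prng, preset["m_wave_pp"]["baseline"],
                                     preset["m_wave_pp"]["between_sd"], 3.0),
            "vo2": _draw_positive(prng, preset["vo2_peak"]["baseline"],
                                  preset["vo2_peak"]["between_sd"], 1.2),
            "hr": _draw_positive(prng, preset["hr_max"]["baseline"],
                                 preset["hr_max"]["between_sd"], 150.0),
            "spo2": min(_draw_positive(prng, preset["spo2"]["baseline"],
                                       preset["spo2"]["between_sd"], 80.0), 100.0),
        }
        scalar_base = {k: prng.normal(0.0, cfg["between_sd"])
                       for k, cfg in preset["scalars"].items()}

        for cond in protocol.conditions:
            crng = prng  # condition draws continue the participant stream
            # number of sprints: multiplicative condition effect, rounded
            f = preset["n_sprints"]["factors"][cond]
            mult = np.exp(crng.normal(0.0, preset["n_sprints"]["resid_cv"]))
            n_spr = int(max(preset["n_sprints"]["min"],
                            round(base["n_sprints"] * f * mult)))
            peak = (base["peak_power"] * preset["peak_power"]["factors"][cond]
                    + crng.normal(0.0, preset["peak_power"]["resid_sd"]))
            dec = preset["decrement_rate"][cond]
            sub = np.random.SeedSequence([seed, i, cond]).generate_state(8)
            power, timeline = generate_power_profile(
                n_spr, peak, dec, preset["power_noise_sd"], int(sub[0]), protocol)
            cadence = generate_cadence_trace(timeline, protocol, seed=int(sub[1]))

            # NIRS schedules: linear decline (or growth) across the set
            def schedule(first, decline, n):
                return first * np.linspace(1.0, 1.0 - decline, n)

            d1_m = base["hhb_m"] * preset["muscle_hhb_delta"]["factors"][cond]
            sched_m = schedule(d1_m, preset["muscle_hhb_delta"]["set_decline"], n_spr)
            nirs_m = generate_nirs_traces(
                timeline, "vastus_lateralis", sched_m,
                o2hb_schedule=preset["muscle_o2hb_scale"][cond] * sched_m,
                tsi_drop_schedule=0.5 * sched_m,
                baseline_tsi=base["tsi"] * preset["tsi_baseline"]["factors"][cond],
                artifact_amp=preset["nirs_artifact_amp"],
                artifact_freq=preset["nirs_artifact_freq"],
                noise_sd=preset["nirs_noise_sd"], seed=int(sub[2]),
                fs=protocol.fs_nirs)
            d1_c = base["hhb_c"] * preset["cerebral_hhb_delta"]["factors"][cond]
            sched_c = schedule(d1_c, preset["cerebral_hhb_delta"]["set_decline"], n_spr)
            nirs_c = generate_nirs_traces(
                timeline, "prefrontal_cortex", sched_c,
                o2hb_schedule=preset["cerebral_o2hb_scale"][cond] * sched_c,
                tsi_drop_schedule=0.25 * sched_c,
                baseline_tsi=72.0,
                artifact_amp=0.3 * preset["nirs_artifact_amp"],
                artifact_freq=preset["nirs_artifact_freq"],
                noise_sd=preset["nirs_noise_sd"], seed=int(sub[3]),
                fs=protocol.fs_nirs)

            rst_dur = float(timeline.ends[-1] + protocol.recovery_duration_s + 10.0)
            vo2_target = base["vo2"] * preset["vo2_peak"]["factors"][cond] \
                + crng.normal(0.0, preset["vo2_peak"]["resid_sd"])
            bt, bv = generate_breath_series(rst_dur, vo2_peak_target=vo2_target,
                                            seed=int(sub[4]))
            hr_target = base["hr"] * preset["hr_max"]["factors"][cond] \
                + crng.normal(0.0, preset["hr_max"]["resid_sd"])
            rng_cardio = np.random.default_rng(int(sub[5]))
            hr = _saturating_trace(rst_dur, protocol.fs_hr, 70.0, hr_target,
                                   60.0, 1.0, rng_cardio, "hr", "bpm")
            spo2_target = min(base["spo2"] * preset["spo2"]["factors"][cond]
                              + crng.normal(0.0, preset["spo2"]["resid_sd"]), 100.0)
            spo2 = _saturating_trace(rst_dur, protocol.fs_spo2, 98.0, spo2_target,
                                     90.0, 0.3, rng_cardio, "spo2", "%")

            scalars = {k: cfg["means"][cond] + scalar_base[k]
                       + crng.normal(0.0, cfg["resid_sd"])
                       for k, cfg in preset["scalars"].items()}

            # neuromuscular pre/post
            nm = {}
            nm_truth = {}
            for j, phase in enumerate(("pre", "post")):
                fkey = f"{phase}_factors"
                mvc_t = base["mvc"] * preset["mvc"][fkey][cond] \
                    + crng.normal(0.0, preset["mvc"]["resid_sd"])
                val_t = float(np.clip(preset["val"][phase][cond] + base["val_shift"]
                                      + crng.normal(0.0, preset["val"]["resid_sd"]),
                                      5.0, 100.0))
                p100_t = base["p100"] + crng.normal(0.0, preset["p100"]["resid_sd"])
                ratio_t = float(np.clip(preset["p10_ratio"][phase][cond]
                                        + crng.normal(0.0, preset["p10_ratio"]["resid_sd"]),
                                        0.05, 1.5))
                p10_t = ratio_t * p100_t
                twitch_t = preset["twitch_over_p100"] * p100_t
                mw_t = base["m_wave"] + crng.normal(0.0, preset["m_wave_pp"]["resid_sd"])
                rmsr_t = float(np.clip(preset["rms_ratio"][phase][cond]
                                       + crng.normal(0.0, preset["rms_ratio"]["resid_sd"]),
                                       0.005, 0.5))
                nm[phase] = generate_neuromuscular_traces(
                    mvc_t, val_t, p100_t, p10_t, twitch_t,
                    noise_sd=preset["nm_noise_sd"], seed=int(sub[6 if j == 0 else 7]),
                    emg_rms=rmsr_t * mw_t, m_wave_pp=mw_t,
                    fs_force=protocol.fs_force, fs_emg=protocol.fs_emg)
                nm_truth.update({f"mvc_{phase}": mvc_t, f"val_{phase}": val_t,
                                 f"p100_{phase}": p100_t, f"p10_{phase}": p10_t,
                                 f"twitch_{phase}": twitch_t,
                                 f"p10_over_p100_{phase}": ratio_t,
                                 f"rms_over_mwave_{phase}": rmsr_t,
                                 f"m_wave_pp_{phase}": mw_t})

            records.append(TestRecord(
                participant=pid, condition=cond, timeline=timeline,
                power=power, cadence=cadence, nirs_muscle=nirs_m,
                nirs_cerebral=nirs_c, hr=hr, spo2=spo2,
                breath_times=bt, breath_vo2=bv, scalars=scalars,
                nm_pre=nm["pre"], nm_post=nm["post"]))
            truth.entries[(pid, cond)] = {
                "n_sprints": float(n_spr),
                "sprint_mean_powers": peak * (1 - dec) ** np.arange(n_spr),
                "decrement_rate": dec,
                "hhb_deltas_muscle": nirs_m.true_deltas["HHb"],
                "o2hb_deltas_muscle": nirs_m.true_deltas["O2Hb"],
                "thb_deltas_muscle": nirs_m.true_deltas["tHb"],
                "tsi_max_muscle": nirs_m.true_tsi_max,
                "hhb_deltas_cerebral": nirs_c.true_deltas["HHb"],
                "thb_deltas_cerebral": nirs_c.true_deltas["tHb"],
                "vo2_peak": vo2_target, "hr_max": hr_target,
                "spo2": spo2_target, **scalars, **nm_truth,
            }
    return StudyDataset(protocol=protocol, records=records,
                        ground_truth=truth, seed=seed)


def simulate_endpoint_table(n_participants: int, baseline: float,
                            between_sd: float, resid_sd: float,
                            factors: dict[int, float] | None = None,
                            conditions: tuple[int, ...] = (0, 45, 60),
                            seed: int = 0) -> pd.DataFrame:
    """Lightweight per-endpoint simulator for statistical calibration.

    Draws one value per participant x condition from the additive
    random-intercept model ``y = baseline * factor_c + b_i + e`` with
    ``b_i ~ N(0, between_sd)`` and ``e ~ N(0, resid_sd)`` — the data-generating
    process that the mixed-model inference assumes.  Used for type-I-error and
    power simulations where generating full signal-level studies would add
    nothing but runtime.
    """
    factors = factors or {c: 1.0 for c in conditions}
    rng = np.random.default_rng(seed)
    b = rng.normal(0.0, between_sd, n_participants)
    rows = []
    for i in range(n_participants):
        for c in conditions:
            rows.append({"participant": f"P{i + 1:02d}", "condition": c,
                         "value": baseline * factors[c] + b[i]
                         + rng.normal(0.0, resid_sd)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# disk layout
# ---------------------------------------------------------------------------

def _write_channel(path: Path, trace: ChannelTrace) -> None:
    pd.DataFrame({"time_s": trace.times(), "value": trace.values}
                 ).to_csv(path, index=False, float_format="%.6f")


def write_study(dataset: StudyDataset, out_dir: str | Path) -> Path:
    """Write one directory per participant x condition with tidy channel CSVs,
    a ground-truth JSON sidecar and a study-level manifest CSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = []
    for rec in dataset.records:
        d = out / f"{rec.participant}_c{rec.condition}"
        d.mkdir(exist_ok=True)
        channels = {
            "power": rec.power, "cadence": rec.cadence,
            "muscle_o2hb": rec.nirs_muscle.o2hb, "muscle_hhb": rec.nirs_muscle.hhb,
            "muscle_tsi": rec.nirs_muscle.tsi,
            "cerebral_o2hb": rec.nirs_cerebral.o2hb,
            "cerebral_hhb": rec.nirs_cerebral.hhb,
            "cerebral_tsi": rec.nirs_cerebral.tsi,
            "hr": rec.hr, "spo2": rec.spo2,
            "force_pre": rec.nm_pre.force, "emg_pre": rec.nm_pre.emg,
            "force_post": rec.nm_post.force, "emg_post": rec.nm_post.emg,
        }
        for name, tr in channels.items():
            _write_channel(d / f"{name}.csv", tr)
            manifest.append({"participant": rec.participant,
                             "condition": rec.condition, "channel": name,
                             "path": str(Path(d.name) / f"{name}.csv")})
        pd.DataFrame({"time_s": rec.breath_times, "value": rec.breath_vo2}
                     ).to_csv(d / "vo2_breaths.csv", index=False, float_format="%.6f")
        sidecar = {
            "timeline": {"starts": rec.timeline.starts.tolist(),
                         "ends": rec.timeline.ends.tolist()},
            "markers_pre": rec.nm_pre.markers, "markers_post": rec.nm_post.markers,
            "scalars": rec.scalars,
            "ground_truth": {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                             for k, v in
                             dataset.ground_truth.get(rec.participant,
                                                      rec.condition).items()},
        }
        (d / "sidecar.json").write_text(json.dumps(sidecar, indent=1, sort_keys=True))
    pd.DataFrame(manifest).to_csv(out / "manifest.csv", index=False)
    return out
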