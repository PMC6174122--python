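"""Evoked-force and EMG neuromuscular fatigue metrics.

The assessment protocol is an MVC with a superimposed 100-Hz doublet delivered
at peak force, followed at 2-s spacing by resting 100-Hz (P100) and 10-Hz
(P10) paired stimulations and a single twitch.  Extracted metrics: MVC peak
force, evoked amplitudes, the interpolated-twitch voluntary activation level

    VAL(%) = (1 - superimposed * (voluntary_at_stim / MVC) / potentiated_doublet) * 100

(with the voluntary/MVC correction factor for stimulations delivered slightly
off the force peak), the low/high-frequency force ratio P10/P100, the EMG RMS
over a 250-ms epoch at peak force, and the M-wave-normalized RMS.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import ChannelTrace

__all__ = [
    "mvc_peak",
    "evoked_amplitude",
    "compute_val",
    "p10_over_p100",
    "emg_rms_at_peak",
    "m_wave_amplitude",
    "rms_over_mwave",
    "NeuromuscularAssessment",
    "analyze_assessment",
]

BASELINE_WINDOW_S = 0.100     # pre-stimulus baseline
EVOKED_WINDOW_S = 0.5         # evoked-force search window
MWAVE_WINDOW_S = 0.050        # M-wave search window after the stimulus


def mvc_peak(force: ChannelTrace, mvc_window: tuple[float, float]
             ) -> tuple[float, float]:
    """Baseline-corrected maximal voluntary force and its time.

    ``mvc_window`` should end at (or before) the superimposed stimulation so
    the evoked increment is excluded.  Baseline is the mean of the first
    0.5 s of the trace (rest).  A zero (or negative) peak is reported with a
    warning rather than an error.
    """
    baseline = float(force.segment(force.start_time,
                                   force.start_time + 0.5).mean())
    seg = force.segment(*mvc_window)
    i = int(np.argmax(seg))
    peak = float(seg[i]) - baseline
    if peak <= 0:
        warnings.warn("non-positive MVC peak force", stacklevel=2)
    i0 = int(np.ceil((mvc_window[0] - force.start_time) * force.fs - 1e-9))
    return peak, force.start_time + (i0 + i) / force.fs


def evoked_amplitude(force: ChannelTrace, marker: float,
                     window_s: float = EVOKED_WINDOW_S,
                     superimposed: bool = False) -> float:
    """Evoked-force amplitude: peak within the post-stimulus window minus the
    pre-stimulus baseline.

    For resting stimulations the baseline is the mean force over the 100 ms
    before the marker; for a superimposed stimulation it is the voluntary
    force at stimulation onset (mean of the 50 ms before the marker, which is
    less sensitive to a single noisy sample than the instantaneous value).
    """
    t_end = force.start_time + force.duration
    if not force.start_time <= marker <= t_end:
        raise ValueError(f"marker {marker} s outside trace span")
    pre = 0.050 if superimposed else BASELINE_WINDOW_S
    baseline = float(force.segment(max(marker - pre, force.start_time),
                                   marker).mean())
    seg = force.segment(marker, min(marker + window_s, t_end))
    return float(seg.max()) - baseline


def compute_val(superimposed: float, voluntary_at_stim: float, mvc: float,
                resting_doublet: float, corrected: bool = True,
                clamp: bool = True) -> float:
    """Interpolated-twitch voluntary activation level in percent.

    ``corrected=True`` applies the off-peak correction factor
    ``voluntary_at_stim / mvc`` to the superimposed amplitude (the form used
    when the stimulation cannot be guaranteed to land exactly on the force
    peak); ``corrected=False`` gives the classical uncorrected ratio.  Values
    above 100 (a negative superimposed estimate, possible under noise) clamp
    to 100 with a warning.
    """
    if resting_doublet <= 0:
        raise ValueError("resting doublet amplitude must be positive")
    if mvc <= 0:
        raise ValueError("MVC must be positive")
    if not 0 <= voluntary_at_stim <= mvc * (1 + 1e-9):
        raise ValueError("voluntary force at stimulation must lie in [0, MVC]")
    eff = superimposed * (voluntary_at_stim / mvc) if corrected else superimposed
    val = (1.0 - eff / resting_doublet) * 100.0
    if val > 100.0 and clamp:
        warnings.warn(f"VAL {val:.1f}% exceeds 100% (negative superimposed "
                      "estimate); clamping", stacklevel=2)
        val = 100.0
    return float(val)


def p10_over_p100(p10: float, p100: float) -> float:
    """Low/high-frequency evoked-force ratio (peripheral fatigue marker)."""
    if p100 <= 0:
        raise ValueError("P100 must be positive")
    return float(p10 / p100)


def emg_rms_at_peak(emg: ChannelTrace, peak_time: float,
                    epoch_s: float = 0.250) -> float:
    """RMS of the baseline-corrected EMG over an epoch centred on peak force."""
    half = epoch_s / 2
    seg = emg.segment(peak_time - half, peak_time + half)
    seg = seg - seg.mean()
    return float(np.sqrt(np.mean(seg ** 2)))


def m_wave_amplitude(emg: ChannelTrace, stim_marker: float,
                     window_s: float = MWAVE_WINDOW_S) -> float:
    """Peak-to-peak amplitude of the evoked compound action potential within
    50 ms after the stimulus.  A flat window yields 0 with a warning."""
    seg = emg.segment(stim_marker, stim_marker + window_s)
    pp = float(seg.max() - seg.min())
    if pp == 0.0:
        warnings.warn("no M-wave deflection after stimulus", stacklevel=2)
    return pp


def rms_over_mwave(rms: float, m_wave_pp: float) -> float:
    """EMG RMS normalized by the M-wave peak-to-peak amplitude."""
    if m_wave_pp <= 0:
        raise ValueError("M-wave amplitude must be positive")
    return float(rms / m_wave_pp)


@dataclass
class NeuromuscularAssessment:
    """Metrics of one pre- or post-RST assessment (a Table-2-style row)."""

    phase: str
    mvc: float
    superimposed: float
    p100: float
    p10: float
    twitch: float
    val: float
    p10_p100: float
    emg_rms: float
    m_wave_pp: float
    rms_mwave: float
    val_exceeded_100: bool = False

    def to_row(self) -> dict:
        return {"phase": self.phase, "mvc_N": self.mvc, "val_pct": self.val,
                "p10_p100": self.p10_p100, "rms_mwave": self.rms_mwave,
                "p100_N": self.p100, "p10_N": self.p10, "twitch_N": self.twitch,
                "val_flagged": self.val_exceeded_100}


def analyze_assessment(force: ChannelTrace, emg: ChannelTrace,
                       markers: dict[str, float], phase: str = "pre",
                       corrected_val: bool = True,
                       m_wave_source: str = "twitch") -> NeuromuscularAssessment:
    """Extract all metrics from one assessment recording.

    The potentiated resting doublet in the activation formula is the P100
    response (the stimulation order — MVC first, then resting stimulations —
    makes it post-contraction, i.e. potentiated).  ``m_wave_source`` selects
    which stimulation's M-wave normalizes the voluntary RMS (single twitch by
    default).
    """
    required = {"superimposed", "p100", "p10", "twitch"}
    if not required <= set(markers):
        raise ValueError(f"markers must include {sorted(required)}")

    t_sd = markers["superimposed"]
    mvc, t_peak = mvc_peak(force, (force.start_time, t_sd))
    superimposed = evoked_amplitude(force, t_sd, superimposed=True)
    p100 = evoked_amplitude(force, markers["p100"])
    p10 = evoked_amplitude(force, markers["p10"])
    twitch = evoked_amplitude(force, markers["twitch"])

    baseline = float(force.segment(force.start_time, force.start_time + 0.5).mean())
    voluntary_at_stim = float(force.segment(t_sd - 0.050, t_sd).mean()) - baseline
    voluntary_at_stim = min(max(voluntary_at_stim, 0.0), mvc)

    raw_val = compute_val(max(superimposed, 0.0), voluntary_at_stim, mvc, p100,
                          corrected=corrected_val, clamp=False)
    exceeded = raw_val > 100.0
    if exceeded:
        warnings.warn(f"{phase}: VAL {raw_val:.1f}% > 100% (likely submaximal "
                      "MVC or noisy superimposed estimate); clamped and "
                      "flagged", stacklevel=2)
    val = min(raw_val, 100.0)

    rms = emg_rms_at_peak(emg, t_peak)
    mw = m_wave_amplitude(emg, markers[m_wave_source])
    return NeuromuscularAssessment(
        phase=phase, mvc=mvc, superimposed=superimposed, p100=p100, p10=p10,
        twitch=twitch, val=val, p10_p100=p10_over_p100(p10, p100),
        emg_rms=rms, m_wave_pp=mw, rms_mwave=rms_over_mwave(rms, mw),
        val_exceeded_100=exceeded)
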