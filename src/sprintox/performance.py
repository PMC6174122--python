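"""Sprint-performance and metabolic endpoint summaries for one RST.

Implements the standard repeated-sprint-ability metrics: per-sprint mean and
peak power, total work, the percent-decrement fatigue index

    S_dec(%) = [1 - (S_mean / S_best)] * 100

with S_best the higher mean power of the first two sprints, the 95 %
anti-pacing check against the warm-up sprints, the cadence-based task-failure
rule (< 70 rpm), the highest 30-s average of breath-by-breath oxygen uptake,
and the lowest stable pulse-oximetry value of the final minute.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import ChannelTrace, SprintTimeline

__all__ = [
    "per_sprint_power",
    "fatigue_index",
    "total_work",
    "validate_pacing",
    "detect_task_failure",
    "vo2_peak",
    "spo2_summary",
    "SprintPerformance",
    "summarize_performance",
]


def _integrate(trace: ChannelTrace, start: float, end: float) -> float:
    """Trapezoidal integral of the trace over [start, end], with the boundary
    values obtained by linear interpolation so partial samples count."""
    t = trace.times()
    if start < t[0] - 1e-9 or end > t[-1] + 1e-9:
        raise ValueError(f"interval [{start}, {end}] outside trace span")
    inner = (t > start) & (t < end)
    ts = np.concatenate(([start], t[inner], [end]))
    vs = np.concatenate(([trace.value_at(start)], trace.values[inner],
                         [trace.value_at(end)]))
    return float(np.trapezoid(vs, ts))


def per_sprint_power(power: ChannelTrace, timeline: SprintTimeline
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Per-sprint (time-average, peak-sample) power in W."""
    if timeline.n_sprints < 1:
        raise ValueError("timeline contains no sprints")
    means = np.empty(timeline.n_sprints)
    peaks = np.empty(timeline.n_sprints)
    for k, (a, b) in enumerate(timeline.intervals()):
        means[k] = _integrate(power, a, b) / (b - a)
        peaks[k] = power.segment(a, b + 0.5 / power.fs).max()
    return means, peaks


def fatigue_index(per_sprint_mean_powers: np.ndarray | list) -> float:
    """Percent decrement S_dec relative to the best of the first two sprints."""
    p = np.asarray(per_sprint_mean_powers, dtype=float)
    if p.size < 2:
        raise ValueError("fatigue index needs at least two sprints")
    s_best = float(p[:2].max())
    if s_best <= 0:
        raise ValueError("best sprint power must be positive")
    return float((1.0 - p.mean() / s_best) * 100.0)


def total_work(power: ChannelTrace, timeline: SprintTimeline) -> float:
    """Work performed during the sprints, in kJ (trapezoidal integration)."""
    if timeline.n_sprints < 1:
        raise ValueError("timeline contains no sprints")
    return sum(_integrate(power, a, b) for a, b in timeline.intervals()) / 1000.0


def validate_pacing(first_two_sprint_peaks: tuple[float, float] | np.ndarray,
                    warmup_best_peak: float, threshold: float = 0.95) -> bool:
    """True iff the better of the first two RST sprints reached at least
    ``threshold`` (default 95 %) of the best warm-up sprint's peak power."""
    peaks = np.asarray(first_two_sprint_peaks, dtype=float)
    return bool(peaks.max() >= threshold * warmup_best_peak)


def detect_task_failure(cadence: ChannelTrace, timeline: SprintTimeline,
                        threshold_rpm: float = 70.0, dwell_s: float = 1.0
                        ) -> int | None:
    """First sprint (0-based index) in which cadence stays below the failure
    threshold for at least ``dwell_s`` seconds, or None.

    The dwell requirement ignores single-sample cadence dropouts; a test ends
    at the first sprint where the rider can no longer hold 70 rpm.
    """
    min_run = max(int(round(dwell_s * cadence.fs)), 1)
    for k, (a, b) in enumerate(timeline.intervals()):
        below = cadence.segment(a, b + 0.5 / cadence.fs) < threshold_rpm
        run = 0
        for flag in below:
            run = run + 1 if flag else 0
            if run >= min_run:
                return k
    return None


def vo2_peak(breath_times: np.ndarray, breath_values: np.ndarray,
             window_s: float = 30.0) -> float:
    """Highest ``window_s``-second average of breath-by-breath oxygen uptake.

    The irregular series is treated as a sample-and-hold step function and the
    time-weighted mean is maximized over all window placements; because the
    objective is piecewise linear in the window start, the maximum is attained
    with a window edge on a breath time, so only those candidates are scanned.
    """
    t = np.asarray(breath_times, dtype=float)
    v = np.asarray(breath_values, dtype=float)
    if t.size != v.size or t.size < 2:
        raise ValueError("need matching breath times and values (>= 2 breaths)")
    if np.any(np.diff(t) <= 0):
        raise ValueError("breath times must be strictly increasing")
    span = t[-1] - t[0]
    if span < window_s:
        raise ValueError(f"record of {span:.1f} s is shorter than the "
                         f"{window_s:.0f}-s averaging window")

    cum = np.concatenate(([0.0], np.cumsum(v[:-1] * np.diff(t))))

    def window_mean(s: float) -> float:
        e = s + window_s
        ia = int(np.searchsorted(t, s, side="right") - 1)
        ib = int(np.searchsorted(t, e, side="right") - 1)
        area = (cum[ib] - cum[ia]) - (s - t[ia]) * v[ia] + (e - t[ib]) * v[ib]
        return area / window_s

    candidates = np.concatenate((t, t - window_s))
    candidates = candidates[(candidates >= t[0]) & (candidates <= t[-1] - window_s)]
    return float(max(window_mean(s) for s in candidates))


def spo2_summary(spo2: ChannelTrace, final_minute: tuple[float, float]) -> float:
    """Lowest stable pulse-oximetry value within the final minute of the RST.

    "Stable" is operationalized as a run of >= 3 consecutive samples whose
    range is <= 2 %; the summary is the minimum run mean.  If no stable run
    exists the plain minimum is returned with a warning.
    """
    seg = spo2.segment(*final_minute)
    best = np.inf
    for i in range(seg.size - 2):
        for j in range(i + 3, seg.size + 1):
            run = seg[i:j]
            if run.max() - run.min() <= 2.0:
                best = min(best, float(run.mean()))
            else:
                break
    if not np.isfinite(best):
        warnings.warn("no stable run of >= 3 samples in the final minute; "
                      "falling back to the plain minimum", stacklevel=2)
        return float(seg.min())
    return best


@dataclass
class SprintPerformance:
    """Endpoint summary of one RST (one row of a Table-1-style report)."""

    n_sprints: int
    sprint_mean_powers: np.ndarray
    sprint_peak_powers: np.ndarray
    mean_power: float
    total_work_kj: float
    s_dec: float
    s_best: float
    pacing_valid: bool | None = None
    failure_sprint: int | None = None
    vo2_peak: float | None = None
    hr_max: float | None = None
    spo2: float | None = None
    scalars: dict = field(default_factory=dict)

    def to_row(self) -> dict:
        row = {"n_sprints": self.n_sprints, "mean_power_W": self.mean_power,
               "fatigue_index_pct": self.s_dec, "total_work_kJ": self.total_work_kj,
               "hr_max_bpm": self.hr_max, "spo2_pct": self.spo2,
               "vo2_Lmin": self.vo2_peak}
        row.update(self.scalars)
        return row


def summarize_performance(power: ChannelTrace, timeline: SprintTimeline,
                          cadence: ChannelTrace | None = None,
                          breath_times: np.ndarray | None = None,
                          breath_vo2: np.ndarray | None = None,
                          hr: ChannelTrace | None = None,
                          spo2: ChannelTrace | None = None,
                          scalars: dict | None = None,
                          warmup_best_peak: float | None = None,
                          ) -> SprintPerformance:
    """Assemble the full performance summary of one RST."""
    means, peaks = per_sprint_power(power, timeline)
    perf = SprintPerformance(
        n_sprints=timeline.n_sprints, sprint_mean_powers=means,
        sprint_peak_powers=peaks, mean_power=float(means.mean()),
        total_work_kj=total_work(power, timeline),
        s_dec=fatigue_index(means) if means.size >= 2 else np.nan,
        s_best=float(means[:2].max()),
        scalars=dict(scalars or {}))
    if warmup_best_peak is not None:
        perf.pacing_valid = validate_pacing(peaks[:2], warmup_best_peak)
    if cadence is not None:
        perf.failure_sprint = detect_task_failure(cadence, timeline)
    if breath_times is not None and breath_vo2 is not None:
        perf.vo2_peak = vo2_peak(breath_times, breath_vo2)
    if hr is not None:
        end = timeline.ends[-1]
        perf.hr_max = float(hr.segment(0.0, min(end + 30.0, hr.times()[-1])).max())
    if spo2 is not None:
        end = min(timeline.ends[-1] + timeline.recovery_duration_s,
                  spo2.start_time + spo2.duration)
        perf.spo2 = spo2_summary(spo2, (end - 60.0, end + 0.5 / spo2.fs))
    return perf
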