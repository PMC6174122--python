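"""Core containers for uniformly sampled physiological channels and sprint timelines.

A repeated sprint test (RST) is a sequence of fixed-duration all-out sprints
separated by active-recovery intervals, ridden to task failure, so the basic
temporal structure every module shares is a set of ordered, non-overlapping
sprint intervals over a common time axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["ChannelTrace", "SprintTimeline"]


@dataclass
class ChannelTrace:
    """One uniformly sampled signal.

    Parameters
    ----------
    values : ndarray
        Samples in the channel's native units (uM for NIRS chromophore
        concentration changes, % for TSI and SpO2, W for power, N for force,
        mV for EMG, rpm for cadence, bpm for heart rate).
    fs : float
        Sampling rate in Hz.
    site : str
        Anatomical site label, e.g. ``"vastus_lateralis"`` or
        ``"prefrontal_cortex"``.
    channel : str
        Channel label, e.g. ``"O2Hb"``, ``"HHb"``, ``"tHb"``, ``"TSI"``,
        ``"power"``, ``"force"``.
    units : str
        Unit string carried through for reporting.
    start_time : float
        Time of the first sample in seconds on the protocol clock.
    """

    values: np.ndarray
    fs: float
    site: str = ""
    channel: str = ""
    units: str = ""
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("ChannelTrace values must be one-dimensional")
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.values.size and not np.all(np.isfinite(self.values)):
            raise ValueError("ChannelTrace values must be finite")

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def duration(self) -> float:
        """Span covered by the samples, in seconds."""
        return 0.0 if self.n == 0 else (self.n - 1) / self.fs

    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.n) / self.fs

    def index_of(self, t: float) -> int:
        """Nearest sample index to time ``t`` (seconds, protocol clock)."""
        i = int(round((t - self.start_time) * self.fs))
        return min(max(i, 0), self.n - 1)

    def segment(self, start: float, end: float) -> np.ndarray:
        """Samples with start <= t < end. Raises if the window is empty."""
        i0 = int(np.ceil((start - self.start_time) * self.fs - 1e-9))
        i1 = int(np.ceil((end - self.start_time) * self.fs - 1e-9))
        i0, i1 = max(i0, 0), min(i1, self.n)
        if i1 <= i0:
            raise ValueError(f"empty segment [{start}, {end}) for trace of span "
                             f"[{self.start_time}, {self.start_time + self.duration}]")
        return self.values[i0:i1]

    def value_at(self, t: float) -> float:
        """Linearly interpolated value at time ``t``."""
        return float(np.interp(t, self.times(), self.values))

    def with_values(self, values: np.ndarray, channel: str | None = None) -> "ChannelTrace":
        out = replace(self, values=np.asarray(values, dtype=float))
        if channel is not None:
            out.channel = channel
        return out


@dataclass
class SprintTimeline:
    """Ordered sprint intervals (and the recovery intervals between them).

    ``starts``/``ends`` give each sprint interval in seconds on the protocol
    clock.  ``troughs``, when present, are the pre-sprint trough times found by
    signal-driven segmentation (the local deoxygenation minimum preceding each
    sprint); metric extraction uses them to anchor the per-sprint minimum.
    """

    starts: np.ndarray
    ends: np.ndarray
    troughs: np.ndarray | None = None
    recovery_duration_s: float = 20.0

    def __post_init__(self) -> None:
        self.starts = np.asarray(self.starts, dtype=float)
        self.ends = np.asarray(self.ends, dtype=float)
        if self.starts.shape != self.ends.shape:
            raise ValueError("starts and ends must have equal length")
        if np.any(self.ends <= self.starts):
            raise ValueError("each sprint must have end > start")
        if self.n_sprints > 1:
            if np.any(np.diff(self.starts) <= 0) or np.any(self.starts[1:] < self.ends[:-1]):
                raise ValueError("sprint intervals must be ordered and non-overlapping")
        if self.troughs is not None:
            self.troughs = np.asarray(self.troughs, dtype=float)
            if self.troughs.shape != self.starts.shape:
                raise ValueError("troughs must have one entry per sprint")

    @property
    def n_sprints(self) -> int:
        return int(self.starts.size)

    def intervals(self) -> list[tuple[float, float]]:
        return list(zip(self.starts.tolist(), self.ends.tolist()))

    def recovery_intervals(self) -> list[tuple[float, float]]:
        """Recovery interval following each sprint (the last one uses the
        configured recovery duration)."""
        out = []
        for k in range(self.n_sprints):
            r_end = (self.starts[k + 1] if k + 1 < self.n_sprints
                     else self.ends[k] + self.recovery_duration_s)
            out.append((float(self.ends[k]), float(r_end)))
        return out

    @classmethod
    def regular(cls, n_sprints: int, sprint_duration_s: float = 10.0,
                recovery_duration_s: float = 20.0, first_start_s: float = 0.0) -> "SprintTimeline":
        """Evenly spaced protocol timeline (ergometer log)."""
        if n_sprints < 1:
            raise ValueError("need at least one sprint")
        period = sprint_duration_s + recovery_duration_s
        starts = first_start_s + period * np.arange(n_sprints)
        return cls(starts=starts, ends=starts + sprint_duration_s,
                   recovery_duration_s=recovery_duration_s)
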