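"""Peak/valley detection and the per-second / per-session amplitude
averages that drive the pressure formulas.

Detection is a strict three-point comparison (a sample is a peak iff it
exceeds both neighbours), followed by a physiological plausibility
filter: at 120 beats/min a peak and its neighbouring valley are 0.25 s
apart, so any adjacent peak-valley pair closer than 0.25 s must be a
disturbance and the later member of the pair is discarded; the rule is
re-applied until no violation remains. Exactly 0.25 s is retained (the
comparison is strict).

For each one-second window [w, w+1) the peak (valley) amplitude is the
sum of surviving peak (valley) values divided by their count, truncated
to two decimals; a session averages a fixed number of such windows
(ten by default, one ten-second measurement).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .bp import truncate2
from .errors import InsufficientDataError, InvalidArgumentError
from .trace import PulseTrace

__all__ = ["ExtremaSeries", "SecondSummary", "PeakValleySummary",
           "detect_extrema", "per_second_summary", "session_summary",
           "summarize_trace", "MIN_PEAK_VALLEY_GAP_S"]

#: Minimum plausible adjacent peak-valley separation, seconds.
MIN_PEAK_VALLEY_GAP_S = 0.25


@dataclass(frozen=True)
class ExtremaSeries:
    """Detected (and filtered) peak and valley times/values."""

    peak_times: np.ndarray
    peak_values: np.ndarray
    valley_times: np.ndarray
    valley_values: np.ndarray

    def __post_init__(self):
        for name in ("peak_times", "peak_values", "valley_times", "valley_values"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        for tname in ("peak_times", "valley_times"):
            t = getattr(self, tname)
            if t.size > 1 and not np.all(np.diff(t) > 0):
                raise InvalidArgumentError(f"{tname} must be strictly increasing")
        if self.peak_times.size != self.peak_values.size:
            raise InvalidArgumentError("peak times/values length mismatch")
        if self.valley_times.size != self.valley_values.size:
            raise InvalidArgumentError("valley times/values length mismatch")


def _local_extrema(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of strict 3-point maxima and minima; a flat run counts as
    one extremum at its first sample."""
    n = x.size
    peaks, valleys = [], []
    i = 1
    while i < n - 1:
        # collapse a plateau to its first sample
        j = i
        while j < n - 1 and x[j + 1] == x[j]:
            j += 1
        if j >= n - 1:
            break
        left, here, right = x[i - 1], x[i], x[j + 1]
        if here > left and here > right:
            peaks.append(i)
        elif here < left and here < right:
            valleys.append(i)
        i = j + 1
    return np.asarray(peaks, dtype=int), np.asarray(valleys, dtype=int)


def _filter_close_pairs(events: list[tuple[float, float, int]]) -> list[tuple[float, float, int]]:
    """Repeatedly drop the later member of any adjacent peak-valley pair
    closer than the minimum gap. ``events`` are (time, value, type)
    sorted by time, type +1 peak / -1 valley."""
    events = list(events)
    changed = True
    while changed:
        changed = False
        for k in range(len(events) - 1):
            t0, _, typ0 = events[k]
            t1, _, typ1 = events[k + 1]
            if typ0 != typ1 and (t1 - t0) < MIN_PEAK_VALLEY_GAP_S:
                del events[k + 1]  # discard the later of the offending pair
                changed = True
                break
    return events


def detect_extrema(trace: PulseTrace) -> ExtremaSeries:
    """Detect peaks and valleys and apply the 0.25 s discard rule.

    A constant trace yields an empty series (not an error).
    """
    if trace.n_channels != 1:
        raise InvalidArgumentError("detect_extrema expects a single-channel trace")
    x = trace.samples[0]
    if x.size < 3:
        raise InvalidArgumentError("need at least 3 samples to detect extrema")
    p_idx, v_idx = _local_extrema(x)
    t = trace.times
    events = sorted(
        [(float(t[i]), float(x[i]), +1) for i in p_idx]
        + [(float(t[i]), float(x[i]), -1) for i in v_idx]
    )
    events = _filter_close_pairs(events)
    peaks = [(tt, vv) for tt, vv, typ in events if typ == +1]
    valleys = [(tt, vv) for tt, vv, typ in events if typ == -1]
    return ExtremaSeries(
        peak_times=np.array([e[0] for e in peaks]),
        peak_values=np.array([e[1] for e in peaks]),
        valley_times=np.array([e[0] for e in valleys]),
        valley_values=np.array([e[1] for e in valleys]),
    )


@dataclass(frozen=True)
class SecondSummary:
    """One row of the per-second amplitude table."""

    window: int           # seconds, 0-based window [w, w+1)
    peak_count: int
    valley_count: int
    peak_sum: float
    valley_sum: float
    e_peak: float | None  # truncate2(peak_sum / peak_count); None if count 0
    e_valley: float | None

    @property
    def valid(self) -> bool:
        return self.e_peak is not None and self.e_valley is not None


def per_second_summary(extrema: ExtremaSeries, window_index: int) -> SecondSummary:
    """Counts, sums and truncated averages for window [w, w+1) seconds."""
    if window_index < 0:
        raise InvalidArgumentError("window_index must be >= 0")
    w0, w1 = float(window_index), float(window_index) + 1.0
    pm = (extrema.peak_times >= w0) & (extrema.peak_times < w1)
    vm = (extrema.valley_times >= w0) & (extrema.valley_times < w1)
    pc, vc = int(pm.sum()), int(vm.sum())
    ps = float(extrema.peak_values[pm].sum())
    vs = float(extrema.valley_values[vm].sum())
    return SecondSummary(
        window=window_index,
        peak_count=pc,
        valley_count=vc,
        peak_sum=ps,
        valley_sum=vs,
        e_peak=truncate2(ps / pc) if pc > 0 else None,
        e_valley=truncate2(vs / vc) if vc > 0 else None,
    )


@dataclass(frozen=True)
class PeakValleySummary:
    """Per-second rows plus the session averages used for one
    blood-pressure measurement."""

    rows: tuple[SecondSummary, ...]
    e_peak: float
    e_valley: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (f"{r.window + 1} s", r.peak_count, r.valley_count,
                 r.peak_sum, r.valley_sum, r.e_peak, r.e_valley)
                for r in self.rows
            ],
            columns=["time_s", "e_peak_len", "e_valley_len",
                     "e_peak_sum", "e_valley_sum", "e_peak", "e_valley"],
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def session_summary(rows: Sequence[SecondSummary], required: int = 10) -> PeakValleySummary:
    """Average the per-second amplitudes over a measurement session.

    Requires ``required`` valid rows (both counts non-zero); the session
    E_peak (E_valley) is the arithmetic mean of the per-second values.
    """
    valid = [r for r in rows if r.valid]
    if len(valid) < required:
        raise InsufficientDataError(
            f"need {required} valid per-second rows, got {len(valid)}",
            n_valid=len(valid), n_required=required,
        )
    use = valid[:required]
    e_peak = float(np.mean([r.e_peak for r in use]))
    e_valley = float(np.mean([r.e_valley for r in use]))
    return PeakValleySummary(rows=tuple(use), e_peak=e_peak, e_valley=e_valley)


def summarize_trace(
    pulse: PulseTrace, duration_s: int = 10
) -> PeakValleySummary:
    """End-to-end feature extraction on a separated pulse: extrema,
    per-second rows for each of ``duration_s`` windows, session summary."""
    if pulse.duration < duration_s:
        raise InsufficientDataError(
            f"trace covers {pulse.duration:.2f} s but {duration_s} s are required",
            n_valid=int(pulse.duration), n_required=duration_s,
        )
    extrema = detect_extrema(pulse)
    rows = [per_second_summary(extrema, w) for w in range(duration_s)]
    return session_summary(rows, required=duration_s)
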