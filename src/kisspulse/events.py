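"""Synchronised-event (SE) detection and quantification on dF/F traces.

An SE is a supra-threshold excursion of the population calcium signal:
samples exceeding ``trace_mean + k_sd * trace_sd`` (default k = 3).  Each
maximal supra-threshold run lasting at least ``min_duration`` seconds of
retained signal is a candidate event; candidates with peaks closer than
``min_separation`` seconds are merged keeping the larger peak.

Event frequency is reported against elapsed wall-clock time (off-windows of
the duty cycle included), so events/hr remains physically meaningful.
Relative amplitudes are measured on per-animal normalised traces as peak
minus the nearest preceding nadir.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator

from .photometry import DffTrace

__all__ = [
    "SyncEvent",
    "EventSummary",
    "SyncEventDetector",
    "detect_events",
    "event_frequency",
    "relative_amplitude",
    "baseline_metrics",
]


@dataclass
class SyncEvent:
    """One detected synchronised event."""

    onset_t: float  # seconds, first supra-threshold sample
    peak_t: float  # seconds
    end_t: float  # seconds, last supra-threshold sample
    peak_dff: float  # % (or normalised units)
    rel_amplitude: float = float("nan")  # peak minus preceding nadir (normalised)

    def __post_init__(self) -> None:
        if not (self.onset_t <= self.peak_t <= self.end_t):
            raise ValueError("event must satisfy onset_t <= peak_t <= end_t")


@dataclass
class EventSummary:
    """Per-session event statistics."""

    n_events: int
    freq_per_hr: float
    mean_rel_amplitude: float  # NaN when n_events == 0
    elapsed_hr: float

    def __post_init__(self) -> None:
        if self.elapsed_hr <= 0:
            raise ValueError("elapsed_hr must be positive")


class SyncEventDetector(BaseEstimator):
    """Threshold event detector as an estimator.

    Parameters
    ----------
    k_sd : float
        Threshold multiplier: events exceed ``mean + k_sd * SD`` of the trace.
    min_separation : float
        Peaks closer than this (seconds, wall clock) are merged.
    min_duration : float
        Minimum supra-threshold duration in retained-signal seconds.

    Attributes
    ----------
    threshold_ : float
        The detection threshold used for the fitted trace.
    events_ : list of SyncEvent
    """

    def __init__(
        self, k_sd: float = 3.0, min_separation: float = 30.0, min_duration: float = 2.0
    ):
        self.k_sd = k_sd
        self.min_separation = min_separation
        self.min_duration = min_duration

    def fit(self, trace: DffTrace, y=None) -> "SyncEventDetector":
        if self.k_sd <= 0:
            raise ValueError("k_sd must be positive")
        if trace.t.size == 0:
            raise ValueError("empty trace")
        t, dff = trace.t, trace.dff
        dt = float(np.median(np.diff(t))) if t.size > 1 else 0.0
        if dt <= 0:
            raise ValueError("trace must contain at least two samples")
        if self.min_duration < dt:
            raise ValueError(
                f"min_duration {self.min_duration}s is below the sampling step {dt}s"
            )
        threshold = trace.trace_mean + self.k_sd * trace.trace_sd
        self.threshold_ = float(threshold)

        above = dff > threshold
        events: list[SyncEvent] = []
        n_min = int(round(self.min_duration / dt))
        i, n = 0, above.size
        while i < n:
            if not above[i]:
                i += 1
                continue
            j = i
            while j + 1 < n and above[j + 1]:
                j += 1
            if (j - i + 1) >= n_min:
                k = i + int(np.argmax(dff[i : j + 1]))
                events.append(
                    SyncEvent(
                        onset_t=float(t[i]),
                        peak_t=float(t[k]),
                        end_t=float(t[j]),
                        peak_dff=float(dff[k]),
                    )
                )
            i = j + 1

        # merge events closer than min_separation (wall clock): either peak to
        # peak, or the gap between one run's end and the next run's onset (a
        # brief sub-threshold dip inside a single transient is not a new event)
        merged: list[SyncEvent] = []
        for ev in events:
            if merged and (
                ev.peak_t - merged[-1].peak_t < self.min_separation
                or ev.onset_t - merged[-1].end_t < self.min_separation
            ):
                prev = merged[-1]
                keep = ev if ev.peak_dff > prev.peak_dff else prev
                merged[-1] = SyncEvent(
                    onset_t=min(prev.onset_t, ev.onset_t),
                    peak_t=keep.peak_t,
                    end_t=max(prev.end_t, ev.end_t),
                    peak_dff=keep.peak_dff,
                )
            else:
                merged.append(ev)
        merged.sort(key=lambda e: e.peak_t)
        self.events_ = merged
        return self

    def predict(self, trace: DffTrace | None = None) -> list[SyncEvent]:
        if trace is not None:
            return SyncEventDetector(**self.get_params()).fit(trace).events_
        if not hasattr(self, "events_"):
            raise RuntimeError("detector is not fitted")
        return self.events_


def detect_events(
    trace: DffTrace,
    k_sd: float = 3.0,
    min_separation: float = 30.0,
    min_duration: float = 2.0,
) -> list[SyncEvent]:
    """Detect SEs on a dF/F trace (see :class:`SyncEventDetector`)."""
    det = SyncEventDetector(
        k_sd=k_sd, min_separation=min_separation, min_duration=min_duration
    )
    return det.fit(trace).events_


def event_frequency(
    events: Sequence[SyncEvent],
    elapsed_hr: float,
    mean_rel_amplitude: float | None = None,
) -> EventSummary:
    """Events per hour of wall-clock session time (off-windows included)."""
    if elapsed_hr <= 0:
        raise ValueError("elapsed time must be positive")
    if mean_rel_amplitude is None:
        amps = [e.rel_amplitude for e in events if np.isfinite(e.rel_amplitude)]
        mean_rel_amplitude = float(np.mean(amps)) if amps else float("nan")
    return EventSummary(
        n_events=len(events),
        freq_per_hr=len(events) / elapsed_hr,
        mean_rel_amplitude=mean_rel_amplitude,
        elapsed_hr=elapsed_hr,
    )


def relative_amplitude(
    events: Sequence[SyncEvent],
    trace: DffTrace,
    lookback_s: float = 120.0,
) -> tuple[list[float], float]:
    """Peak minus nearest preceding nadir for each event, and the mean.

    The nadir is the trace minimum between the previous event's end (or the
    trace start) and the event peak, looking back at most ``lookback_s``
    seconds.  Amplitudes are conventionally computed on normalised traces.
    Events are updated in place with their ``rel_amplitude``.
    """
    t, dff = trace.t, trace.dff
    amps: list[float] = []
    prev_end = -np.inf
    for ev in events:
        if ev.peak_t < t[0] or ev.peak_t > t[-1]:
            raise ValueError(f"event peak at {ev.peak_t}s lies outside the trace span")
        start = max(prev_end, ev.peak_t - lookback_s)
        mask = (t >= start) & (t <= ev.peak_t)
        nadir = float(np.min(dff[mask])) if np.any(mask) else float(dff[0])
        amp = ev.peak_dff - nadir
        ev.rel_amplitude = amp
        amps.append(amp)
        prev_end = ev.end_t
    mean = float(np.mean(amps)) if amps else float("nan")
    return amps, mean


def baseline_metrics(
    trace: DffTrace, events: Sequence[SyncEvent]
) -> dict[str, float | int | bool]:
    """Quantify baseline (non-event) activity.

    Returns the median and SD of non-event samples and the fraction of them
    exceeding ``trace_mean + 1 SD`` — a simple summary of the raised-baseline
    phenotype of late pregnancy / late lactation.  If every sample falls
    inside an event the result is flagged empty rather than raising.
    """
    if trace.t.size == 0:
        raise ValueError("empty trace")
    mask = np.ones(trace.t.size, dtype=bool)
    for ev in events:
        mask &= ~((trace.t >= ev.onset_t) & (trace.t <= ev.end_t))
    base = trace.dff[mask]
    if base.size == 0:
        return {
            "n_baseline_samples": 0,
            "empty": True,
            "median_dff": float("nan"),
            "sd_dff": float("nan"),
            "frac_above_1sd": float("nan"),
        }
    cut = trace.trace_mean + trace.trace_sd
    return {
        "n_baseline_samples": int(base.size),
        "empty": False,
        "median_dff": float(np.median(base)),
        "sd_dff": float(np.std(base, ddof=1)) if base.size > 1 else 0.0,
        "frac_above_1sd": float(np.mean(base > cut)),
    }
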