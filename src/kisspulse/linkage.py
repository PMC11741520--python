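"""Pairing of synchronised events with LH pulses and per-state summaries.

Each SE is matched one-to-one to the earliest unmatched LH pulse peaking
within a window after the SE (default 12 min, two sampling intervals).  The
association between SEs and pulses is tested with a Pearson chi-squared on a
2x2 table built from post-SE windows versus equal-width control windows
immediately preceding each SE, each scored for pulse occurrence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .events import EventSummary, SyncEvent
from .pulsar import LHPulse
from .synth import STATE_ORDER

__all__ = [
    "PairingResult",
    "StateSummary",
    "pair_se_lh",
    "association_test",
    "summarize_states",
]


@dataclass
class PairingResult:
    """Outcome of SE-LH pulse matching for one or more pooled sessions."""

    n_se: int
    n_matched: int
    n_pulses: int
    window_min: float
    matches: list[tuple[float, float]] = field(default_factory=list)  # (se_min, pulse_min)
    contingency: np.ndarray | None = None  # 2x2: window type x pulse occurrence
    chi2: float = float("nan")
    p: float = float("nan")

    def __post_init__(self) -> None:
        if not 0 <= self.n_matched <= self.n_se:
            raise ValueError("n_matched must lie in [0, n_se]")

    @property
    def match_fraction(self) -> float:
        return self.n_matched / self.n_se if self.n_se else float("nan")


@dataclass
class StateSummary:
    """Between-session mean +/- SEM for one reproductive state."""

    state: str
    n_sessions: int
    mean_freq_per_hr: float
    sem_freq_per_hr: float  # NaN for a single session
    mean_rel_amplitude: float
    sem_rel_amplitude: float


def _contingency(
    se_min: np.ndarray, pulse_min: np.ndarray, window: float
) -> np.ndarray:
    """2x2 counts: post-SE windows vs preceding control windows of equal
    width, scored for containing at least one pulse peak."""
    post_hit = sum(
        bool(np.any((pulse_min > s) & (pulse_min <= s + window))) for s in se_min
    )
    ctrl_hit = sum(
        bool(np.any((pulse_min > s - window) & (pulse_min <= s))) for s in se_min
    )
    n = se_min.size
    return np.array(
        [[post_hit, n - post_hit], [ctrl_hit, n - ctrl_hit]], dtype=float
    )


def pair_se_lh(
    events: Sequence[SyncEvent],
    pulses: Sequence[LHPulse],
    window_min: float = 12.0,
) -> PairingResult:
    """Match SEs to LH pulses within ``window_min`` minutes.

    Event times are in seconds and pulse times in minutes; the conversion is
    done here.  Matching is greedy-earliest and one-to-one: each SE takes the
    first unmatched pulse peaking in ``(se, se + window]``.
    """
    if window_min < 0:
        raise ValueError("pairing window must be non-negative")
    se_min = np.asarray(sorted(e.peak_t / 60.0 for e in events))
    pulse_min = np.asarray(sorted(p.peak_t for p in pulses))

    matched_pulse = np.zeros(pulse_min.size, dtype=bool)
    matches: list[tuple[float, float]] = []
    for s in se_min:
        cand = np.flatnonzero(
            (pulse_min > s) & (pulse_min <= s + window_min) & ~matched_pulse
        )
        if cand.size:
            j = int(cand[0])
            matched_pulse[j] = True
            matches.append((float(s), float(pulse_min[j])))

    table = _contingency(se_min, pulse_min, window_min) if se_min.size else None
    return PairingResult(
        n_se=int(se_min.size),
        n_matched=len(matches),
        n_pulses=int(pulse_min.size),
        window_min=window_min,
        matches=matches,
        contingency=table,
    )


def association_test(
    result: PairingResult | np.ndarray,
) -> tuple[float, float]:
    """Pearson chi-squared (1 df, two-sided, no continuity correction) on the
    2x2 SE-window x pulse-occurrence table.

    A zero row or column margin makes the statistic undefined and raises.
    """
    table = result.contingency if isinstance(result, PairingResult) else np.asarray(result, dtype=float)
    if table is None or table.shape != (2, 2):
        raise ValueError("a 2x2 contingency table is required")
    if np.any(table < 0):
        raise ValueError("contingency counts must be non-negative")
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    if np.any(rows == 0) or np.any(cols == 0):
        raise ValueError("degenerate table: zero row or column margin")
    n = table.sum()
    expected = np.outer(rows, cols) / n
    chi2 = float(((table - expected) ** 2 / expected).sum())
    p = float(stats.chi2.sf(chi2, df=1))
    if isinstance(result, PairingResult):
        result.chi2 = chi2
        result.p = p
    return chi2, p


def summarize_states(
    sessions: Sequence[tuple[str, EventSummary]],
) -> list[StateSummary]:
    """Per-state mean +/- SEM of event frequency and relative amplitude.

    SEM is between-session (the unit of replication is the session/animal,
    not the sample).  States are ordered by the canonical reproductive-state
    sequence; a single-session state reports SEM = NaN.
    """
    by_state: dict[str, list[EventSummary]] = {}
    for state, summ in sessions:
        if state not in STATE_ORDER:
            raise ValueError(
                f"unknown state {state!r}; valid states: {', '.join(STATE_ORDER)}"
            )
        by_state.setdefault(state, []).append(summ)

    def _sem(values: np.ndarray) -> float:
        if values.size < 2:
            return float("nan")
        return float(np.std(values, ddof=1) / np.sqrt(values.size))

    out: list[StateSummary] = []
    for state in STATE_ORDER:
        if state not in by_state:
            continue
        freqs = np.asarray([s.freq_per_hr for s in by_state[state]])
        amps = np.asarray(
            [s.mean_rel_amplitude for s in by_state[state] if np.isfinite(s.mean_rel_amplitude)]
        )
        out.append(
            StateSummary(
                state=state,
                n_sessions=int(freqs.size),
                mean_freq_per_hr=float(np.mean(freqs)),
                sem_freq_per_hr=_sem(freqs),
                mean_rel_amplitude=float(np.mean(amps)) if amps.size else float("nan"),
                sem_rel_amplitude=_sem(amps),
            )
        )
    return out
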