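"""Two-channel fibre-photometry preprocessing.

GCaMP photometry records a calcium-dependent 490 nm signal together with a
405 nm control (isosbestic) signal that shares the motion and photobleaching
artifacts but carries no calcium information.  The control channel is
smoothed with a Savitzky-Golay filter, regressed onto the signal channel by
ordinary least squares, and the fitted control is subtracted from and divided
into the signal channel to give dF/F in percent:

    dF/F_i = 100 * (f490_i - fit405_i) / fit405_i

Per-animal normalisation divides each trace by the mean of the per-trace
maxima of three reference (pre-pregnancy) recordings, so amplitudes are
comparable within an animal across reproductive states.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.signal import savgol_filter
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "SchedulePattern",
    "RawPhotometrySession",
    "DffTrace",
    "NormalizationConstant",
    "IsosbesticCorrector",
    "fit_control_channel",
    "compute_dff",
    "compute_norm_constant",
    "normalize_dff",
]


@dataclass(frozen=True)
class SchedulePattern:
    """Duty-cycled acquisition schedule: ``on_s`` seconds of illumination every
    ``on_s + off_s`` seconds, sampled at ``rate_hz`` while on."""

    on_s: float = 5.0
    off_s: float = 15.0
    rate_hz: float = 10.0

    def __post_init__(self) -> None:
        if self.on_s <= 0:
            raise ValueError("on_s must be > 0")
        if self.off_s < 0:
            raise ValueError("off_s must be >= 0")
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be > 0")

    @property
    def period_s(self) -> float:
        return self.on_s + self.off_s

    @property
    def duty_cycle(self) -> float:
        return self.on_s / self.period_s


@dataclass
class RawPhotometrySession:
    """Timestamped 405/490 nm fluorescence confined to schedule on-windows."""

    t: np.ndarray  # seconds from session start
    f405: np.ndarray  # a.u.
    f490: np.ndarray  # a.u.
    schedule: SchedulePattern = field(default_factory=SchedulePattern)
    animal_id: str = "synthetic"
    state: str = "nl_diestrus"

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.f405 = np.asarray(self.f405, dtype=float)
        self.f490 = np.asarray(self.f490, dtype=float)
        if not (self.t.shape == self.f405.shape == self.f490.shape):
            raise ValueError("t, f405 and f490 must have equal length")
        if self.t.size and np.any(np.diff(self.t) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        for name, arr in (("t", self.t), ("f405", self.f405), ("f490", self.f490)):
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite values")

    @property
    def duration_s(self) -> float:
        """Wall-clock span including off-windows (end of last on-window)."""
        if self.t.size == 0:
            return 0.0
        return float(self.t[-1]) + 1.0 / self.schedule.rate_hz


@dataclass
class DffTrace:
    """Motion/bleach-corrected dF/F(%) series.

    ``trace_mean`` and ``trace_sd`` are computed over the full trace (events
    included); the event detector thresholds at mean + k*SD.
    """

    t: np.ndarray  # seconds
    dff: np.ndarray  # percent (or normalised units when ``normalised``)
    normalised: bool = False
    trace_mean: float = 0.0
    trace_sd: float = 0.0
    animal_id: str = "synthetic"
    state: str = "nl_diestrus"
    duration_s: float | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.dff = np.asarray(self.dff, dtype=float)
        if self.t.shape != self.dff.shape:
            raise ValueError("t and dff must have equal length")
        if not np.all(np.isfinite(self.dff)):
            raise ValueError("dff contains non-finite values")
        if self.duration_s is None:
            self.duration_s = float(self.t[-1]) if self.t.size else 0.0

    @classmethod
    def from_values(
        cls,
        t: np.ndarray,
        dff: np.ndarray,
        *,
        normalised: bool = False,
        **meta,
    ) -> "DffTrace":
        dff = np.asarray(dff, dtype=float)
        mean = float(np.mean(dff)) if dff.size else 0.0
        sd = float(np.std(dff, ddof=1)) if dff.size > 1 else 0.0
        return cls(
            t=t, dff=dff, normalised=normalised, trace_mean=mean, trace_sd=sd, **meta
        )


@dataclass(frozen=True)
class NormalizationConstant:
    """Per-animal scale: mean of per-trace maximum dF/F over reference
    (pre-pregnancy) recordings."""

    animal_id: str
    value: float
    n_traces: int = 3

    def __post_init__(self) -> None:
        if self.value <= 0:
            raise ValueError("normalisation constant must be > 0")


class IsosbesticCorrector(BaseEstimator, TransformerMixin):
    """Control-channel motion/bleach correction as a transformer.

    Parameters
    ----------
    sg_window : int
        Savitzky-Golay window length in samples applied to the 405 nm
        channel (default 101 samples, ~10 s of retained signal at 10 Hz).
        Must be odd and larger than ``sg_order``.
    sg_order : int
        Polynomial order of the Savitzky-Golay filter.

    Attributes
    ----------
    slope_, intercept_ : float
        OLS coefficients mapping the smoothed control onto the 490 nm signal.
    fitted405_ : ndarray
        ``slope_ * SG(f405) + intercept_`` for the fitted session.
    """

    def __init__(self, sg_window: int = 101, sg_order: int = 2):
        self.sg_window = sg_window
        self.sg_order = sg_order

    def fit(self, session: RawPhotometrySession, y=None) -> "IsosbesticCorrector":
        f405 = np.asarray(session.f405, dtype=float)
        f490 = np.asarray(session.f490, dtype=float)
        if f405.shape != f490.shape:
            raise ValueError("f405 and f490 must have equal length")
        if self.sg_window % 2 == 0 or self.sg_window <= self.sg_order:
            raise ValueError("sg_window must be odd and greater than sg_order")
        if f405.size < self.sg_window:
            raise ValueError(
                f"series length {f405.size} shorter than sg_window {self.sg_window}"
            )
        smoothed = savgol_filter(f405, self.sg_window, self.sg_order)
        if np.std(smoothed) <= 1e-12 * max(1.0, abs(float(np.mean(smoothed)))):
            raise ValueError("degenerate regression: smoothed control has zero variance")
        # OLS of f490 on the smoothed control, with intercept.
        slope, intercept = np.polyfit(smoothed, f490, 1)
        self.slope_ = float(slope)
        self.intercept_ = float(intercept)
        self.smoothed405_ = smoothed
        self.fitted405_ = self.slope_ * smoothed + self.intercept_
        return self

    def transform(self, session: RawPhotometrySession) -> DffTrace:
        if not hasattr(self, "slope_"):
            raise RuntimeError("corrector is not fitted")
        smoothed = savgol_filter(
            np.asarray(session.f405, dtype=float), self.sg_window, self.sg_order
        )
        fitted = self.slope_ * smoothed + self.intercept_
        return compute_dff(session, fitted)

    def fit_transform(self, session: RawPhotometrySession, y=None) -> DffTrace:
        self.fit(session)
        return compute_dff(session, self.fitted405_)


def fit_control_channel(
    f405: np.ndarray,
    f490: np.ndarray,
    sg_window: int = 101,
    sg_order: int = 2,
) -> np.ndarray:
    """Smooth the 405 nm control and fit it to the 490 nm signal by OLS.

    Returns the fitted control series ``a * SG(f405) + b``.  Positivity of
    the output is not guaranteed and is checked by :func:`compute_dff`.
    """
    session = RawPhotometrySession(
        t=np.arange(len(np.asarray(f405))), f405=f405, f490=f490
    )
    corr = IsosbesticCorrector(sg_window=sg_window, sg_order=sg_order).fit(session)
    return corr.fitted405_


def compute_dff(session: RawPhotometrySession, fitted405: np.ndarray) -> DffTrace:
    """dF/F(%) from a raw session and a fitted control series."""
    fitted405 = np.asarray(fitted405, dtype=float)
    if fitted405.shape != session.f490.shape:
        raise ValueError("fitted405 and session have different lengths")
    nonpos = np.flatnonzero(fitted405 <= 0)
    if nonpos.size:
        raise ValueError(
            f"fitted 405 signal is non-positive at index {int(nonpos[0])}; "
            "cannot form dF/F"
        )
    dff = 100.0 * (session.f490 - fitted405) / fitted405
    return DffTrace.from_values(
        t=session.t,
        dff=dff,
        normalised=False,
        animal_id=session.animal_id,
        state=session.state,
        duration_s=session.duration_s,
    )


def compute_norm_constant(
    traces: Sequence[DffTrace], animal_id: str | None = None
) -> NormalizationConstant:
    """Mean of per-trace maximum dF/F over reference recordings.

    Three pre-pregnancy traces are expected; any other number is accepted
    with a warning so partial datasets remain usable.
    """
    if len(traces) == 0:
        raise ValueError("at least one reference trace is required")
    if len(traces) != 3:
        warnings.warn(
            f"normalisation expects 3 reference traces, got {len(traces)}",
            UserWarning,
            stacklevel=2,
        )
    maxima = [float(np.max(tr.dff)) for tr in traces]
    if animal_id is None:
        animal_id = traces[0].animal_id
    return NormalizationConstant(
        animal_id=animal_id, value=float(np.mean(maxima)), n_traces=len(traces)
    )


def normalize_dff(trace: DffTrace, norm: NormalizationConstant) -> DffTrace:
    """Divide a trace elementwise by the per-animal normalisation constant."""
    if norm.value <= 0:
        raise ValueError("normalisation constant must be > 0")
    return replace(
        trace,
        dff=trace.dff / norm.value,
        normalised=True,
        trace_mean=trace.trace_mean / norm.value,
        trace_sd=trace.trace_sd / norm.value,
    )
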