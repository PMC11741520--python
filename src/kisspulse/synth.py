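"""Synthetic paired photometry + LH sessions with reproductive-state presets.

The generator emulates duty-cycled two-channel GCaMP recordings of the
arcuate kisspeptin population together with serial blood LH sampling:

* synchronised events (SEs) occur as a stationary renewal process at the
  per-state mean rate with a hard refractory gap, each adding a
  fast-rise/slow-decay calcium transient to the 490 nm channel only;
* both channels share exponential photobleaching and a slow common-mode
  motion artifact (coupling-proportional gains) plus channel white noise;
* samples exist only inside the scheduled 5 s on / 15 s off windows;
* each SE triggers, with the preset coupling probability, a delayed LH
  secretory bolus cleared with first-order kinetics; LH is read on a 6-min
  grid (plus an extra sample 2 min after an SE when the next scheduled draw
  is more than 3 min away), with multiplicative assay noise and censoring to
  the assay working range;
* "elevated baseline" states add low-amplitude events at twice the SE rate
  and a slow baseline oscillation.

Ground-truth event and pulse times are returned for recovery testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .photometry import RawPhotometrySession, SchedulePattern
from .pulsar import LHSeries

__all__ = [
    "StatePreset",
    "NoiseModel",
    "GroundTruth",
    "STATE_ORDER",
    "build_preset",
    "available_states",
    "simulate_photometry",
    "simulate_lh",
    "simulate_paired_session",
]

#: canonical ordering of reproductive states as reported
STATE_ORDER = (
    "nl_diestrus",
    "preg_d4",
    "preg_d14",
    "preg_d18",
    "lact_d7",
    "lact_d14",
    "lact_d18",
    "postwean_24h",
    "postwean_diestrus",
    "ovx",
)


@dataclass(frozen=True)
class StatePreset:
    """Generator parameterisation for one reproductive state.

    ``se_rate`` values are the reported per-state mean SE frequencies;
    amplitudes are conventions (absolute dF/F amplitudes are not reported
    and only within-animal relative amplitudes are meaningful).
    """

    name: str
    se_rate: float  # events / hour
    se_amplitude_mean: float = 15.0  # dF/F %
    se_amplitude_cv: float = 0.1
    min_event_gap: float = 900.0  # seconds, hard refractory
    baseline_mode: str = "normal"  # 'normal' | 'elevated'
    baseline_osc_amp: float = 0.0  # dF/F %, slow oscillation in elevated mode
    coupling_prob: float = 1.0
    pulse_delay_range: tuple[float, float] = (0.5, 3.0)  # minutes after SE
    lh_basal: float = 0.2  # ng/ml
    lh_halflife: float = 15.0  # minutes
    lh_bolus_mean: float = 1.5  # ng/ml

    def __post_init__(self) -> None:
        if self.se_rate < 0:
            raise ValueError("se_rate must be >= 0")
        if not 0 <= self.coupling_prob <= 1:
            raise ValueError("coupling_prob must be in [0, 1]")
        if self.lh_basal < 0:
            raise ValueError("lh_basal must be >= 0")
        if self.baseline_mode not in ("normal", "elevated"):
            raise ValueError("baseline_mode must be 'normal' or 'elevated'")
        if self.se_rate > 0 and 3600.0 / self.se_rate <= self.min_event_gap:
            raise ValueError("se_rate too high for the refractory min_event_gap")


@dataclass(frozen=True)
class NoiseModel:
    """Shared-artifact and assay noise parameters.

    Bleaching and the slow motion artifact are common to both channels; the
    motion gains are proportional to the channel baselines (both signals ride
    the same fibre coupling), which is what makes control-channel regression
    effective.  Assay parameters follow the LH ELISA working range
    (0.04-4 ng/ml, intra-assay CV 4.40%).
    """

    bleach_tau: float = 14400.0  # seconds (duty-cycled illumination)
    motion_sd: float = 0.01  # a.u., common-mode artifact amplitude
    motion_corr_s: float = 60.0  # correlation time of the artifact, seconds
    white_sd_405: float = 0.002  # a.u.
    white_sd_490: float = 0.003  # a.u.
    assay_cv: float = 4.40  # %
    lod: float = 0.04  # ng/ml
    assay_cap: float = 4.0  # ng/ml

    def __post_init__(self) -> None:
        for name in (
            "bleach_tau",
            "motion_sd",
            "white_sd_405",
            "white_sd_490",
            "assay_cv",
            "lod",
            "assay_cap",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.lod >= self.assay_cap:
            raise ValueError("lod must be below assay_cap")


@dataclass
class GroundTruth:
    """Injected event/pulse times and amplitudes for recovery tests."""

    se_times: np.ndarray = field(default_factory=lambda: np.empty(0))  # seconds (onsets)
    se_amplitudes: np.ndarray = field(default_factory=lambda: np.empty(0))  # dF/F %
    pulse_times: np.ndarray = field(default_factory=lambda: np.empty(0))  # minutes
    pulse_amplitudes: np.ndarray = field(default_factory=lambda: np.empty(0))  # ng/ml
    min_event_gap: float = 300.0

    def __post_init__(self) -> None:
        self.se_times = np.asarray(self.se_times, dtype=float)
        self.se_amplitudes = np.asarray(self.se_amplitudes, dtype=float)
        self.pulse_times = np.asarray(self.pulse_times, dtype=float)
        self.pulse_amplitudes = np.asarray(self.pulse_amplitudes, dtype=float)
        for name, arr in (("se_times", self.se_times), ("pulse_times", self.pulse_times)):
            if arr.size > 1 and np.any(np.diff(arr) <= 0):
                raise ValueError(f"{name} must be strictly increasing")
        if self.se_times.size > 1 and np.any(
            np.diff(self.se_times) < self.min_event_gap - 1e-9
        ):
            raise ValueError("se_times violate min_event_gap")


# Per-state mean SE frequencies as reported (events/hour), with amplitude and
# baseline conventions.  Late-pregnancy and late-lactation states use the
# elevated-baseline mode (low-amplitude extra events + slow oscillation).
_PRESETS: dict[str, StatePreset] = {
    "nl_diestrus": StatePreset("nl_diestrus", 1.25, se_amplitude_mean=15.0),
    "preg_d4": StatePreset("preg_d4", 0.29, se_amplitude_mean=12.0),
    "preg_d14": StatePreset("preg_d14", 0.0, se_amplitude_mean=12.0),
    "preg_d18": StatePreset(
        "preg_d18",
        2.18,
        se_amplitude_mean=5.0,
        baseline_mode="elevated",
        baseline_osc_amp=2.0,
    ),
    "lact_d7": StatePreset("lact_d7", 0.0, se_amplitude_mean=12.0),
    "lact_d14": StatePreset("lact_d14", 0.58, se_amplitude_mean=10.0),
    "lact_d18": StatePreset(
        "lact_d18",
        0.85,
        se_amplitude_mean=12.0,
        baseline_mode="elevated",
        baseline_osc_amp=0.8,
    ),
    "postwean_24h": StatePreset("postwean_24h", 1.38, se_amplitude_mean=15.0),
    "postwean_diestrus": StatePreset("postwean_diestrus", 1.67, se_amplitude_mean=15.0),
    # OVX activity is genuinely clustered: a much shorter refractory
    "ovx": StatePreset("ovx", 4.78, se_amplitude_mean=25.0, min_event_gap=300.0),
}


def available_states() -> tuple[str, ...]:
    return STATE_ORDER


def build_preset(name: str, **overrides) -> StatePreset:
    """Return the registered preset for a reproductive state.

    Keyword overrides replace individual fields (e.g. ``coupling_prob``).
    """
    if name not in _PRESETS:
        raise ValueError(
            f"unknown state {name!r}; valid states: {', '.join(STATE_ORDER)}"
        )
    preset = _PRESETS[name]
    return replace(preset, **overrides) if overrides else preset


# --- event-time process -----------------------------------------------------

def draw_event_times(
    rng: np.random.Generator,
    rate_per_hr: float,
    duration_s: float,
    min_gap_s: float = 300.0,
) -> np.ndarray:
    """Stationary renewal process: gaps are ``min_gap + Exp(theta)`` with
    ``theta = 1/rate - min_gap`` so the mean rate equals ``rate_per_hr``.

    The first event is drawn from the equilibrium forward-recurrence
    distribution, making the expected count ``rate * duration`` exactly.
    """
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    if rate_per_hr < 0:
        raise ValueError("rate must be >= 0")
    if rate_per_hr == 0:
        return np.empty(0)
    mu = 3600.0 / rate_per_hr  # mean gap, seconds
    theta = mu - min_gap_s
    if theta <= 0:
        raise ValueError("rate too high for the refractory gap")
    # equilibrium forward recurrence: density S(x)/mu
    if rng.uniform() < min_gap_s / mu:
        first = rng.uniform(0.0, min_gap_s)
    else:
        first = min_gap_s + rng.exponential(theta)
    times = []
    t = first
    while t < duration_s:
        times.append(t)
        t += min_gap_s + rng.exponential(theta)
    return np.asarray(times)


def _se_kernel(t: np.ndarray, tau_rise: float = 5.0, tau_decay: float = 40.0) -> np.ndarray:
    """Two-exponential calcium transient, peak-normalised to 1 at its maximum."""
    w = np.where(t >= 0, np.exp(-np.maximum(t, 0) / tau_decay) - np.exp(-np.maximum(t, 0) / tau_rise), 0.0)
    t_peak = (np.log(tau_decay) - np.log(tau_rise)) * tau_rise * tau_decay / (tau_decay - tau_rise)
    peak = np.exp(-t_peak / tau_decay) - np.exp(-t_peak / tau_rise)
    return w / peak


def _lognormal(rng: np.random.Generator, mean: float, cv: float, size: int) -> np.ndarray:
    """Lognormal draws with the given arithmetic mean and CV."""
    if mean <= 0:
        raise ValueError("mean must be positive")
    sigma2 = np.log(1.0 + cv**2)
    mu = np.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, np.sqrt(sigma2), size=size)


def simulate_photometry(
    preset: StatePreset,
    duration_hr: float = 3.0,
    schedule: SchedulePattern | None = None,
    noise: NoiseModel | None = None,
    seed: int | np.random.SeedSequence | np.random.Generator = 0,
    animal_id: str = "synthetic",
) -> tuple[RawPhotometrySession, GroundTruth]:
    """Simulate a duty-cycled two-channel photometry session.

    SEs are injected into the 490 nm channel only; bleaching and motion are
    common to both channels.  Returns the retained (on-window) samples and
    the injected ground truth.
    """
    if duration_hr <= 0:
        raise ValueError("duration must be positive")
    schedule = schedule or SchedulePattern()
    noise = noise or NoiseModel()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    duration_s = duration_hr * 3600.0
    dt = 1.0 / schedule.rate_hz
    t_full = np.arange(0.0, duration_s, dt)

    se_times = draw_event_times(rng, preset.se_rate, duration_s, preset.min_event_gap)
    se_amps = (
        _lognormal(rng, preset.se_amplitude_mean, preset.se_amplitude_cv, se_times.size)
        if se_times.size
        else np.empty(0)
    )

    dff_true = np.zeros_like(t_full)  # fractional (not percent)
    for t0, a in zip(se_times, se_amps):
        dff_true += (a / 100.0) * _se_kernel(t_full - t0)

    if preset.baseline_mode == "elevated":
        # low-amplitude events at twice the SE rate (plain Poisson, they may
        # overlap) plus a slow baseline oscillation
        mini_rate = 2.0 * preset.se_rate if preset.se_rate > 0 else 2.0
        n_mini = rng.poisson(mini_rate * duration_hr)
        mini_times = np.sort(rng.uniform(0.0, duration_s, size=n_mini))
        mini_amps = _lognormal(
            rng, preset.se_amplitude_mean / 5.0, preset.se_amplitude_cv, n_mini
        )
        for t0, a in zip(mini_times, mini_amps):
            dff_true += (a / 100.0) * _se_kernel(t_full - t0)
        if preset.baseline_osc_amp > 0:
            phase = rng.uniform(0.0, 2.0 * np.pi)
            dff_true += (preset.baseline_osc_amp / 100.0) * np.sin(
                2.0 * np.pi * t_full / 600.0 + phase
            )

    b405, b490 = 1.0, 2.0  # channel baselines, a.u.
    bleach = (
        np.exp(-t_full / noise.bleach_tau) if noise.bleach_tau > 0 else np.ones_like(t_full)
    )
    if noise.motion_sd > 0:
        raw = rng.standard_normal(t_full.size)
        motion = gaussian_filter1d(raw, noise.motion_corr_s / dt)
        motion *= noise.motion_sd / max(np.std(motion), 1e-12)
    else:
        motion = np.zeros_like(t_full)

    f405 = b405 * bleach + 1.0 * motion + rng.normal(0.0, noise.white_sd_405, t_full.size)
    f490 = (
        b490 * bleach * (1.0 + dff_true)
        + (b490 / b405) * motion
        + rng.normal(0.0, noise.white_sd_490, t_full.size)
    )

    on_mask = (t_full % schedule.period_s) < schedule.on_s - dt / 2.0 + 1e-9
    session = RawPhotometrySession(
        t=t_full[on_mask],
        f405=f405[on_mask],
        f490=f490[on_mask],
        schedule=schedule,
        animal_id=animal_id,
        state=preset.name,
    )
    truth = GroundTruth(
        se_times=se_times, se_amplitudes=se_amps, min_event_gap=preset.min_event_gap
    )
    return session, truth


def _lh_sample_grid(
    duration_min: float, sample_interval: float, se_times_min: Iterable[float]
) -> np.ndarray:
    """6-min grid plus an extra sample 2 min after each SE whenever the next
    scheduled draw is more than 3 min away."""
    grid = list(np.arange(0.0, duration_min + 1e-9, sample_interval))
    extras = []
    for se in se_times_min:
        t_extra = se + 2.0
        if t_extra > duration_min:
            continue
        next_sched = np.ceil(se / sample_interval) * sample_interval
        if next_sched - se > 3.0:
            extras.append(t_extra)
    return np.unique(np.asarray(grid + extras))


def simulate_lh(
    truth: GroundTruth,
    preset: StatePreset,
    sample_interval: float = 6.0,
    duration_hr: float = 3.0,
    noise: NoiseModel | None = None,
    seed: int | np.random.SeedSequence | np.random.Generator = 0,
) -> tuple[LHSeries, GroundTruth]:
    """Simulate serial blood LH coupled to the injected SEs.

    Each SE triggers (with probability ``coupling_prob``) a secretory bolus
    delayed by a uniform draw from ``pulse_delay_range``; concentration is
    basal plus the superposition of boluses decaying with the LH half-life.
    Returns the censored, noisy series and the truth updated with bolus
    times.
    """
    if sample_interval <= 0:
        raise ValueError("sample_interval must be positive")
    if duration_hr <= 0:
        raise ValueError("duration must be positive")
    noise = noise or NoiseModel()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    duration_min = duration_hr * 60.0
    se_min = truth.se_times / 60.0

    pulse_times, pulse_amps = [], []
    lo, hi = preset.pulse_delay_range
    for se in se_min:
        if rng.uniform() <= preset.coupling_prob:
            delay = rng.uniform(lo, hi)
            pulse_times.append(se + delay)
            pulse_amps.append(
                _lognormal(rng, preset.lh_bolus_mean, 0.2, 1)[0]
                if preset.lh_bolus_mean > 0
                else 0.0
            )
    pulse_times = np.asarray(pulse_times)
    pulse_amps = np.asarray(pulse_amps)

    t = _lh_sample_grid(duration_min, sample_interval, se_min)
    conc = np.full(t.shape, preset.lh_basal)
    for tp, ap in zip(pulse_times, pulse_amps):
        decay = np.where(
            t >= tp, np.power(2.0, -(t - tp) / preset.lh_halflife), 0.0
        )
        conc = conc + ap * decay

    if noise.assay_cv > 0:
        conc = conc * (1.0 + (noise.assay_cv / 100.0) * rng.standard_normal(t.size))
    conc = np.clip(conc, noise.lod, noise.assay_cap)

    series = LHSeries(t=t, conc=conc, lod=noise.lod, assay_cap=noise.assay_cap)
    new_truth = replace(
        truth,
        pulse_times=pulse_times,
        pulse_amplitudes=pulse_amps,
    )
    return series, new_truth


def simulate_paired_session(
    preset: StatePreset,
    duration_hr: float = 3.0,
    schedule: SchedulePattern | None = None,
    noise: NoiseModel | None = None,
    seed: int | np.random.SeedSequence = 0,
    sample_interval: float = 6.0,
    animal_id: str = "synthetic",
) -> tuple[RawPhotometrySession, LHSeries, GroundTruth]:
    """Photometry session and the paired LH series from one seed."""
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    photometry_seed, lh_seed = ss.spawn(2)
    session, truth = simulate_photometry(
        preset,
        duration_hr,
        schedule,
        noise,
        np.random.default_rng(photometry_seed),
        animal_id=animal_id,
    )
    series, truth = simulate_lh(
        truth,
        preset,
        sample_interval,
        duration_hr,
        noise,
        np.random.default_rng(lh_seed),
    )
    return session, series, truth
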