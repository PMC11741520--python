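"""Synchronised-event detection, frequency, amplitude, baseline metrics."""

import numpy as np
import pytest

from kisspulse import (
    DffTrace,
    IsosbesticCorrector,
    baseline_metrics,
    build_preset,
    detect_events,
    event_frequency,
    relative_amplitude,
    simulate_photometry,
)


def make_trace(dff, dt=0.1):
    dff = np.asarray(dff, dtype=float)
    return DffTrace.from_values(t=np.arange(dff.size) * dt, dff=dff)


def _transient(n, peak_idx, amp, tau_rise=50, tau_decay=400):
    """Discrete two-exponential bump (indices as time)."""
    i = np.arange(n)
    x = np.where(
        i >= peak_idx - 120,
        np.exp(-np.maximum(i - peak_idx + 120, 0) / tau_decay)
        - np.exp(-np.maximum(i - peak_idx + 120, 0) / tau_rise),
        0.0,
    )
    return amp * x / x.max()


class TestDetection:
    def test_single_injected_transient_detected_once(self):
        rng = np.random.default_rng(0)
        noise = rng.normal(0, 0.1, 18000)
        dff = noise + _transient(18000, 9000, 10.0)  # peak ~ 10 SD above mean
        trace = make_trace(dff)
        events = detect_events(trace)
        assert len(events) == 1
        assert events[0].peak_t == pytest.approx(900.0, abs=30.0)

    def test_two_close_transients_merge(self):
        rng = np.random.default_rng(1)
        dff = rng.normal(0, 0.1, 18000)
        dff += _transient(18000, 9000, 10.0) + _transient(18000, 9100, 8.0)  # 10 s apart
        events = detect_events(make_trace(dff), min_separation=30.0)
        assert len(events) == 1
        assert events[0].peak_dff == pytest.approx(dff.max(), rel=0.05)

    def test_flat_trace_zero_events(self, flat_trace):
        assert detect_events(flat_trace) == []

    def test_noise_only_matches_bruteforce_run_scan(self):
        """False positives on pure noise equal an exhaustive run-length scan.

        Oracle: direct enumeration of maximal supra-threshold runs of at
        least the minimum length, with no merging (min_separation=0).
        """
        rng = np.random.default_rng(2)
        dff = rng.normal(0, 1.0, 108000)  # 3 h of retained samples at 10 Hz
        trace = make_trace(dff)
        min_duration = 2.0
        events = detect_events(trace, min_separation=0.0, min_duration=min_duration)

        thr = trace.trace_mean + 3 * trace.trace_sd
        above = dff > thr
        n_min = int(round(min_duration / 0.1))
        count = 0
        run = 0
        for a in above:
            if a:
                run += 1
            else:
                if run >= n_min:
                    count += 1
                run = 0
        if run >= n_min:
            count += 1
        assert len(events) == count

    def test_threshold_monotonicity(self):
        session, _ = simulate_photometry(build_preset("ovx"), 3.0, seed=21)
        trace = IsosbesticCorrector().fit_transform(session)
        counts = [len(detect_events(trace, k_sd=k)) for k in (1.0, 2.0, 3.0, 4.0, 6.0)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_min_duration_below_sampling_step_rejected(self, flat_trace):
        with pytest.raises(ValueError, match="sampling step"):
            detect_events(flat_trace, min_duration=0.01)

    def test_recovery_at_high_snr(self):
        """>= 95% of injected events recovered, <= 5% false positives."""
        inj = det = matched = 0
        for seed in range(12):
            session, truth = simulate_photometry(
                build_preset("nl_diestrus"), 3.0, seed=1000 + seed
            )
            trace = IsosbesticCorrector().fit_transform(session)
            events = detect_events(trace)
            peaks = np.array([e.peak_t for e in events])
            inj += truth.se_times.size
            det += len(events)
            for t0 in truth.se_times:
                if peaks.size and np.min(np.abs(peaks - (t0 + 12))) < 60:
                    matched += 1
        assert matched >= 0.95 * inj
        assert det - matched <= 0.05 * max(det, 1)


class TestFrequency:
    def test_three_events_in_two_hours(self):
        events = detect_events_on_spikes(3)
        summ = event_frequency(events, elapsed_hr=2.0)
        assert summ.freq_per_hr == pytest.approx(1.5)

    def test_zero_events(self):
        summ = event_frequency([], elapsed_hr=3.0)
        assert summ.freq_per_hr == 0.0
        assert np.isnan(summ.mean_rel_amplitude)

    def test_nonpositive_elapsed_rejected(self):
        with pytest.raises(ValueError):
            event_frequency([], elapsed_hr=0.0)

    def test_monte_carlo_rate_recovery(self):
        """Detected frequency across seeds within 3 SE of the preset rate."""
        freqs = []
        for seed in range(16):
            session, _ = simulate_photometry(
                build_preset("postwean_24h"), 3.0, seed=400 + seed
            )
            trace = IsosbesticCorrector().fit_transform(session)
            freqs.append(len(detect_events(trace)) / 3.0)
        mean = np.mean(freqs)
        sem = np.std(freqs, ddof=1) / np.sqrt(len(freqs))
        assert abs(mean - 1.38) < 3 * sem


def detect_events_on_spikes(n):
    """Helper: n well-separated obvious events on a noise floor."""
    rng = np.random.default_rng(3)
    dff = rng.normal(0, 0.1, 72000)
    for k in range(n):
        dff += _transient(72000, 12000 + 24000 * k, 10.0)
    return detect_events(make_trace(dff))


class TestRelativeAmplitude:
    def test_triangular_event(self):
        dff = np.full(4000, 0.1)
        dff[2000:2100] = np.linspace(0.1, 0.6, 100)
        dff[2100:2200] = np.linspace(0.6, 0.1, 100)
        trace = make_trace(dff)
        events = detect_events(trace, k_sd=3.0)
        assert len(events) == 1
        amps, mean = relative_amplitude(events, trace)
        assert mean == pytest.approx(0.5, abs=0.02)

    def test_empty_events(self, flat_trace):
        amps, mean = relative_amplitude([], flat_trace)
        assert amps == []
        assert np.isnan(mean)

    def test_event_outside_span_rejected(self, flat_trace):
        from kisspulse import SyncEvent

        ev = SyncEvent(onset_t=100.0, peak_t=100.0, end_t=100.0, peak_dff=1.0)
        with pytest.raises(ValueError, match="outside"):
            relative_amplitude([ev], flat_trace)

    def test_injected_amplitudes_recovered(self):
        """On normalised low-noise traces, recovered amplitudes are within
        10% of the injected values (the trace is normalised by its own max,
        so truth is amplitude / max-amplitude)."""
        from kisspulse import compute_norm_constant, normalize_dff

        session, truth = simulate_photometry(build_preset("nl_diestrus"), 3.0, seed=777)
        if truth.se_times.size < 2:
            pytest.skip("seed produced too few events to be informative")
        trace = IsosbesticCorrector().fit_transform(session)
        norm = compute_norm_constant([trace, trace, trace])
        ntrace = normalize_dff(trace, norm)
        events = detect_events(ntrace)
        amps, _ = relative_amplitude(events, ntrace)
        truth_norm = truth.se_amplitudes / norm.value
        assert len(amps) == truth.se_times.size
        np.testing.assert_allclose(sorted(amps), sorted(truth_norm), rtol=0.10)


class TestBaselineMetrics:
    def test_flat_zero_trace(self, flat_trace):
        m = baseline_metrics(flat_trace, [])
        assert m["median_dff"] == 0.0
        assert m["frac_above_1sd"] == 0.0

    def test_all_samples_inside_events_flagged(self, flat_trace):
        from kisspulse import SyncEvent

        ev = SyncEvent(onset_t=0.0, peak_t=30.0, end_t=60.0, peak_dff=1.0)
        m = baseline_metrics(flat_trace, [ev])
        assert m["empty"] is True

    def test_elevated_state_has_larger_baseline_fraction(self):
        """Paired seeds: elevated-baseline preset shows a strictly larger
        fraction of non-event samples above mean + 1 SD than the normal one."""
        for seed in range(6):
            fracs = {}
            for state in ("preg_d18", "nl_diestrus"):
                session, _ = simulate_photometry(build_preset(state), 3.0, seed=300 + seed)
                trace = IsosbesticCorrector().fit_transform(session)
                events = detect_events(trace)
                fracs[state] = baseline_metrics(trace, events)["frac_above_1sd"]
            assert fracs["preg_d18"] > fracs["nl_diestrus"]
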