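"""LH censoring, assay SD, baseline, run-criteria pulse detection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kisspulse import (
    LHSeries,
    PulsarDetector,
    PulsarParams,
    assay_sd,
    build_preset,
    censor_to_lod,
    detect_pulses,
    mean_lh,
    simulate_lh,
    simulate_photometry,
    smooth_baseline,
)
from kisspulse.pulsar import scaled_residuals


def make_lh(conc, interval=6.0):
    conc = np.asarray(conc, dtype=float)
    return LHSeries(t=np.arange(conc.size) * interval, conc=conc)


class TestCensoring:
    def test_below_lod_raised_to_lod(self):
        out = censor_to_lod(make_lh([0.01, 0.5, 5.0]))
        np.testing.assert_allclose(out.conc, [0.04, 0.5, 4.0])

    def test_negative_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            censor_to_lod(make_lh([-0.1, 0.5, 0.5]))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.0, 10.0), min_size=3, max_size=40))
    def test_idempotence(self, values):
        once = censor_to_lod(make_lh(values))
        twice = censor_to_lod(once)
        np.testing.assert_array_equal(once.conc, twice.conc)


class TestAssaySd:
    def test_reference_value_at_one(self):
        # (2.5 + 3.3) / 100 — identical under both conventions at 1 ng/ml
        assert assay_sd(1.0) == pytest.approx(0.058)
        assert assay_sd(1.0, convention="cv") == pytest.approx(0.058)

    def test_zero_concentration_floored(self):
        assert assay_sd(0.0) == 0.04

    def test_scaling_with_linear_coefficient_only(self):
        # SD polynomial doubles; the CV reading quadruples (SD = c1*y^2/100)
        lo = assay_sd(1.0, coeffs=(0, 2.5, 0), floor=1e-9)
        assert assay_sd(2.0, coeffs=(0, 2.5, 0), floor=1e-9) == pytest.approx(2 * lo)
        lo_cv = assay_sd(1.0, coeffs=(0, 2.5, 0), floor=1e-9, convention="cv")
        assert assay_sd(
            2.0, coeffs=(0, 2.5, 0), floor=1e-9, convention="cv"
        ) == pytest.approx(4 * lo_cv)


class TestBaseline:
    def test_constant_series(self):
        series = make_lh(np.full(31, 0.7))
        np.testing.assert_allclose(smooth_baseline(series), 0.7)

    def test_linear_ramp_interior(self):
        t = np.arange(0, 186, 6.0)
        ramp = 0.2 + 0.005 * t
        series = LHSeries(t=t, conc=ramp)
        base = smooth_baseline(series)
        interior = slice(8, -8)
        np.testing.assert_allclose(base[interior], ramp[interior], atol=0.02)

    def test_isolated_spike_downweighted(self):
        conc = np.full(31, 0.3)
        conc[15] = 2.0
        base = smooth_baseline(make_lh(conc))
        assert base[15] < 0.5  # spike excluded from its own baseline

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            smooth_baseline(make_lh([0.2, 0.2]))


class TestDetection:
    def test_flat_series_no_pulses(self):
        assert detect_pulses(make_lh(np.full(31, 0.2))) == []

    def test_single_point_pulse(self):
        conc = np.full(31, 0.2)
        conc[15] = 0.2 + 5 * assay_sd(0.2)  # 5 SD above basal, G(1) = 3.5
        pulses = detect_pulses(make_lh(conc))
        assert len(pulses) == 1
        assert pulses[0].run_length == 1
        assert pulses[0].peak_t == pytest.approx(90.0)

    def test_noiseless_injected_pulse_count(self):
        """Well-separated noiseless boluses: detected == injected, every seed."""
        from kisspulse.synth import NoiseModel

        preset = build_preset("nl_diestrus")
        noise = NoiseModel(assay_cv=0.0)
        for seed in range(8):
            _, truth = simulate_photometry(preset, 3.0, seed=200 + seed)
            lh, truth = simulate_lh(
                truth, preset, duration_hr=3.2, noise=noise, seed=seed
            )
            if truth.pulse_times.size == 0:
                continue
            pulses = detect_pulses(lh)
            assert len(pulses) == truth.pulse_times.size

    def test_agreement_with_run_enumeration_oracle(self):
        """Pulse count equals an exhaustive enumeration of qualifying runs.

        Oracle: test every window of length k = 1..5 for all residuals above
        G(k); overlapping qualifying windows collapse into one pulse region.
        Uses series without split-depth troughs so region counting is
        unambiguous.
        """
        params = PulsarParams()
        rng = np.random.default_rng(6)
        for _ in range(20):
            conc = 0.2 + np.abs(rng.normal(0, 0.05, 31))
            for k in rng.choice(np.arange(3, 28), size=2, replace=False):
                conc[k] += rng.uniform(0.5, 1.5)
            series = censor_to_lod(make_lh(conc))
            baseline = smooth_baseline(series, params=params)
            u = scaled_residuals(series, baseline, params)

            qualifying = np.zeros(u.size, dtype=bool)
            for k in range(1, 6):
                gk = params.criterion(k)
                for s in range(u.size - k + 1):
                    if np.all(u[s : s + k] > gk):
                        qualifying[s : s + k] = True
            # count maximal qualifying regions (merge if adjacent within the
            # same supra-G5 run)
            above = u > params.g[-1]
            regions = 0
            in_region = False
            for i in range(u.size):
                if qualifying[i] and not in_region:
                    regions += 1
                    in_region = True
                elif not above[i]:
                    in_region = False

            pulses = detect_pulses(series, params)
            # peak-splitting can only increase the count above the oracle's
            # region count; on these well-separated spikes it must not
            split_free = [p for p in pulses]
            assert len(split_free) == regions

    def test_g_scaling_monotonicity(self):
        _, truth = simulate_photometry(build_preset("nl_diestrus"), 3.0, seed=31)
        lh, _ = simulate_lh(truth, build_preset("nl_diestrus"), duration_hr=3.2, seed=31)
        counts = []
        for scale in (1.0, 1.5, 2.5, 4.0):
            params = PulsarParams(g=tuple(scale * g for g in (3.5, 2.6, 1.9, 1.5, 1.2)))
            counts.append(len(detect_pulses(censor_to_lod(lh), params)))
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_amplitude_positivity(self):
        for seed in range(6):
            _, truth = simulate_photometry(build_preset("nl_diestrus"), 3.0, seed=50 + seed)
            lh, _ = simulate_lh(
                truth, build_preset("nl_diestrus"), duration_hr=3.2, seed=seed
            )
            for p in detect_pulses(censor_to_lod(lh)):
                assert p.amplitude > 0

    def test_peak_split_separates_double_pulse(self):
        conc = np.full(31, 0.2)
        conc[10] = 1.8
        conc[11] = 1.0  # deep interior trough
        conc[12] = 2.0
        pulses = detect_pulses(make_lh(conc))
        assert len(pulses) == 2

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            detect_pulses(make_lh([0.2, 0.3]))

    def test_g6_indexing_selectable(self):
        p = PulsarParams(g_indexing="g6")
        assert p.criterion(5) == 1.5  # keeps the published gap: reuses G(4)
        assert p.criterion(6) == 1.2
        assert PulsarParams().criterion(5) == 1.2


class TestMeanLH:
    def test_simple_mean(self):
        assert mean_lh(make_lh([1.0, 2.0, 3.0])) == pytest.approx(2.0)

    def test_all_lod(self):
        assert mean_lh(make_lh(np.full(31, 0.04))) == pytest.approx(0.04)

    def test_matches_bruteforce(self):
        rng = np.random.default_rng(8)
        vals = rng.uniform(0.04, 4.0, 31)
        assert mean_lh(make_lh(vals)) == pytest.approx(vals.sum() / vals.size)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mean_lh(make_lh([]))


class TestDetectorEstimator:
    def test_fit_populates_attributes(self):
        _, truth = simulate_photometry(build_preset("nl_diestrus"), 3.0, seed=3)
        lh, _ = simulate_lh(truth, build_preset("nl_diestrus"), duration_hr=3.2, seed=3)
        det = PulsarDetector().fit(lh)
        assert hasattr(det, "pulses_")
        assert det.baseline_.shape == lh.t.shape
        assert det.mean_lh_ > 0

    def test_get_params_roundtrip(self):
        det = PulsarDetector(smoothing=0.5)
        params = det.get_params()
        assert params["smoothing"] == 0.5
        det.set_params(peak_split=3.0)
        assert det.peak_split == 3.0
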