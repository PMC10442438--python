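"""Unit and property tests for the dF/F + transient-detection chain."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import fiberphot as fp
from fiberphot.photometry import (DffTrace, PhotometrySession,
                                  sliding_median_mad, sliding_window_mean)

from conftest import make_trace
from oracles import detect_transients_loop, dff_loop, ols_closed_form


def make_session(f470, f405, rate=20.0):
    n = len(f470)
    return PhotometrySession(t=np.arange(n) / rate, f470=f470, f405=f405,
                             rate=rate)


class TestNormalize:
    def test_constant_trace_maps_to_zero(self):
        f = np.full(4000, 2.0)
        d470, d405 = fp.normalize_session(make_session(f, f), trim=60)
        assert np.all(d470.values == 0.0)
        assert np.all(d405.values == 0.0)

    def test_trim_length_arithmetic(self):
        n = 18000  # 900 s at 20 Hz
        f = np.full(n, 3.0)
        d470, _ = fp.normalize_session(make_session(f, f))
        assert len(d470) == 16800  # (900 - 60) * 20

    def test_matches_per_sample_loop_oracle(self):
        rate = 20.0
        t = np.arange(0, 200, 1 / rate)
        f = 1.0 + 0.1 * np.sin(2 * np.pi * 0.05 * t)
        sess = make_session(f, f + 0.5, rate)
        d470, d405 = fp.normalize_session(sess, trim=60, window=60)
        half = int(round(60 * rate / 2))
        keep = t - t[0] >= 60
        assert np.abs(d470.values - dff_loop(f[keep], half)).max() < 1e-10
        assert np.abs(d405.values - dff_loop((f + 0.5)[keep], half)).max() < 1e-10

    def test_scale_invariance(self, rng):
        f = 5.0 + rng.random(4000)
        s1 = make_session(f, f)
        s2 = make_session(3.7 * f, 3.7 * f)
        a, _ = fp.normalize_session(s1)
        b, _ = fp.normalize_session(s2)
        np.testing.assert_allclose(a.values, b.values, atol=1e-9)

    def test_slow_bleach_removed(self):
        sess, _ = fp.gen_photometry(duration=300, transient_rate=0.0,
                                    noise_sigma=0.0, bleach_tau=1000.0, seed=0)
        d470, _ = fp.normalize_session(sess)
        interior = d470.values[1200:-1200]  # away from one-sided edge windows
        assert np.abs(interior).max() < 0.1  # percent

    def test_nonpositive_fluorescence_rejected(self):
        f = np.full(4000, 1.0)
        bad = f.copy()
        bad[10] = 0.0
        with pytest.raises(fp.DataError):
            fp.normalize_session(make_session(bad, f))

    def test_too_short_recording_rejected(self):
        f = np.full(100, 1.0)
        with pytest.raises(fp.DataError):
            fp.normalize_session(make_session(f, f))


class TestSlidingPrimitives:
    def test_mean_matches_loop(self, rng):
        x = rng.normal(size=333)
        from oracles import sliding_mean_loop
        for half in (1, 7, 50, 400):
            np.testing.assert_allclose(sliding_window_mean(x, half),
                                       sliding_mean_loop(x, half), atol=1e-12)

    def test_median_mad_matches_loop_with_exclusion(self, rng):
        x = rng.normal(size=200)
        excl = rng.random(200) < 0.3
        med, mad = sliding_median_mad(x, 15, exclude=excl)
        for i in (0, 5, 99, 199):
            lo, hi = max(0, i - 15), min(200, i + 16)
            sel = x[lo:hi][~excl[lo:hi]]
            assert med[i] == np.median(sel)
            assert mad[i] == np.median(np.abs(sel - np.median(sel)))


class TestIsosbesticFit:
    def test_exact_affine_relation(self, rng):
        x = rng.normal(size=500)
        fit = fp.fit_isosbestic(make_trace(x), make_trace(2 * x + 0.1))
        assert fit.slope == pytest.approx(2.0, abs=1e-12)
        assert fit.intercept == pytest.approx(0.1, abs=1e-12)

    def test_identity(self, rng):
        x = rng.normal(size=500)
        fit = fp.fit_isosbestic(make_trace(x), make_trace(x.copy()))
        assert fit.slope == pytest.approx(1.0)
        assert fit.intercept == pytest.approx(0.0, abs=1e-12)

    def test_matches_closed_form_ols(self, rng):
        x = rng.normal(size=1000)
        y = 0.7 * x + rng.normal(size=1000)
        fit = fp.fit_isosbestic(make_trace(x), make_trace(y))
        slope, intercept = ols_closed_form(x, y)
        assert fit.slope == pytest.approx(slope, abs=1e-10)
        assert fit.intercept == pytest.approx(intercept, abs=1e-10)

    def test_zero_variance_rejected(self):
        with pytest.raises(fp.DegenerateFitError):
            fp.fit_isosbestic(make_trace(np.ones(100)),
                              make_trace(np.arange(100.0)))


class TestMotionCorrect:
    def test_perfect_fit_gives_zero(self, rng):
        x = rng.normal(size=300)
        tr = make_trace(x)
        fit = fp.fit_isosbestic(tr, tr)
        out = fp.motion_correct(tr, fit)
        np.testing.assert_allclose(out.values, 0.0, atol=1e-12)

    def test_exact_affine_artifact_removed(self):
        """A shared artifact entering both normalized channels affinely is
        removed perfectly: the corrected signal equals the calcium truth."""
        dff470, dff405, truth = fp.gen_shared_artifact_dff(n=8000, seed=3)
        fit = fp.fit_isosbestic(dff405, dff470)
        corrected = fp.motion_correct(dff470, fit)
        assert np.abs(corrected.values - truth).max() < 1e-6

    def test_raw_artifact_rms_improves(self):
        pulses = [(80.0, 2.0, 4.0), (150.0, 1.0, 3.0), (220.0, 2.5, 5.0)]
        sess, truth = fp.gen_photometry(duration=300, artifact=pulses,
                                        noise_sigma=0.2, seed=11)
        d470, d405 = fp.normalize_session(sess)
        gs = fp.motion_correct(d470, fp.fit_isosbestic(d405, d470))
        tdff = truth.clean_dff470()
        rmse_corr = np.sqrt(np.mean((gs.values - tdff.values) ** 2))
        rmse_unc = np.sqrt(np.mean((d470.values - tdff.values) ** 2))
        assert rmse_corr < rmse_unc


class TestBandpass:
    def test_dc_rejection(self):
        tr = make_trace(np.full(4000, 3.0))
        out = fp.bandpass_filter(tr)
        assert np.abs(out.values).max() < 1e-6

    def test_passband_and_stopband_gains(self):
        t = np.arange(0, 600, 0.05)
        in_band = fp.bandpass_filter(make_trace(np.sin(2 * np.pi * 1.0 * t)))
        assert 0.7 <= np.abs(in_band.values[2000:-2000]).max() <= 1.0
        low = fp.bandpass_filter(make_trace(np.sin(2 * np.pi * 0.01 * t)))
        assert np.abs(low.values[2000:-2000]).max() <= 0.1

    def test_cutoff_validation(self):
        tr = make_trace(np.zeros(100))
        with pytest.raises(fp.ParameterError):
            fp.bandpass_filter(tr, low=6.0, high=0.2)
        with pytest.raises(fp.ParameterError):
            fp.bandpass_filter(tr, low=0.2, high=15.0)


class TestDetectTransients:
    def test_flat_trace_yields_empty_degenerate(self):
        out = fp.detect_transients(make_trace(np.zeros(2000)))
        assert len(out) == 0 and out.degenerate

    def test_large_event_localized(self):
        """A kernel at 10x the noise SD is detected with the largest
        amplitude of all detections, within 100 ms of the kernel's true
        peak. (The MAD threshold adapts to the noise scale, so smaller
        noise excursions are also reported — by design of the method.)"""
        rng = np.random.default_rng(7)
        rate = 20.0
        t = np.arange(0, 300, 1 / rate)
        noise_sd = 0.1
        x = rng.normal(0, noise_sd, len(t))
        x += 10 * noise_sd * fp.calcium_kernel(t - 150.0, 0.05, 0.5)
        filt = fp.bandpass_filter(make_trace(x))
        out = fp.detect_transients(filt)
        t_peak = 0.05 * 0.5 / 0.45 * np.log(10)  # kernel peak delay
        assert len(out) >= 1
        best = out.peak_times[np.argmax(out.peak_amplitudes)]
        assert abs(best - (150.0 + t_peak)) <= 0.1

    def test_noise_free_session_f1(self):
        """With no measurement noise the full chain recovers the generated
        transient train with F1 >= 0.9 (losses only from Poisson events
        merging into one supra-threshold excursion)."""
        from oracles import f1_score
        sess, truth = fp.gen_photometry(duration=900, transient_rate=0.3,
                                        noise_sigma=0.0, seed=5)
        d470, d405 = fp.normalize_session(sess)
        gs = fp.motion_correct(d470, fp.fit_isosbestic(d405, d470))
        out = fp.detect_transients(fp.bandpass_filter(gs))
        t_peak = truth.kernel_rise * truth.kernel_decay / \
            (truth.kernel_decay - truth.kernel_rise) * \
            np.log(truth.kernel_decay / truth.kernel_rise)
        tt = truth.transient_times[truth.transient_times > 60] + t_peak
        assert f1_score(out.peak_times, tt, tol=0.1) >= 0.9

    @pytest.mark.parametrize("seed", range(25))
    def test_equals_explicit_loop_oracle(self, seed):
        r = np.random.default_rng(seed)
        x = r.normal(0, 1, 700)
        x[r.integers(50, 650, 6)] += r.uniform(3, 9, 6)
        tr = make_trace(x)
        out = fp.detect_transients(tr, mad_window=12.0)
        mine = np.round(out.peak_times * tr.rate).astype(int)
        np.testing.assert_array_equal(mine,
                                      detect_transients_loop(x, tr.rate,
                                                             window_s=12.0))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_oracle_equality_property(self, seed):
        r = np.random.default_rng(seed)
        x = r.normal(0, 1, 300)
        n_ev = int(r.integers(0, 6))
        if n_ev:
            x[r.integers(20, 280, n_ev)] += r.uniform(2, 10, n_ev)
        tr = make_trace(x)
        out = fp.detect_transients(tr, mad_window=8.0)
        mine = np.round(out.peak_times * tr.rate).astype(int)
        np.testing.assert_array_equal(mine,
                                      detect_transients_loop(x, tr.rate,
                                                             window_s=8.0))

    def test_noise_frequency_stable_with_length(self):
        """Transient count on pure noise grows with duration, but the rate
        estimate is stable (no more than 10% length bias, 5 vs 15 min)."""
        rates = []
        for dur in (300.0, 900.0):
            r = np.random.default_rng(99)
            x = r.normal(0, 1, int(dur * 20))
            filt = fp.bandpass_filter(make_trace(x))
            out = fp.detect_transients(filt)
            rates.append(len(out) / dur)
        assert abs(rates[1] - rates[0]) / rates[0] < 0.10


class TestZoneStats:
    def test_frequency_arithmetic(self, epm):
        from fiberphot.behavior import ZoneLabels
        labels = np.array(["open"] * 1200 + ["closed"] * 1200, dtype=object)
        zones = ZoneLabels(labels=labels, maze=epm, rate=20.0)
        ts = fp.TransientSet(peak_times=np.linspace(1, 59, 30),
                             peak_amplitudes=np.full(30, 2.0))
        st_ = fp.transient_zone_stats(ts, zones)
        assert st_.frequency_hz["open"] == pytest.approx(0.5)  # 30 / 60 s
        assert st_.frequency_hz["closed"] == 0.0
        assert st_.differential_hz == pytest.approx(0.5)
        assert st_.mean_amplitude_pct["open"] == pytest.approx(2.0)

    def test_zero_dwell_zone_flagged_undefined(self, epm):
        from fiberphot.behavior import ZoneLabels
        labels = np.array(["closed"] * 100, dtype=object)
        zones = ZoneLabels(labels=labels, maze=epm, rate=20.0)
        ts = fp.TransientSet(peak_times=np.array([1.0]),
                             peak_amplitudes=np.array([2.0]))
        st_ = fp.transient_zone_stats(ts, zones)
        assert "open" in st_.undefined_zones
        assert np.isnan(st_.frequency_hz["open"])
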