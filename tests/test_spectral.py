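"""Welch PSD, 1/f detrending, peak detection, pooled oscillation calling,
band power and frequency-distribution fitting, each against an independent
oracle (closed-form sine power, Parseval, brute-force peak enumeration,
sort-and-count percentile)."""

import numpy as np
import pytest

from calcispect import (
    DFFTrace,
    SpectralResult,
    band_power,
    detect_peaks,
    detrend_psd,
    fit_frequency_distribution,
    pool_and_call_oscillations,
    welch_psd,
)
from calcispect.spectral import analyze_traces, summarize_group

FS = 20.0


def _dff(x, fs=FS):
    x = np.asarray(x, float)
    return DFFTrace(dff=x, fs_hz=fs, baseline_F0=np.ones(x.size))


def _sine(a, f0, duration_s=60.0, fs=FS):
    t = np.arange(int(duration_s * fs)) / fs
    return a * np.sin(2 * np.pi * f0 * t)


class TestWelch:
    def test_sine_peak_location_and_power(self):
        """Closed form: a sine of amplitude A carries power A^2/2."""
        sr = welch_psd(_dff(_sine(0.4, 1.0)))
        f_peak = sr.freqs_hz[np.argmax(sr.psd)]
        assert abs(f_peak - 1.0) <= 0.125
        total = np.trapezoid(sr.psd, sr.freqs_hz)
        assert total == pytest.approx(0.4**2 / 2, rel=0.02)

    def test_zero_signal_zero_psd(self):
        sr = welch_psd(_dff(np.zeros(1200)))
        assert np.all(sr.psd == 0.0)

    def test_white_noise_parseval(self):
        """Integral of the PSD matches the sample variance (50 seeds)."""
        ratios = []
        for seed in range(50):
            x = np.random.default_rng(seed).standard_normal(1200)
            sr = welch_psd(_dff(x))
            ratios.append(np.trapezoid(sr.psd, sr.freqs_hz) / x.var())
        assert abs(np.mean(ratios) - 1.0) < 0.05

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            welch_psd(_dff(np.ones(100)))  # 5 s < one 8 s window

    def test_frequency_resolution(self):
        sr = welch_psd(_dff(np.zeros(1200)))
        assert sr.freqs_hz[1] - sr.freqs_hz[0] == pytest.approx(1 / 8.0)


def _grid(n=161, fmax=10.0):
    return np.linspace(0, fmax, n)  # df = 0.0625 Hz


class TestDetrend:
    def test_exact_power_law_detrends_to_zero(self):
        f = _grid()
        psd = np.zeros_like(f)
        psd[f > 0] = 2.0 * f[f > 0] ** -1.5
        sr = detrend_psd(SpectralResult(roi_id=0, freqs_hz=f, psd=psd))
        band = np.isfinite(sr.detrended_psd)
        np.testing.assert_allclose(sr.detrended_psd[band], 0.0, atol=1e-10)

    def test_power_law_plus_bump_argmax_at_bump(self):
        f = _grid()
        psd = np.zeros_like(f)
        psd[f > 0] = f[f > 0] ** -1.0
        psd += 5.0 * np.exp(-((f - 1.5) ** 2) / (2 * 0.05**2))
        sr = detrend_psd(SpectralResult(roi_id=0, freqs_hz=f, psd=psd))
        band = np.isfinite(sr.detrended_psd)
        f_max = f[band][np.argmax(sr.detrended_psd[band])]
        assert abs(f_max - 1.5) <= f[1] - f[0]

    def test_flat_psd_zero_slope(self):
        f = _grid()
        sr = detrend_psd(SpectralResult(roi_id=0, freqs_hz=f,
                                        psd=np.full_like(f, 3.0)))
        band = np.isfinite(sr.detrended_psd)
        np.testing.assert_allclose(sr.detrended_psd[band], 0.0, atol=1e-12)

    def test_out_of_band_is_nan_and_narrow_band_rejected(self):
        f = _grid()
        sr = detrend_psd(SpectralResult(roi_id=0, freqs_hz=f,
                                        psd=np.ones_like(f)))
        assert np.all(np.isnan(sr.detrended_psd[f < 0.2]))
        with pytest.raises(ValueError):
            detrend_psd(SpectralResult(roi_id=0, freqs_hz=f,
                                       psd=np.ones_like(f)),
                        fit_band=(5.0, 5.01))


class TestPeaks:
    def test_flat_detrended_no_peaks(self):
        f = _grid()
        sr = detrend_psd(SpectralResult(roi_id=0, freqs_hz=f,
                                        psd=np.ones_like(f)))
        assert detect_peaks(sr).peaks == []

    def test_tall_bump_single_peak(self):
        f = _grid()
        rng = np.random.default_rng(0)
        psd = np.zeros_like(f)
        psd[f > 0] = f[f > 0] ** -1.0 * np.exp(0.01 * rng.standard_normal((f > 0).sum()))
        psd += 1e4 * np.exp(-((f - 1.5) ** 2) / (2 * 0.05**2))
        sr = detect_peaks(detrend_psd(SpectralResult(roi_id=0, freqs_hz=f, psd=psd)))
        assert len(sr.peaks) == 1
        assert abs(sr.peaks[0][0] - 1.5) <= f[1] - f[0]

    def test_matches_brute_force_enumeration(self):
        """detect_peaks must agree with a direct loop over strict local
        maxima above 3 SD, on noisy spectra."""
        f = _grid()
        for seed in range(10):
            rng = np.random.default_rng(seed)
            psd = np.exp(rng.standard_normal(f.size))
            sr = detrend_psd(SpectralResult(roi_id=0, freqs_hz=f, psd=psd))
            got = detect_peaks(sr).peaks
            band = np.isfinite(sr.detrended_psd)
            d, fb = sr.detrended_psd[band], f[band]
            thr = 3.0 * d.std()
            expected = [
                (fb[i], d[i])
                for i in range(1, d.size - 1)
                if d[i] > d[i - 1] and d[i] > d[i + 1] and d[i] > thr
            ]
            assert [round(p[0], 9) for p in got] == [
                round(p[0], 9) for p in expected
            ]


def _result_with_peaks(roi_id, peaks):
    f = _grid()
    return SpectralResult(roi_id=roi_id, freqs_hz=f, psd=np.ones_like(f),
                          peaks=peaks)


class TestPooling:
    def test_empty_pool_all_negative(self):
        results = [_result_with_peaks(i, []) for i in range(5)]
        out = pool_and_call_oscillations(results)
        assert all(not r.has_significant_oscillation for r in out)
        assert all(r.oscillation_freq_hz is None for r in out)

    def test_sort_and_count_oracle_100_distinct_heights(self):
        """100 distinct heights, keep top 75%: cutoff is the 25th
        percentile and exactly 75 peaks survive."""
        heights = np.arange(1.0, 101.0)
        np.random.default_rng(0).shuffle(heights)
        results = [_result_with_peaks(i, [(1.0 + 0.01 * i, h)])
                   for i, h in enumerate(heights)]
        out = pool_and_call_oscillations(results, keep_top_percent=75.0)
        kept = [r for r in out if r.has_significant_oscillation]
        cutoff = np.percentile(heights, 25.0)
        assert len(kept) == sum(heights >= cutoff) == 75

    def test_single_peak_always_retained(self):
        out = pool_and_call_oscillations([_result_with_peaks(0, [(1.0, 0.1)])])
        assert out[0].has_significant_oscillation
        assert out[0].oscillation_freq_hz == 1.0

    def test_tallest_retained_peak_defines_frequency(self):
        results = [_result_with_peaks(0, [(1.0, 5.0), (2.0, 9.0)])]
        out = pool_and_call_oscillations(results)
        assert out[0].oscillation_freq_hz == 2.0


class TestBandPower:
    def test_zero_psd(self):
        f = _grid()
        sr = SpectralResult(roi_id=0, freqs_hz=f, psd=np.zeros_like(f))
        assert band_power(sr) == 0.0

    def test_unit_flat_psd_band_width(self):
        f = _grid()
        sr = SpectralResult(roi_id=0, freqs_hz=f, psd=np.ones_like(f))
        assert band_power(sr, band=(0.2, 3.0)) == pytest.approx(2.8)

    def test_sine_in_band_vs_out_of_band(self):
        a = 0.3
        in_band = band_power(welch_psd(_dff(_sine(a, 1.0))))
        out_band = band_power(welch_psd(_dff(_sine(a, 5.0))))
        assert in_band == pytest.approx(a**2 / 2, rel=0.05)
        assert out_band < 0.01 * in_band

    def test_band_outside_grid_rejected(self):
        f = _grid()
        sr = SpectralResult(roi_id=0, freqs_hz=f, psd=np.ones_like(f))
        with pytest.raises(ValueError):
            band_power(sr, band=(0.2, 30.0))


class TestFrequencyFit:
    def test_hand_computed_mean_and_population_sd(self):
        mean, sd = fit_frequency_distribution(np.array([0.5, 1.5, 2.5]))
        assert mean == pytest.approx(1.5)
        assert sd == pytest.approx(np.sqrt(2.0 / 3.0), abs=1e-9)  # 0.8165

    def test_degenerate_identical_samples(self):
        mean, sd = fit_frequency_distribution(np.array([1.0, 1.0, 1.0]))
        assert (mean, sd) == (1.0, 0.0)

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            fit_frequency_distribution(np.array([1.0]))

    def test_monte_carlo_recovery(self):
        rng = np.random.default_rng(42)
        samples = rng.normal(1.5, 0.4, 500)
        mean, sd = fit_frequency_distribution(samples)
        assert abs(mean - 1.5) < 0.06
        assert abs(sd - 0.4) < 0.06


class TestCohortProperties:
    def test_band_power_oscillatory_exceeds_silent(self, oscillatory_cohort):
        from calcispect import SimulationConfig, simulate_traces
        from calcispect.traces import process_traceset

        cfg, ts_osc, _ = oscillatory_cohort
        silent_cfg = SimulationConfig(
            n_rois=20, fraction_oscillatory=0.0, fraction_transient=0.0,
            n_frames=1200, aperiodic_amplitude=0.05, rng_seed=13,
        )
        ts_sil, _ = simulate_traces(silent_cfg)
        res_osc = analyze_traces(process_traceset(ts_osc)[:20])
        res_sil = analyze_traces(process_traceset(ts_sil))
        bp_osc = np.mean([r.band_power_0p2_3 for r in res_osc])
        bp_sil = np.mean([r.band_power_0p2_3 for r in res_sil])
        assert bp_osc > bp_sil

    def test_summary_counts_consistent(self, oscillatory_cohort):
        from calcispect.traces import process_traceset

        _, ts, _ = oscillatory_cohort
        res = analyze_traces(process_traceset(ts)[:30])
        summ = summarize_group(res, "cohort")
        assert 0 <= summ.n_oscillating <= summ.n_rois == 30
        assert summ.percent_oscillating == pytest.approx(
            100 * summ.n_oscillating / 30
        )
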