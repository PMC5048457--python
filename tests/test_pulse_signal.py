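import numpy as np
import pytest
from scipy import signal as sps
from scipy import stats

from pulsecam.errors import ConfigurationError
from pulsecam.preprocess import RegionGrid
from pulsecam.pulse_signal import (
    PulseConfig,
    WindowSpectrum,
    bandpass,
    estimate_pulse,
    min_window_frames,
    pulse_trace,
    sliding_spectra,
)
from pulsecam.segmentation import RegionSignal


def _tone(bpm, fps=30.0, seconds=60.0, amp=0.02, base=0.68):
    t = np.arange(int(fps * seconds)) / fps
    return base * (1 + amp * np.sin(2 * np.pi * bpm / 60.0 * t))


class TestMinWindowFrames:
    @pytest.mark.parametrize(
        "min_bpm,fps,expected",
        [(30, 30, 60), (60, 30, 30), (30, 1, 2), (45, 30, 40)],
    )
    def test_covers_one_period_of_the_slowest_pulse(self, min_bpm, fps, expected):
        assert min_window_frames(min_bpm, fps) == expected

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ConfigurationError):
            min_window_frames(0, 30)
        with pytest.raises(ConfigurationError):
            min_window_frames(30, -1)


class TestBandpass:
    def test_in_band_tone_passes(self):
        x = _tone(72)
        y = bandpass(x, 30.0).values
        assert y[200:-200].max() >= 0.9 * (x.max() - x.mean())

    def test_dc_rejected(self):
        y = bandpass(np.full(600, 0.7), 30.0).values
        assert np.abs(y).max() < 1e-6

    def test_below_band_tone_suppressed(self):
        x = _tone(12)
        y = bandpass(x, 30.0).values
        assert np.abs(y).max() < 0.1 * (x.max() - x.mean())

    def test_short_trace_error_names_minimum(self):
        with pytest.raises(ConfigurationError, match="frames"):
            bandpass(np.zeros(10), 30.0)

    def test_upper_edge_clamped_below_nyquist_with_warning(self):
        with pytest.warns(UserWarning, match="Nyquist"):
            filt = bandpass(_tone(72, fps=5.0, seconds=60), 5.0)
        assert filt.high_bpm < 5.0 / 2 * 60

    def test_zero_phase_no_group_delay(self):
        # a pulsatile burst keeps its peak position through the filter
        fps, n = 30.0, 900
        t = np.arange(n) / fps
        env = np.exp(-0.5 * ((t - 15.0) / 2.0) ** 2)
        x = env * np.sin(2 * np.pi * 1.2 * t)
        y = bandpass(x, fps).values
        peak_in = np.abs(sps.hilbert(x)).argmax()
        peak_out = np.abs(sps.hilbert(y)).argmax()
        assert abs(int(peak_in) - int(peak_out)) <= 1


class TestSlidingSpectra:
    def test_spectrum_count(self):
        filt = bandpass(_tone(72, seconds=20), 30.0)
        spectra = sliding_spectra(filt, window=60)
        assert len(spectra) == 600 - 60 + 1

    def test_tone_peaks_at_its_frequency(self):
        filt = bandpass(_tone(90, seconds=20), 30.0)
        for spec in sliding_spectra(filt, window=300, step=60):
            band = (spec.freqs_bpm >= 30) & (spec.freqs_bpm <= 180)
            peak = spec.freqs_bpm[band][spec.amplitude[band].argmax()]
            assert abs(peak - 90) <= 60.0 * 30 / 300  # one unpadded bin

    def test_zero_trace_gives_zero_spectra(self):
        filt = bandpass(np.full(300, 0.5), 30.0)
        spectra = sliding_spectra(filt, window=60, step=30)
        assert all(s.amplitude.max() < 1e-9 for s in spectra)

    def test_window_shorter_than_minimum_rejected(self):
        filt = bandpass(_tone(72, seconds=10), 30.0)
        with pytest.raises(ConfigurationError, match="minimum"):
            sliding_spectra(filt, window=30)

    def test_window_longer_than_trace_rejected(self):
        filt = bandpass(_tone(72, seconds=10), 30.0)
        with pytest.raises(ConfigurationError, match="exceeds"):
            sliding_spectra(filt, window=400)


def _spectrum(amplitudes, freqs=None, fps=30.0, window=60):
    amplitudes = np.asarray(amplitudes, float)
    if freqs is None:
        freqs = np.linspace(30, 180, amplitudes.size)
    return WindowSpectrum(np.asarray(freqs, float), amplitudes, 0, window, fps)


class TestEstimatePulse:
    def test_dominant_bin_with_low_noise_floor(self):
        freqs = np.arange(30, 181, 6.0)
        amps = np.full(freqs.size, 0.05)
        amps[freqs == 72] = 1.0
        est = estimate_pulse(_spectrum(amps, freqs))
        assert est.significant
        assert est.bpm == pytest.approx(72, abs=0.5)
        # the one-sample t test the rule reduces to must itself reject
        t, p = stats.ttest_1samp(amps[amps < 0.9], 1.0)
        assert p < 0.1

    def test_flat_spectrum_insignificant(self):
        est = estimate_pulse(_spectrum(np.ones(26)))
        assert not est.significant
        assert np.isnan(est.bpm)

    def test_two_near_maximal_bins_average(self):
        freqs = np.arange(30, 181, 2.0)
        amps = np.full(freqs.size, 0.02)
        amps[freqs == 70] = 0.95
        amps[freqs == 74] = 1.0
        est = estimate_pulse(_spectrum(amps, freqs))
        assert est.significant
        assert est.bpm == pytest.approx(72.0)

    def test_zero_spectrum_insignificant(self):
        est = estimate_pulse(_spectrum(np.zeros(26)))
        assert not est.significant

    def test_widening_band_enlarges_peak_group(self, rng):
        # the 90–100% band is a design point: lowering it to 50% must make
        # the peak group a strict superset on any fixed spectrum
        for _ in range(10):
            amps = rng.random(40)
            g90 = amps >= 0.9 * amps.max()
            g50 = amps >= 0.5 * amps.max()
            assert (g50 | g90).sum() == g50.sum()
            assert g50.sum() >= g90.sum()


class TestPulseTrace:
    def _region_signal(self, traces, fps=30.0, counts_value=5000):
        traces = np.atleast_2d(np.asarray(traces, float))
        counts = np.full(traces.shape, counts_value, np.int64)
        return RegionSignal(traces, counts, fps, RegionGrid(1, traces.shape[0]))

    def test_noiseless_tone_frequency_recovery(self):
        # |estimate − f| within 0.5 beats/min across the band
        for f in (45.0, 72.0, 120.0, 170.0):
            sig = self._region_signal(_tone(f, seconds=60))
            trace = pulse_trace(sig)[0]
            assert trace.significant.sum() > 0
            err = np.abs(trace.significant_values() - f)
            assert np.median(err) <= 0.5, f

    def test_off_bin_frequency_refined(self):
        sig = self._region_signal(_tone(71.37, seconds=60))
        trace = pulse_trace(sig)[0]
        assert abs(trace.median_bpm() - 71.37) <= 0.5

    def test_estimates_attributed_to_window_end(self):
        sig = self._region_signal(_tone(72, seconds=30))
        trace = pulse_trace(sig)[0]
        w = trace.window_frames
        assert np.isnan(trace.bpm[: w - 1]).all()
        assert not trace.significant[: w - 1].any()

    def test_noise_mostly_insignificant(self, rng):
        sig = self._region_signal(0.6 + 1e-4 * rng.standard_normal(1800))
        trace = pulse_trace(sig)[0]
        frac = trace.significant[trace.window_frames - 1 :].mean()
        assert frac < 0.5

    def test_unmeasurable_region_yields_sentinel_trace(self):
        sig = self._region_signal(_tone(72, seconds=30), counts_value=50)
        trace = pulse_trace(sig)[0]
        assert np.isnan(trace.bpm).all()
        assert not trace.significant.any()

    def test_error_non_increasing_with_window_length(self, rng):
        # longer analysis windows cannot make the median error worse
        x = _tone(77.3, seconds=90) + 2e-4 * rng.standard_normal(2700)
        errors = []
        for seconds in (5.0, 10.0, 20.0):
            cfg = PulseConfig(window_seconds=seconds)
            trace = pulse_trace(self._region_signal(x), cfg)[0]
            errors.append(np.median(np.abs(trace.significant_values() - 77.3)))
        assert errors[0] + 1e-9 >= errors[1] >= errors[2] - 0.05

    def test_rectangular_sixty_frame_mode_available(self):
        cfg = PulseConfig(window_seconds=2.0, pad_factor=1, window_fn="boxcar",
                          refine=False)
        sig = self._region_signal(_tone(120, seconds=30))
        trace = pulse_trace(sig, cfg)[0]
        # 60-frame rectangular bins are 30 bpm wide; 120 lies on a bin
        assert trace.median_bpm() == pytest.approx(120, abs=15)
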