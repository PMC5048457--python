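"""Pulse-rate estimation from region brightness traces.

Each region's mean-brightness trace is band-limited to the physiological
range (30–180 beats/min) with a zero-phase Butterworth filter and analysed
with a sliding-window FFT: for every window position the amplitude spectrum
is computed and a pulse reading is taken at the spectral peak.

Readings carry a statistical-significance flag built from three conditions.
Within a window's in-band spectrum, the bins whose amplitude reaches at
least 90 % of the maximum form the peak group; the remaining bins form the
background group.  (1) A Student's t test must find the two groups
different at p < 0.1 (a single-bin peak group is tested with the one-sample
variant against the peak amplitude).  (2) The peak group must be
frequency-coherent: a blurred spectrum spreads its near-maximum amplitudes
over distant frequencies, and such incoherent peak groups are rejected
(``max_peak_spread_bins``).  (3) The peak must be prominent: under the
no-signal null hypothesis the (response-whitened) in-band spectrum is the
envelope of band-limited Gaussian noise, and the observed maximum must be
improbably large (p < 0.1) for the noise scale estimated from the
background group, with the exceedance probability taken from the expected
number of envelope level crossings over the band (Rice formula).  The
third condition is what calibrates the false-alarm rate — on a signal-free
trace at most about one window in ten is flagged significant, by design.

The pulse value is the unweighted mean frequency of the peak group; a
single-bin group is refined to sub-bin precision by parabolic interpolation
across its neighbours.

A 60-frame window at 30 frames/s spaces the raw FFT bins 30 beats/min
apart, far coarser than the beats-per-minute accuracy the method aims at;
the default configuration therefore uses 10-second windows, a Hann taper
and ≥8× zero-padding, which together with the peak-group averaging bring
the quantization error well below 1 beat/min.  The literal 60-frame
rectangular-window configuration remains available
(``window_seconds=2, pad_factor=1, window_fn="boxcar"``).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
import scipy.fft as sfft
from numpy.lib.stride_tricks import sliding_window_view
from scipy import signal as sps
from scipy import stats

from .errors import ConfigurationError
from .segmentation import RegionSignal

__all__ = [
    "PulseConfig",
    "FilteredSignal",
    "WindowSpectrum",
    "PulseTrace",
    "PulseEstimate",
    "min_window_frames",
    "bandpass",
    "sliding_spectra",
    "estimate_pulse",
    "pulse_trace",
]

#: Spectra with peak amplitude below this are treated as numerically empty.
AMPLITUDE_FLOOR = 1e-12


@dataclass(frozen=True)
class PulseConfig:
    """Tunables of the signal-analysis stage.

    ``window_seconds`` is clamped from below by the slowest admissible pulse
    (one full period of ``low_bpm`` must fit the window) and from above by
    the trace length.  ``max_peak_spread_bins`` bounds, in units of the
    unpadded frequency resolution ``fps/window``, how far the ≥90 %
    amplitude group may spread around the peak and still count as one
    coherent spectral line.
    """

    low_bpm: float = 30.0
    high_bpm: float = 180.0
    filter_order: int = 4
    window_seconds: float = 10.0
    step: int = 1
    pad_factor: int = 8
    window_fn: str = "hann"
    significance_band: float = 0.90
    p_threshold: float = 0.10
    refine: bool = True
    max_peak_spread_bins: float = 2.0


@dataclass
class FilteredSignal:
    """Band-limited region trace (the L_f stage)."""

    values: np.ndarray
    fps: float
    low_bpm: float
    high_bpm: float
    sos: np.ndarray | None = None  # filter sections, for response whitening

    def response_at(self, freqs_bpm: np.ndarray) -> np.ndarray:
        """Squared magnitude (forward–backward) response at given frequencies."""
        if self.sos is None:
            return np.ones_like(freqs_bpm)
        _, h = sps.sosfreqz(self.sos, worN=freqs_bpm / 60.0, fs=self.fps)
        return np.abs(h) ** 2


@dataclass
class WindowSpectrum:
    """Amplitude spectrum of one sliding-window position."""

    freqs_bpm: np.ndarray
    amplitude: np.ndarray
    start: int
    window_length: int
    fps: float


class PulseEstimate(NamedTuple):
    """One spectral pulse reading: value, significance, diagnostics."""

    bpm: float
    significant: bool
    peak_ratio: float
    p_value: float


@dataclass
class PulseTrace:
    """Per-frame pulse readings for one region.

    Each sliding-window estimate is attributed to the window's last frame,
    so the trace is causal; frames without a significant reading (including
    the first ``window - 1`` frames) hold NaN.
    """

    region: int
    bpm: np.ndarray  # (I,) float, NaN where insignificant
    significant: np.ndarray  # (I,) bool
    peak_ratio: np.ndarray  # (I,) float
    fps: float
    window_frames: int

    def significant_values(self) -> np.ndarray:
        return self.bpm[self.significant]

    def median_bpm(self) -> float:
        v = self.significant_values()
        return float(np.median(v)) if v.size else float("nan")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame_index": np.arange(self.bpm.size),
                "region": self.region + 1,
                "pulse_bpm": self.bpm,
                "significant": self.significant,
                "peak_ratio": self.peak_ratio,
            }
        )


def min_window_frames(min_bpm: float, fps: float) -> int:
    """Fewest frames covering one full period of the slowest pulse.

    ``ceil(fps * 60 / min_bpm)``: at 30 frames/s and a 30 beats/min minimum
    this is the canonical 60-frame window.
    """
    if min_bpm <= 0 or fps <= 0:
        raise ConfigurationError(
            f"min_bpm and fps must be positive, got {min_bpm}, {fps}"
        )
    return int(math.ceil(fps * 60.0 / min_bpm - 1e-9))


def bandpass(
    trace,
    fps: float,
    low_bpm: float = 30.0,
    high_bpm: float = 180.0,
    order: int = 4,
) -> FilteredSignal:
    """Zero-phase Butterworth band-pass of a region trace.

    The mean is removed and the filter is applied forward and backward
    (no group delay).  When the upper band edge reaches the Nyquist
    frequency it is clamped just below it with a warning, so low-frame-rate
    recordings remain filterable.
    """
    x = np.asarray(trace, dtype=float)
    if isinstance(trace, FilteredSignal):
        x = np.asarray(trace.values, dtype=float)
    if x.ndim != 1:
        raise ConfigurationError(f"expected a 1-D trace, got shape {x.shape}")
    if np.isnan(x).any():
        raise ConfigurationError("trace contains NaN; region not measurable")
    if not 0 < low_bpm < high_bpm:
        raise ConfigurationError(
            f"need 0 < low_bpm < high_bpm, got {low_bpm}, {high_bpm}"
        )
    nyq_hz = fps / 2.0
    hi_hz = high_bpm / 60.0
    if hi_hz >= nyq_hz:
        hi_hz = 0.98 * nyq_hz
        warnings.warn(
            f"upper band edge {high_bpm} bpm is at or above Nyquist "
            f"({nyq_hz * 60:.1f} bpm); clamped to {hi_hz * 60:.1f} bpm",
            stacklevel=2,
        )
    lo_hz = low_bpm / 60.0
    if lo_hz >= hi_hz:
        raise ConfigurationError(
            f"pass band empty after Nyquist clamp: [{lo_hz}, {hi_hz}] Hz"
        )
    sos = sps.butter(order, [lo_hz, hi_hz], btype="bandpass", fs=fps, output="sos")
    padlen = 3 * (2 * sos.shape[0] + 1)
    if x.size <= padlen:
        raise ConfigurationError(
            f"trace of {x.size} frames is too short for the order-{order} "
            f"band-pass filter; need more than {padlen} frames"
        )
    y = sps.sosfiltfilt(sos, x - x.mean())
    return FilteredSignal(y, fps, low_bpm, min(high_bpm, hi_hz * 60.0), sos)


def _taper(window: int, window_fn: str) -> np.ndarray:
    try:
        return sps.get_window(window_fn, window, fftbins=True)
    except ValueError as exc:
        raise ConfigurationError(f"unknown window function {window_fn!r}") from exc


def _spectra_matrix(
    values: np.ndarray, fps: float, window: int, step: int,
    pad_factor: int, window_fn: str,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Amplitude spectra of all window positions: (starts, freqs_bpm, amps)."""
    nfft = sfft.next_fast_len(max(window, pad_factor * window))
    segs = sliding_window_view(values, window)[::step]
    amps = np.abs(sfft.rfft(segs * _taper(window, window_fn), n=nfft, axis=1))
    freqs_bpm = np.fft.rfftfreq(nfft, 1.0 / fps) * 60.0
    starts = np.arange(0, values.size - window + 1, step)
    return starts, freqs_bpm, amps


def sliding_spectra(
    filtered: FilteredSignal,
    window: int,
    step: int = 1,
    pad_factor: int = 8,
    window_fn: str = "hann",
) -> list[WindowSpectrum]:
    """Amplitude spectrum at every window position (shifted by ``step``).

    ``window`` may not be shorter than one period of the slowest admissible
    pulse and not longer than the trace.
    """
    if step < 1:
        raise ConfigurationError(f"step must be >= 1, got {step}")
    wmin = min_window_frames(filtered.low_bpm, filtered.fps)
    if window < wmin:
        raise ConfigurationError(
            f"window of {window} frames is shorter than the {wmin}-frame "
            f"minimum for {filtered.low_bpm} bpm at {filtered.fps} fps"
        )
    if window > filtered.values.size:
        raise ConfigurationError(
            f"window of {window} frames exceeds trace length "
            f"{filtered.values.size}"
        )
    starts, freqs, amps = _spectra_matrix(
        filtered.values, filtered.fps, window, step, pad_factor, window_fn
    )
    return [
        WindowSpectrum(freqs, amps[k], int(starts[k]), window, filtered.fps)
        for k in range(starts.size)
    ]


def _welch_two_sample_p(mA, vA, nA, mB, vB, nB):
    """Vectorized Welch two-sample t test p-values (two-sided)."""
    se2 = vA / nA + vB / nB
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (mA - mB) / np.sqrt(se2)
        df = se2**2 / ((vA / nA) ** 2 / (nA - 1) + (vB / nB) ** 2 / (nB - 1))
    p = np.where(
        se2 > 0,
        2.0 * stats.t.sf(np.abs(np.where(se2 > 0, t, 0.0)), np.where(se2 > 0, df, 1.0)),
        np.where(mA != mB, 0.0, 1.0),
    )
    return p


def _one_sample_p(m, v, n, ref):
    """Vectorized one-sample t test of a group mean against ``ref``."""
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m - ref) / np.sqrt(v / n)
    return np.where(
        v > 0,
        2.0 * stats.t.sf(np.abs(np.where(v > 0, t, 0.0)), n - 1),
        np.where(m != ref, 0.0, 1.0),
    )


def _estimate_batch(
    amps: np.ndarray,
    freqs_bpm: np.ndarray,
    config: PulseConfig,
    window: int,
    fps: float,
    response: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Peak-group pulse estimates for a stack of spectra.

    Returns ``(bpm, significant, peak_ratio, p_value)`` arrays over the
    stack.  Implements the 90–100 % amplitude grouping, the t-test
    significance rule, the coherence (peak-spread) gate, the prominence
    gate, and the peak-group mean / parabolic sub-bin refinement.
    ``response`` is the band-pass filter's squared magnitude response at
    ``freqs_bpm``; the prominence test whitens amplitudes by it so that the
    no-signal null has a flat in-band spectrum.
    """
    band = (freqs_bpm >= config.low_bpm) & (freqs_bpm <= config.high_bpm)
    fb = freqs_bpm[band]
    A = amps[:, band]
    resp_b = None if response is None else np.maximum(response[band], 1e-2)
    K, F = A.shape
    bpm = np.full(K, np.nan)
    sig = np.zeros(K, bool)
    p_out = np.full(K, np.nan)
    ratio = np.full(K, np.nan)
    if F == 0:
        return bpm, sig, ratio, p_out

    mx = A.max(axis=1)
    kmax = A.argmax(axis=1)
    nonzero = mx > AMPLITUDE_FLOOR
    in_peak = A >= config.significance_band * mx[:, None]
    nA = in_peak.sum(axis=1)
    nB = F - nA
    sumA = np.einsum("kf,kf->k", A, in_peak)
    sumsqA = np.einsum("kf,kf,kf->k", A, A, in_peak)
    sumAll = A.sum(axis=1)
    sumsqAll = np.einsum("kf,kf->k", A, A)
    with np.errstate(invalid="ignore", divide="ignore"):
        mA = sumA / nA
        mB = (sumAll - sumA) / nB
        vA = (sumsqA - nA * mA**2) / (nA - 1)
        vB = (sumsqAll - sumsqA - nB * mB**2) / (nB - 1)
        ratio = np.where(sumAll > 0, mx / (sumAll / F), np.nan)
    vA = np.maximum(vA, 0.0)
    vB = np.maximum(vB, 0.0)

    p = np.ones(K)
    both = (nA >= 2) & (nB >= 2)
    if both.any():
        p[both] = _welch_two_sample_p(
            mA[both], vA[both], nA[both], mB[both], vB[both], nB[both]
        )
    single_a = (nA == 1) & (nB >= 2)
    if single_a.any():
        p[single_a] = _one_sample_p(
            mB[single_a], vB[single_a], nB[single_a], mx[single_a]
        )
    single_b = (nB == 1) & (nA >= 2)
    if single_b.any():
        p[single_b] = _one_sample_p(
            mA[single_b], vA[single_b], nA[single_b],
            (sumAll - sumA)[single_b],
        )
    p_out = p

    # coherence gate: the peak group must hug the spectral peak.  A spread
    # wider than a pure tone's main lobe marks a blurred (noise) spectrum.
    df_bpm = fb[1] - fb[0] if F > 1 else np.inf
    spread_limit = config.max_peak_spread_bins * (fps / window) * 60.0
    idx = np.arange(F)
    lo_f = np.where(in_peak, idx, F).min(axis=1)
    hi_f = np.where(in_peak, idx, -1).max(axis=1)
    spread_bpm = (hi_f - lo_f) * df_bpm
    compact = spread_bpm <= spread_limit + 1e-9

    # prominence gate: survival probability of the observed spectral maximum
    # under the no-signal null.  Amplitudes are whitened by the filter
    # response so the null is a flat (Rayleigh-envelope) spectrum; its scale
    # is estimated from the background group's mean power (E[A²] = 2σ²).
    # The spectrum is an oversampled smooth envelope, so the exceedance
    # probability uses the expected number of level upcrossings over the
    # band (Rice formula, ≈ n_indep·sqrt(πz)·e^(−z)) rather than a count of
    # discrete independent bins.
    n_indep = max(int(round((fb[-1] - fb[0]) / ((fps / window) * 60.0))) + 1, 1)
    Aw = A if resp_b is None else A / resp_b[None, :]
    mxw = Aw.max(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        pow_bw = np.einsum("kf,kf,kf->k", Aw, Aw, ~in_peak) / nB
        z = mxw**2 / pow_bw  # = mxw² / (2 σ̂²)
        rate = n_indep * np.sqrt(np.maximum(np.pi * z, 0.0)) * np.exp(
            -np.minimum(z, 700.0)
        )
    p_peak = np.where(
        (pow_bw > 0) & np.isfinite(z),
        -np.expm1(-rate),
        np.where(mx > 0, 0.0, 1.0),
    )

    sig = (
        nonzero
        & (nB > 0)
        & compact
        & (p < config.p_threshold)
        & (p_peak < config.p_threshold)
    )

    many = nA >= 2
    with np.errstate(invalid="ignore"):
        bpm[many] = (np.where(in_peak, fb[None, :], 0.0).sum(axis=1) / nA)[many]
    one = nA == 1
    if one.any():
        k = kmax.copy()
        bpm[one] = fb[k[one]]
        if config.refine and F >= 3:
            interior = one & (k > 0) & (k < F - 1)
            if interior.any():
                ki = k[interior]
                rows = np.nonzero(interior)[0]
                am1, a0, ap1 = A[rows, ki - 1], A[rows, ki], A[rows, ki + 1]
                denom = am1 - 2 * a0 + ap1
                with np.errstate(invalid="ignore", divide="ignore"):
                    delta = 0.5 * (am1 - ap1) / denom
                ok = np.isfinite(delta) & (np.abs(delta) <= 1.0)
                bpm[rows[ok]] = fb[ki[ok]] + delta[ok] * df_bpm
    bpm[~sig] = np.nan
    return bpm, sig, ratio, p_out


def estimate_pulse(
    spectrum: WindowSpectrum,
    significance_band: float = 0.90,
    p_threshold: float = 0.10,
    low_bpm: float = 30.0,
    high_bpm: float = 180.0,
    refine: bool = True,
    max_peak_spread_bins: float = 2.0,
) -> PulseEstimate:
    """Pulse reading from one window spectrum (see module docstring).

    The spectrum is restricted to the pass band; bins at or above
    ``significance_band`` of the maximum form the peak group, the rest the
    background group, and the reading is significant when the groups differ
    (t test, ``p < p_threshold``), the peak group is frequency-coherent, and
    the spectrum is not numerically empty.  Insignificant readings return
    NaN as the sentinel value.
    """
    cfg = PulseConfig(
        low_bpm=low_bpm,
        high_bpm=high_bpm,
        significance_band=significance_band,
        p_threshold=p_threshold,
        refine=refine,
        max_peak_spread_bins=max_peak_spread_bins,
    )
    bpm, sig, ratio, p = _estimate_batch(
        spectrum.amplitude[None, :],
        spectrum.freqs_bpm,
        cfg,
        spectrum.window_length,
        spectrum.fps,
    )
    return PulseEstimate(float(bpm[0]), bool(sig[0]), float(ratio[0]), float(p[0]))


def _window_for(config: PulseConfig, fps: float, n_frames: int) -> int:
    wmin = min_window_frames(config.low_bpm, fps)
    window = max(int(round(config.window_seconds * fps)), wmin)
    if window > n_frames:
        window = n_frames
        if window < wmin:
            raise ConfigurationError(
                f"trace of {n_frames} frames is shorter than the "
                f"{wmin}-frame minimum window"
            )
        warnings.warn(
            f"window clamped to the trace length ({n_frames} frames)",
            stacklevel=3,
        )
    return window


def pulse_trace(
    region_signal: RegionSignal, config: PulseConfig = PulseConfig()
) -> list[PulseTrace]:
    """End-to-end spectral analysis of every region trace.

    Band-pass, sliding spectra, and the significance-gated peak estimate per
    window; each estimate is attributed to its window's last frame.
    Unmeasurable regions (too few skin pixels) yield an all-NaN trace.
    """
    traces = []
    I = region_signal.n_frames
    fps = region_signal.fps
    for r in range(region_signal.n_regions):
        nan_trace = PulseTrace(
            r, np.full(I, np.nan), np.zeros(I, bool), np.full(I, np.nan),
            fps, 0,
        )
        if not region_signal.measurable[r]:
            traces.append(nan_trace)
            continue
        filt = bandpass(
            region_signal.traces[r], fps,
            config.low_bpm, config.high_bpm, config.filter_order,
        )
        window = _window_for(config, fps, I)
        starts, freqs, amps = _spectra_matrix(
            filt.values, fps, window, config.step,
            config.pad_factor, config.window_fn,
        )
        bpm_w, sig_w, ratio_w, _ = _estimate_batch(
            amps, freqs, config, window, fps, response=filt.response_at(freqs)
        )
        trace = replace_frames(nan_trace, starts + window - 1, bpm_w, sig_w, ratio_w)
        trace.window_frames = window
        traces.append(trace)
    return traces


def replace_frames(
    trace: PulseTrace,
    frame_idx: np.ndarray,
    bpm: np.ndarray,
    significant: np.ndarray,
    peak_ratio: np.ndarray,
) -> PulseTrace:
    """Scatter window estimates onto their end frames of a trace."""
    trace.bpm[frame_idx] = bpm
    trace.significant[frame_idx] = significant
    trace.peak_ratio[frame_idx] = peak_ratio
    return trace
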