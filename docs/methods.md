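# Methods

`pulsecam` measures the blood pulse rate from ordinary colour video of
skin.  Cardiac blood-volume pulsation modulates the light remitted by
skin, most visibly in the red channel; at consumer-camera noise levels the
modulation is far below single-pixel noise but becomes measurable after
spatial averaging over thousands of skin pixels.  The pipeline therefore
(1) cleans and stabilizes the frames, (2) segments skin and averages its
red-channel brightness per region, and (3) finds the dominant in-band
spectral line of each region trace over a sliding window.

## Pre-processing

**Median filtering.**  Every frame is filtered per channel with a 9×9
median mask, sized so that impulse-noise clusters of up to 4 pixels (the
largest a webcam sensor typically produces) are removed entirely.  Borders
are edge-replicated.  For brightness on the camera's native 8-bit grid the
filter runs as a sliding-histogram (Huang) kernel that reproduces
`scipy.ndimage.median_filter` bit for bit at a fraction of the cost; data
off the 8-bit grid falls back to the scipy route.

**Stabilization.**  The subject drifts by a few pixels over a recording.
Each frame is divided into a 4×4 grid of 16 equal regions; each region's
per-channel Canny edge map is correlated against the corresponding region
of the first frame over all integer shifts within ±10 px (exhaustive
search, implemented as FFT correlation with precomputed reference-frame
statistics).  The correlation score is the zero-mean normalized
cross-correlation over a constant-size overlap (the current region inset
by the search range), averaged over channels; ties break toward the
smallest shift, then row-major order.  Regions with empty edge maps are
uninformative and excluded.

The per-region shifts are combined into one global offset as a *robust*
mean: only regions within 1 px of the per-axis median shift are averaged,
and the result is rounded half away from zero.  A plain mean was tried
first and proved wrong: a region whose only edge content is a smooth
ellipse arc can match itself under a wrong shift with a *perfect*
correlation score of 1.0 (the aperture problem), and a single such region
biases the rounded mean by a pixel even on noiseless input.  With the
robust mean, the stabilizer recovers pure integer translations and
noiseless jitter paths exactly, which the test suite asserts.  Frames
where all 16 regions are uninformative inherit the previous offset with a
logged warning.  The correction is one global translation per frame
(edge-replicated borders), not a local warp: the face moves as a whole.

**Edge detection.**  Canny with Gaussian-derivative gradients (σ = 1.0),
direction-quantized non-maximum suppression, and hysteresis whose high
threshold is the 90th percentile of the channel's gradient-magnitude
distribution (low = 0.4·high).  The detector is an in-package compiled
kernel for throughput; tests cross-check its step-edge localization
against `skimage.feature.canny`.

## Segmentation and region signals

Skin pixels satisfy three two-threshold range tests simultaneously,
`p1 < v ≤ p2` per channel, with the Caucasian brightness ranges
R ∈ (0.59, 0.78], G, B ∈ (0.48, 0.63] as defaults (all configurable; a
multi-level Otsu mode derives the red thresholds from the first frame
instead).  The lower comparison is strict, the upper inclusive.  The mask
is recomputed per frame, so segmentation follows the stabilized content.

The masked frame is divided into a 2×4 grid of 8 regions — the regions
may belong to one face or to several people — and each region's mean
red-channel brightness over its *skin pixels* is one sample of the trace
L_r(i).  Dividing by the skin-pixel count rather than the full region
area makes the trace invariant to how much of the region the skin covers;
the literal masked-sum-over-area convention is available as
`strict_area_denominator=True`, but with partial coverage it scales the
signal by the coverage fraction and couples mask jitter into the
spectrum, so coverage-invariant is the default.  A region needs at least
100 skin pixels in every frame to be measurable at all; below that no
measurement is attempted.

## Spectral pulse estimation

Each measurable trace is mean-removed and band-passed to the
physiological range 30–180 beats/min with a zero-phase order-4
Butterworth filter (applied forward–backward, so no group delay; the
upper edge is clamped just below Nyquist for low frame rates).  A window
slides over the filtered trace one frame at a time; each position yields
an amplitude spectrum and one pulse reading attributed to the window's
last frame (causal).

**Window and resolution.**  The window may not be shorter than one period
of the slowest admissible pulse — `ceil(fps·60/30)` frames, the canonical
60 frames at 30 fps.  A 60-frame raw FFT spaces bins 30 beats/min apart,
so the default configuration uses 10-second windows, a Hann taper, and
zero-padding to ≥8× the window, and refines further below the bin width
(next paragraph).  The literal 60-frame rectangular configuration remains
available (`window_seconds=2, pad_factor=1, window_fn="boxcar"`).

**Reading and significance.**  Within the in-band spectrum, bins at
≥ 90 % of the maximum amplitude form the *peak group*; the rest the
*background group*.  The reading is the unweighted mean frequency of the
peak group — for a symmetric main lobe this interpolates the true
frequency well below the bin width — or, for a single-bin group,
parabolic interpolation across the peak's neighbours.  Significance is
the conjunction of three conditions:

1. *Group separation*: Welch's t test between the two groups' amplitudes
   at p < 0.1 (one-sample variant against the peak amplitude when a group
   has a single member).
2. *Coherence*: the peak group must span at most 2 unpadded bin widths —
   a blurred spectrum scatters near-maximum amplitudes across distant
   frequencies and is rejected.
3. *Prominence*: under the no-signal null the response-whitened in-band
   spectrum is the envelope of band-limited Gaussian noise; the observed
   maximum must be improbable (p < 0.1) given the noise scale estimated
   from the background group's mean power, with the exceedance
   probability from the expected number of envelope level crossings
   (Rice formula) rather than a count of independent bins, because the
   zero-padded spectrum is a smooth oversampled envelope.

The first condition alone is scale-invariant and flags almost any
spectrum with a maximum; measured on band-passed noise it passes 60–78 %
of windows.  The prominence condition is what calibrates the false-alarm
rate: on signal-free traces the measured rate is ≈ 4 % at the 0.1
threshold (30 seeds), while clean tones pass with p ≈ 1e−13.  Frames
without a significant reading carry NaN and are excluded from all error
statistics.

## Evaluation

The error metric is δ = |estimate − reference| per frame, summarized by
its median and maximum over significant frames.  Agreement with a
reference device is assessed by Bland–Altman analysis: differences,
pairwise means, and limits mean ± 1.96·σ where σ is the *sample* standard
deviation of the differences (n−1), the Bland–Altman convention.  Sweep
runners re-run the whole pipeline over grids of spatial resolution and
(frame rate × pulse frequency); every cell records its seed and replicate
count.  Cells where the pulse frequency reaches the Nyquist limit of the
frame rate are reported "aliased" and not run — an aliased reading would
be an artifact, not a measurement.

## Synthetic scenes

The simulator generates the statistical structure the pipeline assumes,
not photorealistic faces: an elliptical skin patch with base colour
inside the segmentation ranges whose red channel is
`base_R·(1 + A·w(2πft))·flicker(t)`; a static speckle texture (σ = 0.015,
clipped at ±0.04) that keeps every pixel inside the segmentation ranges
while giving the edge detector structure to lock onto; per-pixel Gaussian
sensor noise plus ≤4-px impulse clusters; 8-bit quantization; global
integer-jitter random walk; and multiplicative lighting flicker at 100 Hz
(twice the 50 Hz mains) with per-source depth presets — LED 0.05,
fluorescent 0.10, incandescent 0.005, daylight 0.  Flicker at 100 Hz
aliases under a ≤50 fps camera, reproducing the interference between
light source and camera rate without modelling driver electronics.  All
randomness flows through one seeded generator in a fixed draw order, so
batch rendering and constant-memory streaming are bit-identical.

Reference study conditions (`pulsecam.benchmarks`): 240×320 px frames at
30 fps, an ellipse with 100/130 px semi-axes (≈41,000 skin pixels), pulse
72 beats/min, modulation amplitude A = 0.03 of the red base, noise
σ = 0.005, jitter steps ±1 px clamped to ±2 px, daylight; 60 s
recordings (120 s for frame-rate sweeps).  The modulation amplitude is a
free simulator parameter — no physiological amplitude is claimed — chosen
so that the per-pixel modulation (≈0.02) sits well below the per-pixel
noise yet is recoverable by spatial averaging, which is the regime the
method targets.  Downscaled sweep variants are requantized to 8 bits
after area averaging, as a camera delivering that resolution would.

What passing these tests shows — and what it does not.  The synthetic
scenes have exactly the structure the pipeline assumes: skin colour
strictly inside the thresholds, stationary sinusoidal pulse, integer
jitter, known flicker.  Real faces add specular highlights, non-rigid
motion, heart-rate variability, shadows and colour casts that the
simulator deliberately omits; accuracy numbers measured here bound the
method's behaviour under its own assumptions, not its clinical
performance.

## Numerical choices and limitations

* Area-averaging downscaling is exact for fractional ratios (overlap
  weight matrices); spectra and filters use float64, frames float32.
* Amplitude spectra below 1e−12 are treated as numerically empty
  (insignificant) — an exactly constant scene yields no readings rather
  than noise-driven ones.
* The stabilizer searches translations only; rotation, scale and
  sub-pixel motion are out of scope, and the search range adapts
  downward on frames too small to support ±10 px with ≥50 % overlap
  (below that, stabilization is skipped with a warning).
* Problem sizes in the shipped tests and the acceptance script are
  desk-scale: 60–120 s recordings at ≤ 240×320 px, 1–5 seeds per
  condition — enough for the medians to stabilize while a full run stays
  in the minutes range on one core.
* At 1 fps the whole pass band lies above Nyquist; such cells are
  reported "aliased" rather than given a value.
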