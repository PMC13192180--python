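# Methods

This note documents the models, parameter choices and numerical
conventions behind the package, and what the synthetic-data validation
does and does not establish about real recordings and images.

## LFP processing

Offline analysis operates on 5-min segments of the local field
potential (sampled at 10 kHz in the emulated acquisition).  Segments
are filtered with a 4th-order low-pass Butterworth at a 200 Hz corner,
applied forward–backward (`sosfiltfilt`) so transients keep their
timing; the effective magnitude response is the squared single-pass
response, |H(f)|² = 1 / (1 + (f/200)⁸).  The filter order is a
conventional choice: only the corner frequency is part of the
established protocol.

The PSD is estimated with Welch's method: Hamming window of 8192
samples, 50% overlap, per-segment mean removal, density scaling
(mV²/Hz).  At f_s = 10 kHz this yields the characteristic bin spacing
f_s/8192 = 1.220703125 Hz.  A power-of-two window is the natural
reading of the protocol because it reproduces that printed bin spacing
exactly.  The 50% overlap is the standard Welch default; overlap does
not shift the peak frequency, which is what classification consumes.
The spectral peak is the argmax over a 1–200 Hz search band (below
1 Hz, slow drift dominates; above 200 Hz the filter has removed
signal); ties break to the lowest frequency.

### State classification

A segment is assigned one of four states with precedence
NoActivity > Bursts > Gamma > LowActivity:

* **NoActivity** — RMS below `silence_rms` (default 2 µV·RMS expressed
  as 0.002 mV, a generous noise-floor bound for the emulated chain);
* **Bursts** — at least `min_burst_events` (default 3 per 5-min
  segment) detected transients *and* a crest factor (max |v| / RMS) of
  at least 4.  The crest-factor condition distinguishes recurrent
  transients over a quiet background from continuous oscillations: a
  clean sinusoid has crest ≈ 1.4–2.5, while isolated bursts reach ≫ 4.
  Without it, a prominence-based detector run on a continuous gamma
  segment reports its largest cycles as "events" and the precedence
  order would misclassify gamma as bursting;
* **Gamma** — peak frequency strictly above 23 Hz *and* peak power at
  least 10⁻⁴ mV²/Hz;
* **LowActivity** — everything else.

The Gamma thresholds are the protocol's printed constants; the
silence, event-count and crest parameters operationalize states that
were scored visually in the original workflow and are exposed in
`ClassifyThresholds`.

### Burst detection

Burst timepoints are local maxima of the rectified filtered trace with
prominence at least 85% of the maximum peak prominence in the segment,
separated by a 200 ms refractory interval.  Reading the 85% cutoff as
a *fraction of the maximum prominence* makes detection invariant to
amplitude rescaling and to sign flips (rectification), consistent with
the normalization used elsewhere in the analysis.  The refractory
default merges the many cycles within one transient into a single
event; it is configurable for other burst morphologies.

### Burst-triggered wavelet average

The continuous wavelet transform uses the analytic Morlet wavelet with
center-frequency parameter ω₀ = 6 (expressed as the complex Morlet
`cmor2.0-0.9549` so the envelope is exp(−t²/2)).  The default grid is
120 log-spaced frequencies over 0.25–200 Hz; analyses of slower burst
rhythms can pass a grid extending lower, bounded by 1/duration.  The
trace is decimated to 1 kHz beforehand (the grid tops out at 200 Hz,
well under the decimated Nyquist), and the transform is evaluated one
scale at a time so memory stays proportional to the trace length.
Magnitude columns are sampled at the detected burst timepoints,
averaged, and normalized to the maximum; events falling within two
envelope standard deviations (2·f_c/f) of either edge are excluded at
that frequency (cone of influence).  For rhythmic bursting the average
shows one peak at the inter-burst rate and one at the intra-burst
frequency; peak extraction takes the most prominent local maxima.

### Suppression time and Fisher's exact test

`suppression_time` slides a Welch window (default 30 s every 10 s)
and reports the first onset from which the in-band (23–70 Hz) peak
power stays below threshold for two consecutive windows — the analysis
used to time activity loss after drug wash-in.

`fisher_exact_2x2` conditions on both margins and sums hypergeometric
probabilities of tables at most as probable as the observed one (the
two-sided convention of the common statistics packages, with a 1+1e-7
relative tolerance against floating-point ties).  It is verified
exhaustively against a `math.comb` enumeration oracle for all tables
with margins ≤ 10.  Condition comparisons collapse a condition × state
table to "state vs not-state" per condition pair and report raw
per-pair p-values (the original analysis reports per-pair tests
without a multiplicity correction).

## Intracellular analysis

AP detection anchors on voltage peaks (prominence ≥ 10 mV) and walks
back along the dV/dt ≥ 20 mV/ms run leading into the peak; the run's
first sample is the threshold point.  A rate-of-rise criterion is
preferred over an absolute voltage because the resting potential
shifts under cytokine exposure.  The threshold voltage is taken from a
linear fit of the five pre-onset samples extrapolated to the onset —
exact for ramp-like approaches and robust to single-sample noise.
Amplitude is peak minus threshold; half-width is measured at
threshold + amplitude/2 with linear interpolation of the level
crossings; the mAHP is threshold minus the post-peak minimum before
the next AP (window capped at 50 ms), and a train's last AP
contributes a mAHP only when that window ends before the step offset.
The sAHP is the pre-stimulus mean potential minus the post-step
minimum within 1 s.  Input resistance is the steady-state deflection
(last quarter of a −0.2 nA, 200 ms pulse) over the current, in MΩ.

## Image analysis

### Counting

Per the automated macro sequence: maximum-intensity z-projection;
rolling-ball background subtraction on Iba1 (radius 50 px; the ball is
run on a 4×-downscaled copy and the background resized back, the
standard speedup for a slowly varying background); DAPI binarized with
the default-dark iterative-intermeans threshold; the DAPI mask clears
Iba1 signal without a nucleus; the remaining Iba1 is binarized
(default dark), despeckled (3×3 median), outlier-filtered (bright
pixels deviating > 50 units from the radius-2 median), and connected
components of at least 400 px are counted.  The 400 px cutoff (at the
native 0.31 µm/px scan ≈ 38 µm²) is treated as a *minimum* area: its
purpose is to drop small regions where foreign nuclei colocalize with
mere ramifications rather than somata.  Density = count × (1000 /
ROI side in µm)², exactly ×25 for the 200 µm ROI.

### Morphometry

Somata are localized by colocalizing DAPI and Iba1 (pixelwise
minimum), binarizing with the minimum-dark threshold, and taking
component centroids as nuclear centers; the Iba1 channel is grayscale
area-opened (99 px) to emphasize somata over processes, thresholded
(default: 0.75 of the filtered maximum, standing in for the macro's
interactive soma threshold; an absolute value can be passed), and
components under 300 px dropped.  A guard rejects the degenerate case
where the "soma" mask covers more than a quarter of the frame (no
somatic structure).  Territories come from a marker-controlled
watershed on the inverted, σ = 1 px Gaussian-smoothed Iba1 intensity,
restricted to the somata dilated by 100 px (disk radius, computed via
a Euclidean distance transform).  Within each territory the Iba1
signal is unsharp-masked (radius 2, amount 1), median-despeckled,
closed (disk 2), max-entropy (Kapur) thresholded over the territory's
own histogram, reconstructed from the component containing the soma
center, and thinned to a 1-px skeleton.

Sholl profiles sample concentric circles (default step 5 µm) around
the nuclear colocalization center at ≥ 3 samples per pixel of
circumference; one crossing is one maximal run of skeleton pixels
along the circle (the skeleton is dilated by one pixel for the
membership test so diagonal steps are not missed), which avoids
double-counting thick diagonal steps.  The per-cell area under the
Sholl curve (trapezoidal) summarizes arbor complexity.

Pixel-denominated defaults (400 / 300 / 99 / 100 px) correspond to the
0.31 µm/px acquisition; callers at other scales pass rescaled values.

## Assays

Standard curves are ordinary least-squares polynomial fits (degree 1
or 2) of OD against concentration, after optional reference-wavelength
subtraction (450 − 540 nm).  `fit_kind='auto'` selects the quadratic
only when it reduces the residual sum of squares by more than 20%.
Inversion is closed-form for linear fits; for quadratics the real root
inside the calibrated concentration range is taken and the call fails
loudly when both or neither root is in range.  ODs outside the
calibrated range raise unless extrapolation is requested.  LDH
activity uses the endpoint formula nmol / (min × mL); a kinetic
maximal-slope variant is deliberately not implemented.

## Synthetic data: what it emulates, and what it does not

* **LFP.**  Gamma is a sinusoid with 0.1 Hz, ±20% amplitude modulation
  over 1/f-power background noise — chosen over narrowband-filtered
  noise so the true peak frequency is unambiguous for recovery tests.
  Bursts are Gaussian-windowed oscillation packets (default FWHM
  100 ms, amplitude 10× the noise floor — the amplitude calibration of
  visually scored bursts is not specified anywhere, so the 10× ratio
  is this package's choice) riding on a slower field deflection (0.6×
  amplitude) whose width scales with the inter-burst interval; the
  slow component gives the event train genuine low-frequency energy at
  the burst rate, as real LFP bursts have, and keeps its harmonics
  weak.  Events are periodic with ±10% uniform jitter and a
  refractory gap of twice the burst width.  Default 300 s duration at
  10 kHz matches the 5-min analysis segments.
* **Intracellular.**  APs are piecewise-linear waveforms with
  grid-snapped knots, engineered so that every measured parameter
  (threshold, amplitude, half-width, mAHP, sAHP, ohmic deflection) is
  exactly the specified value under the module's measurement
  definitions.  Regular firing spaces spikes evenly (rate = 100 Hz/nA
  above a 0.1 nA rheobase, so a 0.5 nA/200 ms step yields 8 APs);
  bursting fires a 4-spike cluster at 8 ms ISIs and then slows with
  exponentially growing ISIs (rate constant 2 s⁻¹), ending in a slow
  AHP.  These are measurement fixtures, not conductance-based models:
  they validate the measurement code, not neuronal biophysics.
* **Images.**  Microglia are soma disks (6 µm radius) with radial
  two-segment branches over nuclear disks, plus bystander nuclei at
  1000 /mm²; phenotypes rescale branch length (de-ramified ×0.4,
  hypertrophic ×1.3 with a ×1.25 soma).  Rendering applies a Gaussian
  PSF approximation and additive Gaussian noise.  Branch graphs are
  stored in µm so Sholl expectations are analytic.  Real confocal
  stacks have out-of-focus light, intensity inhomogeneity and touching
  cells that these fixtures do not reproduce; passing tests establish
  correctness of the pipeline's geometry and thresholds, not
  field-ready segmentation accuracy.
* **Plates.**  ODs are generated from a declared monotone curve plus
  Gaussian read noise, with the standard series included.

All generators draw exclusively from one `numpy` Generator seeded per
spec; identical spec + seed is bit-identical.

## Problem sizes and tolerances

Validation uses 300-s LFP fixtures (3 × 10⁶ samples), 2.2-s
intracellular traces at 20 kHz, and 200–220 µm image fields at
0.31 µm/px (≈ 650–710 px square) — sizes chosen so the full suite
and the reproduction script each run in minutes on one core while
keeping every printed constant (bin spacing, thresholds, ROI scaling)
at its native value.  Counting accuracy is validated to ≤ 10% error
over 20 fields of 5–50 cells with up to 10% noise; burst recovery to
≥ 95% recall within ±25 ms and wavelet peaks within 20% over rates
0.2–1 Hz × intra-burst 60–150 Hz; noiseless intracellular recovery to
0.5 mV / 0.05 ms (with 0.5 mV noise: 1 mV / 0.2 ms on per-cell
medians).

## Known limitations

* The burst-subtype labels use an explicit quantitative surrogate
  (median inter-event interval ≤ 5 s and mean intra-event dominant
  frequency ≥ 50 Hz for type 1); the original taxonomy was visual.
* Marker-controlled watershed territories depend on the soma threshold
  stand-in; heavily overlapping microglia are merged with a warning
  rather than split.
* No line-noise or artifact rejection is applied to LFP segments.
* The assay module covers linear/quadratic curves only; four-parameter
  logistic immunoassay fits are out of scope.
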