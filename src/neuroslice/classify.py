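"""Network-state classification and burst analysis of LFP segments.

Implements the offline decision rules used on 5-min LFP segments:

* **Gamma** — Welch peak frequency above 23 Hz AND peak power at least
  1e-4 mV^2/Hz;
* **LowActivity** — a spectral peak below either threshold;
* **Bursts** — recurrent high-amplitude transients, found as local
  maxima of the rectified trace whose prominence reaches 85% of the
  largest prominence in the segment;
* **NoActivity** — segment RMS below a silence criterion.

Burst transients are characterized by averaging continuous-wavelet
(analytic Morlet) magnitude columns at the detected burst timepoints;
the averaged spectrum is normalized to its maximum, so during rhythmic
bursting it shows one peak at the inter-burst rate and one at the
intra-burst oscillation frequency.

Since "Bursts" and "No activity" were scored visually in the original
workflow, the thresholds that operationalize them here (minimum event
count, crest factor, silence RMS) are explicit, configurable parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt
from scipy import signal, stats

from .spectral import SpectralPeak, welch_psd, find_spectral_peak
from .trace import Trace

__all__ = [
    "BurstEvent",
    "StateCall",
    "WaveletSpectrum",
    "ClassifyThresholds",
    "detect_bursts",
    "classify_state",
    "burst_triggered_wavelet",
    "suppression_time",
    "fisher_exact_2x2",
    "classify_burst_subtype",
]

#: Analytic Morlet (omega0 = 6) expressed as a pywt complex Morlet:
#: bandwidth B = 2 gives the exp(-t^2/2) envelope, C = 6/(2*pi) the carrier.
MORLET_WAVELET = "cmor2.0-0.9549296585513721"


@dataclass(frozen=True)
class BurstEvent:
    time_s: float
    prominence: float
    peak_amp: float


@dataclass(frozen=True)
class StateCall:
    state: str  # Gamma | LowActivity | Bursts | NoActivity
    peak: SpectralPeak | None
    burst_events: tuple[BurstEvent, ...] = ()
    burst_subtype: int | None = None
    evidence: dict = field(default_factory=dict)


@dataclass(frozen=True)
class WaveletSpectrum:
    freqs: np.ndarray  # Hz, log-spaced, increasing
    magnitude: np.ndarray  # normalized to max = 1
    n_events: int


@dataclass(frozen=True)
class ClassifyThresholds:
    """Operational thresholds of the state classifier.

    ``gamma_freq_min`` and ``power_min`` are the printed classification
    constants; the remaining fields operationalize the visually scored
    states.  ``burst_crest_min`` demands that counted transients stand
    clear of the background (peak amplitude over segment RMS): without
    it a continuous oscillation, whose every cycle is a local maximum
    near the global one, would satisfy a purely prominence-based burst
    criterion.
    """

    gamma_freq_min: float = 23.0  # Hz
    power_min: float = 1e-4  # mV^2/Hz
    silence_rms: float = 2e-3  # mV
    min_burst_events: int = 3  # per 5-min segment
    burst_crest_min: float = 4.0


def detect_bursts(
    trace: Trace,
    prominence_frac: float = 0.85,
    refractory_s: float = 0.2,
) -> list[BurstEvent]:
    """Find burst timepoints on the rectified (low-pass filtered) trace.

    Local maxima of ``|v|`` separated by at least ``refractory_s`` whose
    prominence is at least ``prominence_frac`` times the largest peak
    prominence in the segment.  The fractional cutoff makes the
    criterion amplitude-scale-free, and rectification makes it invariant
    to a sign flip of the trace.
    """
    rect = np.abs(trace.samples)
    if not np.any(rect > 0):
        return []
    distance = max(1, int(round(refractory_s * trace.fs)))
    peaks, props = signal.find_peaks(rect, distance=distance, prominence=1e-30)
    if peaks.size == 0:
        return []
    prom = props["prominences"]
    keep = prom >= prominence_frac * prom.max()
    return [
        BurstEvent(
            time_s=trace.t0 + p / trace.fs,
            prominence=float(pr),
            peak_amp=float(rect[p]),
        )
        for p, pr in zip(peaks[keep], prom[keep])
    ]


def classify_state(
    trace: Trace,
    psd_peak: SpectralPeak,
    bursts: list[BurstEvent] | None = None,
    thresholds: ClassifyThresholds = ClassifyThresholds(),
) -> StateCall:
    """Classify a 5-min segment into one of the four network states.

    Precedence: NoActivity > Bursts > Gamma > LowActivity.  The PSD peak
    must come from the same segment as ``trace``.
    """
    if psd_peak is None:
        raise ValueError("classification requires the segment's PSD peak")
    bursts = list(bursts) if bursts is not None else []
    rms = float(np.sqrt(np.mean(trace.samples**2)))
    crest = float(np.max(np.abs(trace.samples)) / rms) if rms > 0 else 0.0
    evidence = {"rms_mv": rms, "crest_factor": crest, "n_bursts": len(bursts)}

    if rms < thresholds.silence_rms:
        return StateCall("NoActivity", psd_peak, tuple(bursts), evidence=evidence)
    if len(bursts) >= thresholds.min_burst_events and crest >= thresholds.burst_crest_min:
        subtype = classify_burst_subtype(bursts, trace)
        return StateCall("Bursts", psd_peak, tuple(bursts), burst_subtype=subtype, evidence=evidence)
    if psd_peak.peak_freq > thresholds.gamma_freq_min and psd_peak.peak_power >= thresholds.power_min:
        return StateCall("Gamma", psd_peak, (), evidence=evidence)
    return StateCall("LowActivity", psd_peak, (), evidence=evidence)


def _morlet_magnitude_at(
    samples: np.ndarray, fs: float, freqs: np.ndarray, indices: np.ndarray
) -> np.ndarray:
    """|CWT| columns at ``indices``, one scale at a time (memory-bounded).

    Cone-of-influence handling: events closer than two envelope standard
    deviations to either edge are excluded at that frequency.
    """
    wavelet = pywt.ContinuousWavelet(MORLET_WAVELET)
    fc = pywt.central_frequency(wavelet)
    dt = 1.0 / fs
    n = samples.size
    out = np.full((freqs.size, indices.size), np.nan)
    for i, f in enumerate(freqs):
        scale = fc / (f * dt)
        coef, _ = pywt.cwt(samples, [scale], wavelet, sampling_period=dt, method="fft")
        mag = np.abs(coef[0])
        coi = 2.0 * fc / f  # seconds; envelope sigma is fc/f for this wavelet
        coi_n = int(np.ceil(coi * fs))
        ok = (indices >= coi_n) & (indices < n - coi_n)
        out[i, ok] = mag[indices[ok]]
    return out


def burst_triggered_wavelet(
    trace: Trace,
    events: list[BurstEvent],
    freq_grid: np.ndarray | None = None,
    max_fs: float = 1000.0,
) -> WaveletSpectrum:
    """Average Morlet CWT magnitude at the burst timepoints.

    Default frequency grid: 120 log-spaced frequencies over 0.25-200 Hz.
    The trace is decimated to at most ``max_fs`` (the grid stays well
    below that Nyquist) before the transform.  The averaged spectrum is
    normalized to its maximum.
    """
    if not events:
        raise ValueError("burst-triggered averaging requires at least one event")
    if freq_grid is None:
        freq_grid = np.logspace(np.log10(0.25), np.log10(200.0), 120)
    freq_grid = np.asarray(freq_grid, dtype=float)
    if freq_grid.max() >= trace.fs / 2 or freq_grid.min() <= 1.0 / trace.duration:
        raise ValueError("frequency grid outside (1/duration, fs/2)")

    samples, fs = trace.samples, trace.fs
    factor = int(fs // max_fs)
    if factor > 1:
        samples = signal.decimate(samples, factor, ftype="fir", zero_phase=True)
        fs = fs / factor
    idx = np.array([int(round((e.time_s - trace.t0) * fs)) for e in events])
    idx = idx[(idx >= 0) & (idx < samples.size)]
    mags = _morlet_magnitude_at(samples, fs, freq_grid, idx)
    with np.errstate(invalid="ignore"):
        avg = np.nanmean(mags, axis=1)
    avg = np.nan_to_num(avg, nan=0.0)
    m = avg.max()
    if m > 0:
        avg = avg / m
    return WaveletSpectrum(freqs=freq_grid, magnitude=avg, n_events=len(idx))


def wavelet_spectrum_peaks(spectrum: WaveletSpectrum, n: int = 2) -> list[float]:
    """Frequencies of the ``n`` most prominent local maxima of the spectrum."""
    peaks, props = signal.find_peaks(spectrum.magnitude, prominence=0.0)
    if peaks.size == 0:
        return [float(spectrum.freqs[np.argmax(spectrum.magnitude)])]
    order = np.argsort(props["prominences"])[::-1][:n]
    return [float(spectrum.freqs[p]) for p in np.sort(peaks[order])]


def suppression_time(
    trace: Trace,
    band: tuple[float, float] = (23.0, 70.0),
    power_min: float = 1e-4,
    window_s: float = 30.0,
    step_s: float = 10.0,
) -> float | None:
    """Time (s, from trace start) at which band activity stays suppressed.

    Sliding Welch windows of ``window_s`` every ``step_s``; returns the
    first window onset from which the band peak power stays below
    ``power_min`` for at least two consecutive windows, or None if the
    activity never stays suppressed.
    """
    if band[1] >= trace.fs / 2:
        raise ValueError("band outside Nyquist range")
    if trace.duration <= window_s:
        raise ValueError("trace shorter than one analysis window")
    win_n = int(round(window_s * trace.fs))
    nperseg = min(8192, win_n)
    onsets = np.arange(0.0, trace.duration - window_s + 1e-9, step_s)
    below = []
    for onset in onsets:
        i0 = int(round(onset * trace.fs))
        seg = Trace(trace.samples[i0 : i0 + win_n], trace.fs, trace.t0 + onset)
        psd = welch_psd(seg, window_len_samples=nperseg)
        peak = find_spectral_peak(psd, band=band)
        below.append(peak.peak_power < power_min)
    for i in range(len(below) - 1):
        if below[i] and below[i + 1]:
            return float(onsets[i])
    return None


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher's exact p-value for a 2x2 contingency table.

    Conditions on both margins and sums the hypergeometric probabilities
    of all tables at most as probable as the observed one (the
    convention of the common statistics packages).  Returns p in (0, 1].
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        if np.any(t != np.round(t)) or np.any(t < 0):
            raise ValueError("table entries must be non-negative integers")
        t = t.astype(int)
    a, b = int(t[0, 0]), int(t[0, 1])
    c, d = int(t[1, 0]), int(t[1, 1])
    n = a + b + c + d
    if n == 0:
        return 1.0
    r1, c1 = a + b, a + c
    rv = stats.hypergeom(n, c1, r1)
    support = np.arange(max(0, r1 + c1 - n), min(r1, c1) + 1)
    probs = rv.pmf(support)
    p_obs = rv.pmf(a)
    p = float(probs[probs <= p_obs * (1 + 1e-7)].sum())
    return min(p, 1.0)


def classify_burst_subtype(events: list[BurstEvent], trace: Trace) -> int | None:
    """Heuristic bursting subtype from rate and intra-burst frequency.

    Subtype 1: rhythmic fast bursting (median inter-event interval at
    most 5 s AND mean intra-event dominant frequency at least 50 Hz);
    subtype 2 otherwise.  Returns None when fewer than two events exist
    (undetermined).
    """
    if len(events) < 2:
        return None
    times = np.array([e.time_s for e in events])
    med_iei = float(np.median(np.diff(np.sort(times))))
    # dominant frequency inside a +/-100 ms window around each event
    half = int(round(0.1 * trace.fs))
    freqs = []
    for e in events:
        i = int(round((e.time_s - trace.t0) * trace.fs))
        seg = trace.samples[max(0, i - half) : i + half]
        if seg.size < 16:
            continue
        seg = seg - seg.mean()
        spec = np.abs(np.fft.rfft(seg * np.hanning(seg.size))) ** 2
        f = np.fft.rfftfreq(seg.size, 1.0 / trace.fs)
        sel = f >= 10.0  # ignore the envelope's own low-frequency content
        if spec[sel].max() <= 0:
            continue
        freqs.append(f[sel][np.argmax(spec[sel])])
    mean_f = float(np.mean(freqs)) if freqs else 0.0
    return 1 if (med_iei <= 5.0 and mean_f >= 50.0) else 2
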