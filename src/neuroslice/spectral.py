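"""LFP segmentation, filtering and Welch spectral analysis.

The offline processing chain for extracellular recordings: cut a 5-min
analysis segment from the ~40-min recording, low-pass the local field
potential at 200 Hz with a zero-phase Butterworth filter, estimate the
one-sided power spectral density with Welch's method using a Hamming
window of 8192 points (fs = 10 kHz gives the 1.2207 Hz bin spacing of
the original analysis), and extract the peak power and peak frequency
used for network-state classification.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .trace import Trace

__all__ = [
    "PSDResult",
    "SpectralPeak",
    "extract_segment",
    "lowpass_butterworth",
    "welch_psd",
    "find_spectral_peak",
]

#: Default Welch window length in samples; 10 kHz / 8192 = 1.2207 Hz bins.
DEFAULT_WINDOW_LEN = 8192
#: Default low-pass corner frequency (Hz).
DEFAULT_CORNER_HZ = 200.0
#: Default peak-search band (Hz): above DC drift, below the filter corner.
DEFAULT_BAND = (1.0, 200.0)


@dataclass(frozen=True)
class PSDResult:
    """One-sided Welch power spectral density in mV^2/Hz."""

    freqs: np.ndarray
    power: np.ndarray
    bin_hz: float
    window: str
    window_len: int
    overlap_frac: float

    def __post_init__(self) -> None:
        freqs = np.asarray(self.freqs, dtype=float)
        power = np.asarray(self.power, dtype=float)
        if freqs.ndim != 1 or freqs.shape != power.shape:
            raise ValueError("freqs and power must be matching 1-D arrays")
        df = np.diff(freqs)
        if np.any(df <= 0) or not np.allclose(df, df[0], rtol=1e-9):
            raise ValueError("frequency grid must be strictly increasing and uniform")
        if np.any(power < 0):
            raise ValueError("power spectral density must be non-negative")
        object.__setattr__(self, "freqs", freqs)
        object.__setattr__(self, "power", power)


@dataclass(frozen=True)
class SpectralPeak:
    """Location and height of the PSD maximum within a search band."""

    peak_freq: float
    peak_power: float
    search_band: tuple[float, float]


def extract_segment(trace: Trace, start_s: float, end_s: float) -> Trace:
    """Return the half-open segment [start_s, end_s) of a trace.

    Times are relative to the trace's own time origin ``t0``.  The
    returned trace carries the updated ``t0``.
    """
    if not (0.0 <= start_s < end_s <= trace.duration + 0.5 / trace.fs):
        raise ValueError(
            f"segment [{start_s}, {end_s}) outside trace of duration {trace.duration:g} s"
        )
    i0 = int(round(start_s * trace.fs))
    i1 = int(round(end_s * trace.fs))
    i1 = min(i1, trace.n)
    return Trace(trace.samples[i0:i1].copy(), trace.fs, trace.t0 + i0 / trace.fs)


def lowpass_butterworth(
    trace: Trace, corner_hz: float = DEFAULT_CORNER_HZ, order: int = 4
) -> Trace:
    """Zero-phase Butterworth low-pass filter.

    The filter is applied forward and backward (``sosfiltfilt``) so burst
    timing is preserved; the effective magnitude response is the squared
    single-pass response of the declared order.
    """
    if not 0 < corner_hz < trace.fs / 2:
        raise ValueError(f"corner {corner_hz} Hz must lie below Nyquist ({trace.fs / 2} Hz)")
    sos = signal.butter(order, corner_hz, btype="low", fs=trace.fs, output="sos")
    filtered = signal.sosfiltfilt(sos, trace.samples)
    return Trace(filtered, trace.fs, trace.t0)


def welch_psd(
    trace: Trace,
    window_len_samples: int = DEFAULT_WINDOW_LEN,
    window: str = "hamming",
    overlap_frac: float = 0.5,
) -> PSDResult:
    """One-sided Welch PSD in mV^2/Hz.

    Mean (constant) detrending per segment; density scaling, so the PSD
    integrates to the signal variance for zero-mean broadband input.
    ``bin_hz = fs / window_len_samples``.
    """
    if window_len_samples > trace.n:
        raise ValueError(
            f"trace of {trace.n} samples shorter than one window ({window_len_samples})"
        )
    if not 0.0 <= overlap_frac < 1.0:
        raise ValueError("overlap fraction must be in [0, 1)")
    noverlap = int(round(overlap_frac * window_len_samples))
    freqs, power = signal.welch(
        trace.samples,
        fs=trace.fs,
        window=window,
        nperseg=window_len_samples,
        noverlap=noverlap,
        detrend="constant",
        scaling="density",
    )
    return PSDResult(
        freqs=freqs,
        power=power,
        bin_hz=trace.fs / window_len_samples,
        window=window,
        window_len=window_len_samples,
        overlap_frac=overlap_frac,
    )


def find_spectral_peak(
    psd: PSDResult, band: tuple[float, float] = DEFAULT_BAND
) -> SpectralPeak:
    """Argmax of the PSD restricted to ``band`` (inclusive); ties break low.

    ``np.argmax`` returns the first (lowest-frequency) index among ties,
    which is the declared tie-break.
    """
    lo, hi = band
    if not lo < hi:
        raise ValueError("empty search band")
    mask = (psd.freqs >= lo) & (psd.freqs <= hi)
    if not mask.any():
        raise ValueError(f"band {band} contains no frequency bins")
    sub_f = psd.freqs[mask]
    sub_p = psd.power[mask]
    i = int(np.argmax(sub_p))
    return SpectralPeak(peak_freq=float(sub_f[i]), peak_power=float(sub_p[i]), search_band=(lo, hi))


def write_psd(psd: PSDResult, path) -> None:
    """Export a PSD as two-column delimited text (freq_hz, power_mv2_per_hz)."""
    np.savetxt(
        path,
        np.column_stack([psd.freqs, psd.power]),
        fmt="%.9g",
        delimiter="\t",
        header="freq_hz\tpower_mv2_per_hz",
    )
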