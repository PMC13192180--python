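"""Synthetic local-field-potential traces.

Four activity classes are emulated, matching the network states an
experimenter sees in carbachol-driven hippocampal slice cultures:

``gamma``
    A sinusoid at ``gamma_freq`` under slow (0.1 Hz) amplitude
    modulation, over 1/f-like background noise.  The sinusoid-plus-
    modulation model (rather than narrowband-filtered noise) keeps the
    spectral ground truth unambiguous: the Welch peak must land on
    ``gamma_freq``.
``low``
    The same oscillation model; callers choose a sub-gamma frequency
    and/or small amplitude to land on the low-activity side of the
    classification thresholds.
``bursts``
    Recurrent transients over a quiet background: Gaussian-windowed
    oscillation packets at ``intra_burst_freq``, placed at ``burst_rate``
    with uniform timing jitter of +/-10% of the inter-event interval and
    a refractory gap of twice the burst width.
``silent``
    Background noise only (all zeros when ``noise_sd = 0``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..trace import Trace
from .ground_truth import GroundTruth

__all__ = ["LfpGenSpec", "generate_lfp"]

STATE_KINDS = ("gamma", "low", "bursts", "silent")


@dataclass(frozen=True)
class LfpGenSpec:
    """Parameters of one synthetic LFP trace.

    Amplitudes and noise in mV; a burst amplitude of ten times the noise
    floor gives transients that stand clear of the background the way
    visually scored bursts do.
    """

    state_kind: str = "gamma"
    duration_s: float = 300.0
    fs: float = 10_000.0
    gamma_freq: float = 35.0
    gamma_amp: float = 0.05
    burst_rate: float = 0.55
    intra_burst_freq: float = 100.0
    burst_amp: float = 0.05
    burst_width_s: float = 0.10
    noise_sd: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        if self.state_kind not in STATE_KINDS:
            raise ValueError(f"state_kind must be one of {STATE_KINDS}")
        if self.duration_s <= 0:
            raise ValueError("duration must be positive")
        if min(self.gamma_amp, self.burst_amp, self.noise_sd) < 0:
            raise ValueError("amplitudes must be non-negative")
        fmax = max(self.gamma_freq, self.intra_burst_freq)
        if self.fs <= 2 * fmax:
            raise ValueError(
                f"fs = {self.fs} Hz aliases the {fmax} Hz component (need fs > {2 * fmax})"
            )


def _pink_noise(rng: np.random.Generator, n: int, sd: float) -> np.ndarray:
    """1/f-power noise with RMS ``sd`` (zero DC)."""
    if sd == 0:
        return np.zeros(n)
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    scale = np.zeros_like(f)
    scale[1:] = 1.0 / np.sqrt(f[1:])
    shaped = np.fft.irfft(spec * scale, n)
    return shaped * (sd / np.std(shaped))


def _burst_times(spec: LfpGenSpec, rng: np.random.Generator) -> np.ndarray:
    """Jittered quasi-periodic event centers with a refractory gap."""
    interval = 1.0 / spec.burst_rate
    refractory = 2.0 * spec.burst_width_s
    base = np.arange(interval / 2, spec.duration_s - interval / 4, interval)
    jitter = rng.uniform(-0.1 * interval, 0.1 * interval, size=base.size)
    times = base + jitter
    # enforce the refractory gap without dropping events
    for i in range(1, times.size):
        if times[i] - times[i - 1] < refractory:
            times[i] = times[i - 1] + refractory
    return times[times < spec.duration_s - spec.burst_width_s]


def generate_lfp(spec: LfpGenSpec) -> tuple[Trace, GroundTruth]:
    """Generate one LFP trace per ``spec``; bit-identical for same spec+seed."""
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration_s * spec.fs))
    t = np.arange(n) / spec.fs
    truth: dict = {"state_kind": spec.state_kind, "fs": spec.fs, "duration_s": spec.duration_s}

    if spec.state_kind in ("gamma", "low"):
        phase = rng.uniform(0, 2 * np.pi)
        mod_phase = rng.uniform(0, 2 * np.pi)
        envelope = spec.gamma_amp * (1.0 + 0.2 * np.sin(2 * np.pi * 0.1 * t + mod_phase))
        v = envelope * np.sin(2 * np.pi * spec.gamma_freq * t + phase)
        v = v + _pink_noise(rng, n, spec.noise_sd)
        truth.update(gamma_freq=spec.gamma_freq, gamma_amp=spec.gamma_amp)
    elif spec.state_kind == "bursts":
        v = rng.standard_normal(n) * spec.noise_sd if spec.noise_sd > 0 else np.zeros(n)
        times = _burst_times(spec, rng)
        sigma = spec.burst_width_s / 2.355  # burst_width_s is the envelope FWHM
        # each transient = fast oscillation packet riding on a slower field
        # deflection, so the event train carries genuine low-frequency
        # energy at the burst rate (as LFP bursts do)
        # the slow deflection broadens with the inter-burst interval, so
        # its harmonic content stays weak relative to the fundamental
        sigma_slow = max(4.0 * sigma, 1.0 / (8.0 * spec.burst_rate))
        half = 4.0 * sigma_slow
        for tc in times:
            phase = rng.uniform(0, 2 * np.pi)
            i0 = max(0, int((tc - half) * spec.fs))
            i1 = min(n, int((tc + half) * spec.fs) + 1)
            tt = t[i0:i1] - tc
            v[i0:i1] += spec.burst_amp * (
                np.exp(-(tt**2) / (2 * sigma**2))
                * np.sin(2 * np.pi * spec.intra_burst_freq * tt + phase)
                + 0.6 * np.exp(-(tt**2) / (2 * sigma_slow**2))
            )
        truth.update(
            burst_times=times,
            burst_rate=spec.burst_rate,
            intra_burst_freq=spec.intra_burst_freq,
            burst_amp=spec.burst_amp,
            burst_width_s=spec.burst_width_s,
        )
    else:  # silent
        v = rng.standard_normal(n) * spec.noise_sd if spec.noise_sd > 0 else np.zeros(n)

    truth["noise_sd"] = spec.noise_sd
    return Trace(v, spec.fs, 0.0), GroundTruth("lfp", truth)
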