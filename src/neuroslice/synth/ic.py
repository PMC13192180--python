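"""Synthetic sharp-electrode (intracellular) traces.

Stylized pyramidal-cell voltage responses to current-step protocols.
Action potentials are rendered as piecewise-linear waveforms whose knots
are chosen so that, under the analysis module's measurement definitions
(threshold at the dV/dt criterion, amplitude = peak - threshold,
half-width at the threshold + amplitude/2 level, mAHP = threshold minus
the inter-spike minimum, sAHP = resting potential minus the post-step
minimum), every parameter is recovered exactly on noiseless fixtures:

* the AP onset is a slope discontinuity at a grid sample, so the first
  dV/dt crossing lands on the sample holding exactly ``ap_threshold_mV``;
* the rise and the supra-threshold part of the fall are linear, so the
  interpolated half-level crossings give exactly ``half_width_ms``;
* the fast afterhyperpolarization bottoms out at a grid sample at
  exactly ``threshold - mahp_mV``; the post-step slow AHP is an alpha
  function whose minimum sits on the grid at ``rmp - sahp_mV``.

Two firing modes: ``regular`` (near-constant inter-spike interval, rate
proportional to supra-rheobase current) and ``bursting`` (a short
initial high-frequency cluster, then exponentially adapting slowdown,
with a terminal slow AHP) — the phenotypes seen in control vs
cytokine-exposed CA3 pyramidal cells.

Sub-threshold steps produce an exponential RC deflection whose steady
state is exactly ``I x R_input`` (Ohm's law), so input resistance
round-trips through the analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ..trace import Trace
from .ground_truth import GroundTruth

__all__ = ["IcStep", "IcGenSpec", "generate_ic_trace"]

_RISE_MS = 0.25  # AP rise time (threshold to peak); 5 samples at 20 kHz


@dataclass(frozen=True)
class IcStep:
    """One current step: amplitude (nA), duration (s), onset (s)."""

    amp_na: float
    duration_s: float
    onset_s: float

    @property
    def offset_s(self) -> float:
        return self.onset_s + self.duration_s


@dataclass(frozen=True)
class IcGenSpec:
    firing_mode: str = "regular"
    rmp_mv: float = -70.0
    ap_amp_mv: float = 80.0
    ap_threshold_mv: float = -50.0
    half_width_ms: float = 1.2
    mahp_mv: float = 5.0
    sahp_mv: float = 3.0
    step_protocol: tuple[IcStep, ...] = (IcStep(0.5, 0.2, 0.5),)
    adaptation_rate: float = 2.0  # 1/s, bursting-mode ISI growth
    input_resistance_mohm: float = 20.0
    membrane_tau_ms: float = 10.0
    rheobase_na: float = 0.1
    rate_gain_hz_per_na: float = 100.0
    latency_ms: float = 10.0  # first-AP latency, regular mode
    burst_latency_ms: float = 4.0
    burst_isi_ms: float = 8.0
    n_burst_aps: int = 4
    adapted_isi0_ms: float = 30.0
    fs: float = 20_000.0
    post_s: float = 1.5  # tail after the last step (holds the sAHP)
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.firing_mode not in ("regular", "bursting"):
            raise ValueError("firing_mode must be 'regular' or 'bursting'")
        if self.ap_amp_mv <= 0 or self.half_width_ms <= 0:
            raise ValueError("AP amplitude and half-width must be positive")
        if self.half_width_ms <= _RISE_MS / 2 + 0.05:
            raise ValueError(f"half-width must exceed {_RISE_MS / 2 + 0.05} ms")
        if self.mahp_mv < 0 or self.sahp_mv < 0:
            raise ValueError("AHP amplitudes must be non-negative")
        steps = tuple(sorted(self.step_protocol, key=lambda s: s.onset_s))
        for a, b in zip(steps, steps[1:]):
            if a.offset_s > b.onset_s:
                raise ValueError("protocol step windows overlap")
        object.__setattr__(self, "step_protocol", steps)

    @property
    def duration_s(self) -> float:
        return max(s.offset_s for s in self.step_protocol) + self.post_s


def _ap_times_regular(spec: IcGenSpec, step: IcStep) -> list[float]:
    """Evenly spaced spikes; count = gain x (I - rheobase) x duration."""
    drive = step.amp_na - spec.rheobase_na
    n = int(math.floor(spec.rate_gain_hz_per_na * drive * step.duration_s + 1e-9))
    dur_ms = step.duration_s * 1e3
    avail = dur_ms - spec.latency_ms
    if n < 1 or avail <= 0:
        return []
    n = min(n, int(avail // 5.0))  # keep ISIs >= 5 ms so waveforms never overlap
    isi = avail / n
    return [spec.latency_ms + k * isi for k in range(n)]


def _ap_times_bursting(spec: IcGenSpec, step: IcStep) -> list[float]:
    """Initial high-frequency cluster, then exponentially adapting ISIs."""
    dur_ms = step.duration_s * 1e3
    times = []
    t = spec.burst_latency_ms
    for _ in range(spec.n_burst_aps):
        if t > dur_ms - 5.0:
            break
        times.append(t)
        t += spec.burst_isi_ms
    while True:
        elapsed_s = times[-1] / 1e3 if times else 0.0
        isi = spec.adapted_isi0_ms * math.exp(spec.adaptation_rate * elapsed_s)
        t = (times[-1] if times else 0.0) + isi
        if t > dur_ms - 5.0:
            break
        times.append(t)
    return times


def _render_step(v, spec: IcGenSpec, step: IcStep, ap_times_ms, k_on, k_off, dt_ms):
    """Fill v[k_on:k_off] (the step window) and the post-step tail."""
    thr, amp, mahp = spec.ap_threshold_mv, spec.ap_amp_mv, spec.mahp_mv
    rmp = spec.rmp_mv
    n_r = int(round(_RISE_MS / dt_ms))
    fall_slope = (amp / 2) / (spec.half_width_ms - _RISE_MS / 2)  # mV/ms
    v_rest_target = thr  # inter-spike recovery asymptote

    onsets = [k_on + int(round(tm / dt_ms)) for tm in ap_times_ms]
    # pre-first-AP depolarizing ramp from RMP toward threshold
    if onsets:
        ramp = np.linspace(rmp, thr, onsets[0] - k_on + 1)
        v[k_on : onsets[0] + 1] = ramp
    for j, k0 in enumerate(onsets):
        apex = k0 + n_r
        # supra-threshold fall: linear at fall_slope down to threshold level
        t_cross = amp / fall_slope  # ms after apex
        k_next = onsets[j + 1] if j + 1 < len(onsets) else k_off
        # grid-snapped AHP minimum, kept clear of the next AP onset
        k_min = apex + max(
            int(round((amp + mahp) / fall_slope / dt_ms)), int(math.ceil(t_cross / dt_ms)) + 1
        )
        k_min = min(k_min, max(k_next - 2, apex + int(math.ceil(t_cross / dt_ms)) + 1))
        knots_t = [k0, apex, apex + t_cross / dt_ms, float(k_min)]
        knots_v = [thr, thr + amp, thr, thr - mahp]
        idx = np.arange(k0, min(k_min + 1, k_off))
        v[k0 : k0 + idx.size] = np.interp(idx, knots_t, knots_v)
        # exponential recovery toward just below threshold
        if k_min + 1 < k_next:
            tau = max((k_next - k_min) * dt_ms / 6.0, 0.4)
            tt = (np.arange(k_min + 1, min(k_next, k_off)) - k_min) * dt_ms
            v[k_min + 1 : k_min + 1 + tt.size] = v_rest_target - (v_rest_target - (thr - mahp)) * np.exp(-tt / tau)

    if not onsets:
        # passive RC deflection, steady state exactly I x R (mV = nA x MOhm)
        dv_ss = step.amp_na * spec.input_resistance_mohm
        tt = (np.arange(k_on, k_off) - k_on) * dt_ms
        v[k_on:k_off] = rmp + dv_ss * (1.0 - np.exp(-tt / spec.membrane_tau_ms))

    # post-step: relax to RMP; suprathreshold steps add the terminal slow AHP
    v_end = v[k_off - 1]
    tail = np.arange(k_off, v.size)
    tt = (tail - k_off) * dt_ms
    relax = rmp + (v_end - rmp) * np.exp(-tt / spec.membrane_tau_ms)
    if onsets and spec.sahp_mv > 0:
        t_p = 150.0  # ms to sAHP trough
        alpha = (tt / t_p) * np.exp(1.0 - tt / t_p)
        relax = relax - spec.sahp_mv * alpha
    v[k_off:] = relax


def generate_ic_trace(spec: IcGenSpec) -> tuple[Trace, GroundTruth]:
    """Generate one intracellular trace; bit-identical for same spec+seed."""
    rng = np.random.default_rng(spec.seed)
    fs = spec.fs
    dt_ms = 1e3 / fs
    n = int(round(spec.duration_s * fs))
    v = np.full(n, spec.rmp_mv)

    steps_truth = []
    for step in spec.step_protocol:
        k_on = int(round(step.onset_s * fs))
        k_off = int(round(step.offset_s * fs))
        if k_off > n:
            raise ValueError("protocol exceeds trace duration")
        if step.amp_na > spec.rheobase_na:
            if spec.firing_mode == "regular":
                ap_ms = _ap_times_regular(spec, step)
            else:
                ap_ms = _ap_times_bursting(spec, step)
        else:
            ap_ms = []
        # snap AP times to the sample grid; the snapped values are the truth
        ap_ms = [int(round(tm / dt_ms)) * dt_ms for tm in ap_ms]
        _render_step(v, spec, step, ap_ms, k_on, k_off, dt_ms)
        steps_truth.append(
            {
                "amp_na": step.amp_na,
                "duration_s": step.duration_s,
                "onset_s": k_on / fs,
                "ap_times_s": [k_on / fs + tm / 1e3 for tm in ap_ms],
                "latency_ms": ap_ms[0] if ap_ms else None,
                "n_aps": len(ap_ms),
            }
        )

    if spec.noise_sd > 0:
        v = v + rng.standard_normal(n) * spec.noise_sd

    truth = GroundTruth(
        "ic",
        {
            "firing_mode": spec.firing_mode,
            "rmp_mv": spec.rmp_mv,
            "ap_threshold_mv": spec.ap_threshold_mv,
            "ap_amp_mv": spec.ap_amp_mv,
            "half_width_ms": spec.half_width_ms,
            "mahp_mv": spec.mahp_mv,
            "sahp_mv": spec.sahp_mv,
            "input_resistance_mohm": spec.input_resistance_mohm,
            "steps": steps_truth,
            "fs": fs,
        },
    )
    return Trace(v, fs, 0.0), truth
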