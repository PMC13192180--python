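"""Sharp-electrode trace metrics.

Action-potential detection and waveform parameters, per-step latency
and spike counts, medium and slow afterhyperpolarization, input
resistance and resting membrane potential.

Measurement conventions:

* AP threshold — voltage at the first sample of the dV/dt >= 20 mV/ms
  run leading into the spike peak (a rate-of-rise criterion is robust
  to the resting-potential shifts seen under cytokine exposure);
* amplitude — peak minus threshold;
* half-width — width at the threshold + amplitude/2 level, with linear
  interpolation of the level crossings;
* mAHP — threshold minus the post-peak minimum before the next AP
  (search capped at 50 ms);
* sAHP — pre-stimulus resting potential minus the most hyperpolarized
  potential within 1 s after the step offset;
* input resistance — steady-state deflection over injected current,
  mV / nA = MOhm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .synth.ic import IcStep
from .trace import Trace

__all__ = [
    "ApEvent",
    "StepResponse",
    "PassiveProperties",
    "detect_aps",
    "step_metrics",
    "input_resistance",
    "detect_multiplets",
]


@dataclass(frozen=True)
class ApEvent:
    t: float  # s, threshold-crossing time
    threshold_mv: float
    peak_mv: float
    amplitude_mv: float
    half_width_ms: float
    mahp_mv: float | None


@dataclass(frozen=True)
class StepResponse:
    step: IcStep
    ap_events: tuple[ApEvent, ...]
    latency_first_ms: float | None
    n_aps_total: int
    n_aps_first_100ms: int
    mahp_mv: float | None
    sahp_mv: float | None


@dataclass(frozen=True)
class PassiveProperties:
    rmp_mv: float
    input_resistance_mohm: float


def _interp_crossing(v: np.ndarray, i0: int, i1: int, level: float, rising: bool) -> float | None:
    """Fractional sample index of the first level crossing in [i0, i1)."""
    seg = v[i0:i1]
    if rising:
        hits = np.nonzero((seg[:-1] < level) & (seg[1:] >= level))[0]
    else:
        hits = np.nonzero((seg[:-1] >= level) & (seg[1:] < level))[0]
    if hits.size == 0:
        return None
    j = hits[0]
    dv = seg[j + 1] - seg[j]
    frac = 0.0 if dv == 0 else (level - seg[j]) / dv
    return i0 + j + frac


def detect_aps(
    trace: Trace,
    dvdt_thresh: float = 20.0,  # mV/ms
    min_amp_mv: float = 10.0,
    mahp_window_ms: float = 50.0,
) -> list[ApEvent]:
    """Detect action potentials and measure their waveform parameters.

    Spike peaks are located first (prominence >= ``min_amp_mv``); each
    peak is then anchored to the nearest preceding run of dV/dt >=
    ``dvdt_thresh`` (lightly smoothed derivative), whose first sample
    defines the threshold.  Peaks without such a run within 3 ms — slow
    subthreshold humps — are discarded.
    """
    if trace.fs < 10_000:
        raise ValueError("AP analysis requires fs >= 10 kHz")
    v = trace.samples
    dt_ms = 1e3 / trace.fs
    dv = np.diff(v) / dt_ms
    above = np.zeros(v.size, dtype=bool)
    above[:-1] = dv >= dvdt_thresh

    peaks, _ = signal.find_peaks(v, prominence=min_amp_mv, distance=max(1, int(1e-3 * trace.fs)))
    events: list[ApEvent] = []
    back = int(round(3.0 / dt_ms))
    last_onset = -1
    for p in peaks:
        lo = max(0, p - back)
        win = above[lo:p]
        if not win.any():
            continue
        # start of the run of supra-threshold dV/dt nearest the peak
        k = len(win) - 1
        while k >= 0 and not win[k]:
            k -= 1
        end = k
        while k >= 0 and win[k]:
            k -= 1
        onset = lo + k + 1
        if onset == last_onset:
            continue  # same rise claimed by a larger later peak
        last_onset = onset
        # threshold from a short linear fit of the pre-onset baseline,
        # extrapolated to the onset sample: exact on ramps, and it
        # averages down single-sample noise
        f0 = max(0, onset - 5)
        if onset - f0 >= 3:
            x = np.arange(f0, onset)
            coef = np.polyfit(x, v[f0:onset], 1)
            thr = float(np.polyval(coef, onset))
        else:
            thr = float(v[onset])
        peak_v = float(v[p])
        amp = peak_v - thr
        if amp < min_amp_mv:
            continue
        events.append((onset, p, thr, peak_v, amp))

    out: list[ApEvent] = []
    n = v.size
    for j, (onset, p, thr, peak_v, amp) in enumerate(events):
        level = thr + amp / 2.0
        up = _interp_crossing(v, onset, p + 1, level, rising=True)
        down_end = events[j + 1][0] if j + 1 < len(events) else n
        down = _interp_crossing(v, p, down_end, level, rising=False)
        hw = (down - up) * dt_ms if (up is not None and down is not None) else np.nan
        mahp_end = min(down_end, p + int(round(mahp_window_ms / dt_ms)))
        mahp = thr - float(v[p:mahp_end].min()) if mahp_end > p else None
        out.append(
            ApEvent(
                t=trace.t0 + onset / trace.fs,
                threshold_mv=thr,
                peak_mv=peak_v,
                amplitude_mv=amp,
                half_width_ms=float(hw),
                mahp_mv=mahp,
            )
        )
    return out


def step_metrics(
    trace: Trace,
    step: IcStep,
    sahp_window_s: float = 1.0,
    baseline_s: float = 0.1,
    **detect_kwargs,
) -> StepResponse:
    """Latency, spike counts and AHP amplitudes for one current step.

    The sAHP is the pre-stimulus mean potential minus the post-step
    minimum within ``sahp_window_s``; it is only meaningful after
    suprathreshold steps and is reported as None when no AP occurred.
    """
    fs = trace.fs
    k_on = int(round((step.onset_s - trace.t0) * fs))
    k_off = int(round((step.offset_s - trace.t0) * fs))
    if k_on < 0 or k_off > trace.n:
        raise ValueError("step window outside trace")

    aps = detect_aps(trace, **detect_kwargs)
    tail_s = 0.05  # APs straddling the offset still belong to the step
    in_step = [
        a for a in aps if step.onset_s <= a.t - 0.0 < step.offset_s + tail_s
    ]
    latency = (in_step[0].t - step.onset_s) * 1e3 if in_step else None
    n_100 = sum(1 for a in in_step if a.t - step.onset_s < 0.1)
    # the mAHP of the train's last AP is only valid when its search
    # window ends before the step offset (otherwise the post-step
    # relaxation, not the AHP, sets the minimum)
    mahp_win_s = detect_kwargs.get("mahp_window_ms", 50.0) / 1e3
    mahps = [
        a.mahp_mv
        for i, a in enumerate(in_step)
        if a.mahp_mv is not None
        and (i + 1 < len(in_step) or a.t + mahp_win_s <= step.offset_s)
    ]
    mahp = float(np.median(mahps)) if mahps else None

    b0 = max(0, k_on - int(round(baseline_s * fs)))
    rmp = float(np.mean(trace.samples[b0:k_on])) if k_on > b0 else float(trace.samples[0])
    sahp = None
    if in_step:
        k_end = min(trace.n, k_off + int(round(sahp_window_s * fs)))
        post_min = float(trace.samples[k_off:k_end].min())
        sahp = rmp - post_min
    return StepResponse(
        step=step,
        ap_events=tuple(in_step),
        latency_first_ms=latency,
        n_aps_total=len(in_step),
        n_aps_first_100ms=n_100,
        mahp_mv=mahp,
        sahp_mv=sahp,
    )


def input_resistance(deflection_mv: float, current_na: float = -0.2) -> float:
    """Input resistance R = V/I in MOhm (mV / nA).

    A hyperpolarizing pulse with a negative steady-state deflection
    yields a positive resistance.  A zero deflection returns 0 MOhm,
    which callers should treat as implausible.
    """
    if current_na == 0:
        raise ValueError("current must be non-zero")
    return deflection_mv / current_na


def steady_state_deflection(trace: Trace, step: IcStep, baseline_s: float = 0.1) -> float:
    """Voltage deflection at late steady state (last quarter of the pulse)."""
    fs = trace.fs
    k_on = int(round((step.onset_s - trace.t0) * fs))
    k_off = int(round((step.offset_s - trace.t0) * fs))
    b0 = max(0, k_on - int(round(baseline_s * fs)))
    baseline = float(np.mean(trace.samples[b0:k_on]))
    q = k_off - (k_off - k_on) // 4
    return float(np.mean(trace.samples[q:k_off])) - baseline


def detect_multiplets(ap_events: list[ApEvent], isi_max_ms: float = 30.0) -> list[dict]:
    """Group spikes into doublets/triplets by maximal runs of short ISIs.

    A multiplet is a maximal run of consecutive inter-spike intervals
    each at most ``isi_max_ms``; runs of 2 spikes are doublets, 3 are
    triplets, longer runs are labeled by their spike count.
    """
    times = [a.t for a in ap_events]
    if any(b <= a for a, b in zip(times, times[1:])):
        raise ValueError("AP events must be time-sorted")
    labels = {2: "doublet", 3: "triplet"}
    out = []
    i = 0
    while i < len(times):
        j = i
        while j + 1 < len(times) and (times[j + 1] - times[j]) * 1e3 <= isi_max_ms:
            j += 1
        count = j - i + 1
        if count >= 2:
            out.append(
                {
                    "kind": labels.get(count, f"{count}-plet"),
                    "n": count,
                    "t_first_s": times[i],
                    "t_last_s": times[j],
                }
            )
        i = j + 1
    return out
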