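"""State classification, burst detection, wavelet averaging, Fisher test."""

import math

import numpy as np
import pytest

from neuroslice.classify import (
    BurstEvent,
    ClassifyThresholds,
    burst_triggered_wavelet,
    classify_burst_subtype,
    classify_state,
    detect_bursts,
    fisher_exact_2x2,
    suppression_time,
    wavelet_spectrum_peaks,
)
from neuroslice.spectral import SpectralPeak, lowpass_butterworth, welch_psd, find_spectral_peak
from neuroslice.synth import LfpGenSpec, generate_lfp
from neuroslice.trace import Trace


def _peak(freq, power):
    return SpectralPeak(peak_freq=freq, peak_power=power, search_band=(1, 200))


class TestDetectBursts:
    def test_silent_trace_yields_nothing(self):
        assert detect_bursts(Trace(np.zeros(10_000), 10_000.0)) == []

    def test_two_identical_transients(self):
        fs = 10_000.0
        t = np.arange(int(30 * fs)) / fs
        v = np.zeros_like(t)
        for tc in (10.0, 20.0):
            v += np.exp(-((t - tc) ** 2) / (2 * 0.05**2)) * np.sin(2 * np.pi * 80 * (t - tc))
        events = detect_bursts(Trace(v, fs))
        times = sorted(e.time_s for e in events)
        assert len(times) == 2
        assert times[0] == pytest.approx(10.0, abs=0.02)
        assert times[1] == pytest.approx(20.0, abs=0.02)

    def test_recovers_ground_truth_events(self, bursts_fixture):
        _, _, truth, _, events = bursts_fixture
        det = np.array([e.time_s for e in events])
        matched = sum(np.min(np.abs(det - t)) <= 0.025 for t in truth["burst_times"])
        assert matched / len(truth["burst_times"]) >= 0.95

    def test_sign_flip_invariance(self, bursts_fixture):
        _, _, _, filtered, events = bursts_fixture
        flipped = detect_bursts(filtered.scaled(-1.0))
        assert [e.time_s for e in flipped] == [e.time_s for e in events]


class TestClassifyState:
    def test_gamma_when_both_thresholds_met(self, gamma_fixture):
        _, _, filtered, _, peak = gamma_fixture
        call = classify_state(filtered, peak, [])
        assert call.state == "Gamma"
        assert peak.peak_freq > 23.0 and peak.peak_power >= 1e-4

    def test_low_frequency_peak_is_low_activity(self):
        tr, _ = generate_lfp(LfpGenSpec(state_kind="low", gamma_freq=15.0, duration_s=10.0, seed=1))
        call = classify_state(tr, _peak(15.0, 2e-4), [])
        assert call.state == "LowActivity"

    def test_low_power_peak_is_low_activity(self):
        tr, _ = generate_lfp(
            LfpGenSpec(state_kind="gamma", gamma_amp=0.005, noise_sd=1e-4, duration_s=10.0, seed=1)
        )
        call = classify_state(tr, _peak(34.0, 1e-5), [])
        assert call.state == "LowActivity"

    def test_all_zero_trace_is_no_activity(self):
        tr = Trace(np.zeros(10_000), 10_000.0)
        call = classify_state(tr, _peak(34.0, 0.0), [])
        assert call.state == "NoActivity"

    def test_bursting_segment_is_bursts(self, bursts_fixture):
        _, _, _, filtered, events = bursts_fixture
        psd = welch_psd(filtered)
        call = classify_state(filtered, find_spectral_peak(psd), events)
        assert call.state == "Bursts" and call.burst_subtype == 1

    def test_amplitude_ladder_flips_gamma_to_low_never_bursts(self, gamma_fixture):
        _, _, filtered, _, _ = gamma_fixture
        states = []
        # bottom of the ladder stays above the silence criterion
        for scale in np.logspace(0, -1, 10):
            scaled = filtered.scaled(scale)
            peak = find_spectral_peak(welch_psd(scaled))
            bursts = detect_bursts(scaled)
            states.append(classify_state(scaled, peak, bursts).state)
        assert states[0] == "Gamma" and states[-1] == "LowActivity"
        assert "Bursts" not in states
        flip = states.index("LowActivity")
        assert all(s == "Gamma" for s in states[:flip])
        assert all(s != "Gamma" for s in states[flip:])


class TestBurstTriggeredWavelet:
    def test_burst_fixture_shows_rate_and_intra_burst_peaks(self, bursts_fixture):
        spec, _, _, filtered, events = bursts_fixture
        ws = burst_triggered_wavelet(filtered, events)
        lo, hi = sorted(wavelet_spectrum_peaks(ws, 2))
        assert lo == pytest.approx(spec.burst_rate, rel=0.2)
        assert hi == pytest.approx(spec.intra_burst_freq, rel=0.2)

    def test_gamma_with_surrogate_timepoints_peaks_at_gamma(self, short_freq_grid):
        tr, _ = generate_lfp(
            LfpGenSpec(state_kind="gamma", gamma_freq=34.0, noise_sd=0.0, duration_s=60.0, seed=5)
        )
        events = [BurstEvent(t, 1.0, 1.0) for t in np.arange(15.0, 45.0, 2.0)]
        ws = burst_triggered_wavelet(tr, events, freq_grid=short_freq_grid)
        peak = ws.freqs[np.argmax(ws.magnitude)]
        assert peak == pytest.approx(34.0, rel=0.1)

    def test_normalized_to_unit_maximum(self, bursts_fixture, short_freq_grid):
        _, _, _, filtered, events = bursts_fixture
        ws = burst_triggered_wavelet(filtered, events[:20], freq_grid=short_freq_grid)
        assert ws.magnitude.max() == 1.0

    def test_scale_invariance_of_normalized_spectrum(self, bursts_fixture, short_freq_grid):
        _, _, _, filtered, events = bursts_fixture
        a = burst_triggered_wavelet(filtered, events[:10], freq_grid=short_freq_grid)
        b = burst_triggered_wavelet(filtered.scaled(7.3), events[:10], freq_grid=short_freq_grid)
        np.testing.assert_allclose(a.magnitude, b.magnitude, atol=1e-12)

    def test_empty_events_rejected(self, gamma_fixture):
        _, _, filtered, _, _ = gamma_fixture
        with pytest.raises(ValueError):
            burst_triggered_wavelet(filtered, [])


class TestSuppressionTime:
    def test_switch_to_silence_is_located(self):
        g, _ = generate_lfp(LfpGenSpec(state_kind="gamma", duration_s=120.0, seed=3))
        s, _ = generate_lfp(LfpGenSpec(state_kind="silent", duration_s=120.0, seed=3))
        full = Trace(np.concatenate([g.samples, s.samples]), g.fs)
        t = suppression_time(full, window_s=30.0, step_s=10.0)
        assert t is not None and 120.0 <= t <= 150.0

    def test_persistent_gamma_returns_none(self):
        g, _ = generate_lfp(LfpGenSpec(state_kind="gamma", duration_s=120.0, seed=4))
        assert suppression_time(g, window_s=30.0) is None

    def test_silent_from_start_is_zero_within_window(self):
        s, _ = generate_lfp(LfpGenSpec(state_kind="silent", duration_s=90.0, seed=5))
        t = suppression_time(s, window_s=30.0, step_s=10.0)
        assert t == 0.0


def _fisher_oracle(a, b, c, d):
    """Independent enumeration of the conditional table distribution."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    if n == 0:
        return 1.0

    def prob(x):
        return math.comb(r1, x) * math.comb(r2, c1 - x) / math.comb(n, c1)

    p_obs = prob(a)
    return sum(
        prob(x)
        for x in range(max(0, c1 - r2), min(r1, c1) + 1)
        if prob(x) <= p_obs * (1 + 1e-7)
    )


class TestFisherExact:
    def test_symmetric_table_is_one(self):
        assert fisher_exact_2x2([[1, 1], [1, 1]]) == pytest.approx(1.0)

    def test_three_zero_zero_three(self):
        # margins (3,3)/(3,3): 4 tables with probabilities {1,9,9,1}/20
        assert fisher_exact_2x2([[3, 0], [0, 3]]) == pytest.approx(0.1)

    def test_row_swap_symmetry(self):
        for t in ([[2, 5], [7, 1]], [[0, 4], [3, 3]]):
            assert fisher_exact_2x2(t) == pytest.approx(fisher_exact_2x2(t[::-1]))

    def test_exhaustive_against_enumeration_oracle(self):
        # every 2x2 table with all margins <= 10
        for a in range(11):
            for b in range(11 - a):
                for c in range(11 - a):
                    for d in range(min(11 - b, 11 - c)):
                        if a + b + c + d == 0:
                            continue
                        got = fisher_exact_2x2([[a, b], [c, d]])
                        want = _fisher_oracle(a, b, c, d)
                        assert got == pytest.approx(want, abs=1e-10), (a, b, c, d)

    def test_negative_entries_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2([[1, -1], [0, 2]])
        with pytest.raises(ValueError):
            fisher_exact_2x2(np.array([[0.5, 1], [1, 1]]))


class TestBurstSubtype:
    def test_fast_rhythmic_bursting_is_type_one(self, bursts_fixture):
        _, _, _, filtered, events = bursts_fixture
        assert classify_burst_subtype(events, filtered) == 1

    def test_slow_low_frequency_bursting_is_type_two(self):
        spec = LfpGenSpec(
            state_kind="bursts", burst_rate=0.05, intra_burst_freq=20.0,
            burst_width_s=0.3, duration_s=120.0, seed=6,
        )
        tr, _ = generate_lfp(spec)
        filtered = lowpass_butterworth(tr)
        events = detect_bursts(filtered)
        assert len(events) >= 2
        assert classify_burst_subtype(events, filtered) == 2

    def test_single_event_is_undetermined(self):
        tr = Trace(np.zeros(10_000), 10_000.0)
        assert classify_burst_subtype([BurstEvent(0.5, 1.0, 1.0)], tr) is None
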