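"""Slow-wave filter/detector and slow-wave/spindle coupling."""

import numpy as np
import pytest
from scipy import signal as sps

from spindleq import slowwave as sw
from spindleq.events import OscillatoryEvent

FS = 256.0


def spindle_at(t1, oq=None):
    return OscillatoryEvent("", t1, t1 + 1.0, 0.95, 12.5, 12.5, oq=oq)


class TestFilter:
    def test_passband_1hz_low_attenuation_zero_lag(self):
        t = np.arange(int(30 * FS)) / FS
        x = np.sin(2 * np.pi * 1.0 * t)
        y = sw.sw_filter(x, FS)
        core = slice(int(5 * FS), -int(5 * FS))
        gain = y[core].max() / 1.0
        assert gain > 0.9
        # zero net phase: peaks coincide
        xc = np.correlate(y[core] - y[core].mean(),
                          x[core] - x[core].mean(), "full")
        lag = np.argmax(xc) - (len(x[core]) - 1)
        assert abs(lag) <= 2

    def test_spindle_band_attenuated(self):
        # design check: single-pass stopband >= 20 dB at 12.5 Hz, so the
        # forward-backward pass leaves at most ~1% amplitude (ripple-bound)
        t = np.arange(int(30 * FS)) / FS
        y = sw.sw_filter(np.sin(2 * np.pi * 12.5 * t), FS)
        assert np.abs(y[int(5 * FS) : -int(5 * FS)]).max() < 0.015
        n, wn = sps.cheb2ord([0.5, 4.0], [0.3, 8.0], 3.0, 20.0, fs=FS)
        sos = sps.cheby2(n, 20.0, wn, btype="bandpass", fs=FS, output="sos")
        w, h = sps.sosfreqz(sos, worN=[12.5], fs=FS)
        assert np.abs(h[0]) ** 2 <= 0.0105  # two passes: |H|^2

    def test_zero_in_zero_out(self):
        np.testing.assert_array_equal(sw.sw_filter(np.zeros(4096), FS), 0.0)

    def test_low_rate_rejected(self):
        with pytest.raises(ValueError):
            sw.sw_filter(np.zeros(100), 10.0)


class TestDetectSlowWaves:
    def _train(self, amps, fs=FS, period=1.0):
        """Alternating negative troughs and positive peaks of given heights."""
        n = int(len(amps) * period * fs) + int(fs)
        x = np.zeros(n)
        half = int(period * fs / 2)
        for i, a in enumerate(amps):
            i0 = int(i * period * fs)
            x[i0 : i0 + half] = -1.0 * np.sin(np.pi * np.arange(half) / half)
            x[i0 + half : i0 + 2 * half] = a * np.sin(np.pi * np.arange(half) / half)
        # trailing trough to close the last wave
        x[n - half :] = -np.sin(np.pi * np.arange(half) / half)
        return x

    def test_median_selection_brute_force(self):
        x = self._train([1.0, 2.0, 3.0, 4.0])
        cands = sw.detect_slow_waves(x, FS, selection="all")
        assert len(cands) == 4
        kept = sw.detect_slow_waves(x, FS, selection="above_median")
        # median of (1,2,3,4) = 2.5 -> amplitudes 3 and 4 survive
        assert len(kept) == 2
        assert all(k.peak_amplitude > 2.5 for k in kept)

    def test_positive_offset_flat_no_events(self):
        assert sw.detect_slow_waves(np.full(1000, 5.0), FS) == []

    def test_close_negative_deflections_rejected(self):
        fs = FS
        n = int(2 * fs)
        x = np.zeros(n)
        # two sub-zero minima 0.05 s apart around a positive bump
        i = int(1.0 * fs)
        gap = int(0.05 * fs)
        x[i] = -1.0
        x[i + gap] = -1.0
        x[i + gap // 2] = 0.5
        out = sw.detect_slow_waves(x, fs, selection="all", min_separation=0.1)
        assert all(not (i / fs <= o.peak_time <= (i + gap) / fs) for o in out)

    def test_above_median_count_half(self, rng):
        x = sw.sw_filter(rng.standard_normal(int(120 * FS)), FS)
        cands = sw.detect_slow_waves(x, FS, selection="all")
        kept = sw.detect_slow_waves(x, FS, selection="above_median")
        amps = sorted(c.peak_amplitude for c in cands)
        expected = sum(1 for a in amps if a > np.median(amps))
        assert len(kept) == expected
        assert abs(len(kept) - len(cands) / 2) <= 1


class TestCoupling:
    def test_within_window_coupled(self):
        sws = [sw.SlowWave(10.0, 5.0, 9.8, 10.2)]
        res = sw.couple(sws, [spindle_at(10.10)], window=0.125)
        assert res.pct_sw_followed_by_spindle == 100.0
        assert res.pct_spindles_preceded_by_sw == 100.0

    def test_outside_window_not_coupled(self):
        sws = [sw.SlowWave(10.0, 5.0, 9.8, 10.2)]
        res = sw.couple(sws, [spindle_at(10.20)], window=0.125)
        assert res.pct_sw_followed_by_spindle == 0.0

    def test_boundary_lag_exactly_window_coupled(self):
        sws = [sw.SlowWave(10.0, 5.0, 9.8, 10.2)]
        res = sw.couple(sws, [spindle_at(10.125)], window=0.125)
        assert res.pct_sw_followed_by_spindle == 100.0

    def test_empty_inputs_flagged(self):
        res = sw.couple([], [], 0.125)
        assert res.empty and res.pct_sw_followed_by_spindle == 0.0

    def test_poisson_chance_level(self, rng):
        lam_p = 0.5  # spindles per second
        T = 10000.0
        sws = [sw.SlowWave(t, 1.0, t - 0.2, t + 0.2)
               for t in np.sort(rng.uniform(0, T, size=int(0.2 * T)))]
        spins = [spindle_at(t) for t in np.sort(rng.uniform(0, T, size=int(lam_p * T)))]
        res = sw.couple(sws, spins, window=0.125)
        p_expect = (1 - np.exp(-lam_p * 0.125)) * 100
        se = 100 * np.sqrt(p_expect / 100 * (1 - p_expect / 100) / len(sws))
        assert abs(res.pct_sw_followed_by_spindle - p_expect) < 3 * se

    def test_translation_invariance(self, rng):
        sws = [sw.SlowWave(t, 1.0, t - 0.2, t + 0.2)
               for t in np.sort(rng.uniform(0, 500, 100))]
        spins = [spindle_at(t) for t in np.sort(rng.uniform(0, 500, 200))]
        base = sw.couple(sws, spins, 0.125)
        moved = sw.shift_control(sws, [spindle_at(s.t1 + 33.0) for s in spins],
                                 offset=33.0, window=0.125)
        assert moved.pct_sw_followed_by_spindle == base.pct_sw_followed_by_spindle
        assert moved.pct_spindles_preceded_by_sw == base.pct_spindles_preceded_by_sw

    def test_constructed_pairs_coupled_iff_lag_within_window(self):
        for lag, expect in [(0.05, 100.0), (0.125, 100.0), (0.2, 0.0)]:
            sws = [sw.SlowWave(float(t), 1.0, t - 0.2, t + 0.2)
                   for t in range(10, 100, 10)]
            spins = [spindle_at(s.peak_time + lag) for s in sws]
            res = sw.couple(sws, spins, window=0.125)
            assert res.pct_sw_followed_by_spindle == expect

    def test_per_oq_breakdown(self):
        sws = [sw.SlowWave(10.0, 1.0, 9.8, 10.2)]
        spins = [spindle_at(10.05, oq=4), spindle_at(50.0, oq=1)]
        res = sw.couple(sws, spins, 0.125, oq_split=True)
        assert res.per_oq[4] == 100.0 and res.per_oq[1] == 0.0


class TestShiftControl:
    def test_zero_offset_identity(self, rng):
        sws = [sw.SlowWave(t, 1.0, t - 0.2, t + 0.2)
               for t in np.sort(rng.uniform(0, 200, 50))]
        spins = [spindle_at(t) for t in rng.uniform(0, 200, 80)]
        a = sw.couple(sws, spins, 0.125)
        b = sw.shift_control(sws, spins, offset=0.0, window=0.125)
        assert a.pct_sw_followed_by_spindle == b.pct_sw_followed_by_spindle

    def test_collapses_constructed_coupling(self):
        sws = [sw.SlowWave(float(t), 1.0, t - 0.2, t + 0.2)
               for t in range(10, 500, 5)]
        spins = [spindle_at(s.peak_time + 0.1) for s in sws]
        assert sw.couple(sws, spins, 0.125).pct_sw_followed_by_spindle == 100.0
        shifted = sw.shift_control(sws, spins, offset=0.7, window=0.125)
        assert shifted.pct_sw_followed_by_spindle < 10.0

    def test_independent_streams_unchanged_within_noise(self, rng):
        sws = [sw.SlowWave(t, 1.0, t - 0.2, t + 0.2)
               for t in np.sort(rng.uniform(0, 5000, 800))]
        spins = [spindle_at(t) for t in np.sort(rng.uniform(0, 5000, 1500))]
        a = sw.couple(sws, spins, 0.125).pct_sw_followed_by_spindle
        b = sw.shift_control(sws, spins, 0.7, 0.125).pct_sw_followed_by_spindle
        assert abs(a - b) < 5.0
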