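"""Hysteresis event detection, o-Quality binning, event statistics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from spindleq import events as ev
from spindleq.io import EpochSpectra, Hypnogram

from conftest import brute_force_detect

CFG = ev.DetectionConfig()


def series(vals, dt=1.0):
    v = np.asarray(vals, dtype=float)
    return np.arange(len(v)) * dt, v


class TestDetectEvents:
    def test_single_run(self):
        t, r = series([0.89, 0.93, 0.94, 0.93, 0.89])
        out = ev.detect_events(t, r, config=CFG)
        assert len(out) == 1
        e = out[0]
        assert (e.t1, e.t2) == (1.0, 4.0)
        assert e.max_r == 0.94

    def test_merge_when_dip_stays_above_lower_threshold(self):
        t, r = series([0.89, 0.93, 0.91, 0.93, 0.89])
        out = ev.detect_events(t, r, config=CFG)
        assert len(out) == 1
        assert out[0].t2 - out[0].t1 == 3.0

    def test_split_when_dip_below_lower_threshold(self):
        t, r = series([0.89, 0.93, 0.89, 0.93, 0.88])
        out = ev.detect_events(t, r, config=CFG)
        assert len(out) == 2

    def test_dip_exactly_at_lower_threshold_merges(self):
        t, r = series([0.89, 0.93, 0.90, 0.93, 0.89])
        assert len(ev.detect_events(t, r, config=CFG)) == 1

    def test_short_series_empty(self):
        assert ev.detect_events([0.0], [0.95], config=CFG) == []

    def test_matches_brute_force_scanner(self, rng):
        r = rng.uniform(0.85, 0.97, size=10000)
        t = np.arange(len(r), dtype=float)
        mine = ev.detect_events(t, r, config=CFG)
        ref = brute_force_detect(t, r, CFG.r_b, CFG.r_a)
        assert len(mine) == len(ref)
        for e, (s, end) in zip(mine, ref):
            assert e.t1 == t[s]
            expected_t2 = t[end] if end < len(t) else t[-1] + 1.0
            assert e.t2 == expected_t2
            assert e.max_r == r[s:end].max()

    @given(st.lists(st.floats(0.85, 0.99), min_size=2, max_size=200),
           st.floats(0.9, 0.93), st.floats(0.001, 0.02))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_hysteresis_property_vs_brute_force(self, vals, r_b, gap):
        r_b = round(r_b, 4)
        cfg = ev.DetectionConfig(r_b=r_b, r_a=round(r_b - gap, 4),
                                 oq_edges=tuple(round(r_b + 0.01 * i, 4)
                                                for i in range(4)))
        t = np.arange(len(vals), dtype=float)
        mine = ev.detect_events(t, np.array(vals), config=cfg)
        ref = brute_force_detect(t, np.array(vals), cfg.r_b, cfg.r_a)
        assert len(mine) == len(ref)

    def test_threshold_monotonicity(self, rng):
        r = rng.uniform(0.85, 0.99, size=5000)
        t = np.arange(len(r), dtype=float)

        def count(r_b, r_a):
            c = ev.DetectionConfig(r_b=r_b, r_a=r_a,
                                   oq_edges=tuple(round(r_b + 0.01 * i, 4)
                                                  for i in range(4)))
            return len(ev.detect_events(t, r, config=c))

        # raising r_b never increases event count
        assert count(0.94, 0.90) <= count(0.92, 0.90)
        # raising r_a toward r_b never decreases count (more splits)
        assert count(0.92, 0.915) >= count(0.92, 0.90)

    def test_interpolated_boundaries_bracket_crossing(self):
        t, r = series([0.90, 0.94, 0.94, 0.90], dt=2.0)
        out = ev.detect_events(t, r, config=CFG, interpolate=True)
        (e,) = out
        assert 0.0 < e.t1 < 2.0 and 4.0 < e.t2 < 6.0


class TestOQuality:
    @pytest.mark.parametrize("max_r,expected", [
        (0.925, 1), (0.93, 2), (0.9399, 2), (0.94, 3), (0.949, 3),
        (0.95, 4), (0.99, 4), (0.92, 1),
    ])
    def test_bin_edges(self, max_r, expected):
        e = ev.OscillatoryEvent("", 0, 1, max_r, 12.0, 12.0)
        assert ev.assign_oquality(e, CFG) == expected

    def test_below_threshold_rejected(self):
        e = ev.OscillatoryEvent("", 0, 1, 0.919, 12.0, 12.0)
        with pytest.raises(ValueError):
            ev.assign_oquality(e, CFG)

    def test_partition_sums_to_total(self, rng):
        r = rng.uniform(0.80, 0.99, size=8000)
        t = np.arange(len(r), dtype=float)
        out = ev.detect_events(t, r, config=CFG)
        counts = {}
        for e in out:
            assert e.oq in (1, 2, 3, 4)
            counts[e.oq] = counts.get(e.oq, 0) + 1
        assert sum(counts.values()) == len(out)


class TestSelectSpindles:
    def test_band_filter(self):
        keep = ev.OscillatoryEvent("", 0, 1, 0.93, 12.3, 12.3)
        drop = ev.OscillatoryEvent("", 0, 1, 0.93, 9.5, 9.5)
        assert ev.select_spindles([keep, drop]) == [keep]

    def test_labeled_schedule_mostly_spindles(self, rng):
        """Sigma-band bursts are kept, delta bursts dropped, >=90% correct."""
        evs = []
        truth = []
        for _ in range(100):
            is_spindle = rng.random() < 0.5
            f = rng.uniform(10.5, 14.5) if is_spindle else rng.uniform(1, 4)
            evs.append(ev.OscillatoryEvent("", 0, 1, 0.93, f, f))
            truth.append(is_spindle)
        selected = ev.select_spindles(evs)
        correct = sum(1 for e, t in zip(evs, truth) if (e in selected) == t)
        assert correct >= 90


class TestEventStatistics:
    def test_incidence_arithmetic(self):
        hyp = Hypnogram(["NREM"] * 150, 4.0)  # 10 NREM minutes
        evs = [ev.OscillatoryEvent("", 10 * i, 10 * i + 1, 0.93, 12, 12, oq=1)
               for i in range(30)]
        stats = ev.event_statistics(evs, hyp)
        assert stats["incidence_per_min"] == pytest.approx(3.0)

    def test_empty_events(self):
        hyp = Hypnogram(["NREM"] * 15, 4.0)
        stats = ev.event_statistics([], hyp)
        assert stats["n_events"] == 0
        assert len(stats["durations"]) == 0

    def test_zero_state_minutes_undefined(self):
        hyp = Hypnogram(["Wake"] * 15, 4.0)
        stats = ev.event_statistics([], hyp)
        assert np.isnan(stats["incidence_per_min"])

    def test_poisson_rate_recovery(self, rng):
        lam = 5.0  # per minute
        dur_min = 60.0
        n = rng.poisson(lam * dur_min)
        times = np.sort(rng.uniform(0, dur_min * 60, size=n))
        hyp = Hypnogram(["NREM"] * int(dur_min * 15), 4.0)
        evs = [ev.OscillatoryEvent("", t, t + 0.5, 0.93, 12, 12, oq=1)
               for t in times]
        stats = ev.event_statistics(evs, hyp)
        sigma = np.sqrt(lam / dur_min)
        assert abs(stats["incidence_per_min"] - lam) < 3 * sigma


class TestConditionedSpectra:
    def _spectra(self, power, n_ep):
        freqs = np.arange(0, 20.25, 0.25)
        return EpochSpectra(frequencies=freqs,
                            power=np.tile(power, (n_ep, 1)),
                            epoch_times=np.arange(n_ep) * 4.0)

    def test_identical_groups_flat_100(self):
        sp = self._spectra(np.ones(81), 10)
        evs = [ev.OscillatoryEvent("", 4 * i + 1, 4 * i + 2, 0.93, 12, 12)
               for i in range(5)]
        ratio = ev.conditioned_spectra(sp, evs)
        np.testing.assert_allclose(ratio, 100.0)

    def test_constructed_coupling_shows_sigma_peak(self):
        freqs = np.arange(0, 20.25, 0.25)
        base = np.ones((20, len(freqs)))
        sigma_bins = (freqs >= 10) & (freqs <= 15)
        evs = []
        for i in range(10):  # events in even epochs, excess sigma power there
            base[2 * i, sigma_bins] *= 3.0
            evs.append(ev.OscillatoryEvent("", 8 * i + 1, 8 * i + 2,
                                           0.96, 12.5, 12.5))
        sp = EpochSpectra(frequencies=freqs, power=base,
                          epoch_times=np.arange(20) * 4.0)
        ratio = ev.conditioned_spectra(sp, evs)
        assert ratio[sigma_bins].mean() > 250
        off = (freqs < 8)
        np.testing.assert_allclose(ratio[off], 100.0)

    def test_no_overlapping_epochs_errors(self):
        sp = self._spectra(np.ones(81), 5)
        far = [ev.OscillatoryEvent("", 1000.0, 1001.0, 0.93, 12, 12)]
        with pytest.raises(ValueError):
            ev.conditioned_spectra(sp, far)
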