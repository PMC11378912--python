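"""Co-occurrence grouping, CSD, laminar profiles, spike-phase coupling."""

import numpy as np
import pytest
from scipy import signal as sps
from scipy.special import i0, i1

from spindleq import laminar as lam
from spindleq.events import OscillatoryEvent


def ev(center, channel="ch0", max_r=0.95, oq=4):
    return OscillatoryEvent(channel, center - 0.5, center + 0.5, max_r,
                            12.5, 12.5, oq=oq)


def brute_force_groups(centers, window):
    """Union-find transitive closure over all pairs within the window."""
    n = len(centers)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if abs(centers[i] - centers[j]) <= window:
                parent[find(i)] = find(j)
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    return sorted(sorted(g) for g in groups.values())


class TestGroupCooccurring:
    def test_within_window_one_spindle(self):
        out = lam.group_cooccurring([ev(10.0, "ch1"), ev(10.3, "ch2")], 0.5)
        assert len(out) == 1
        assert out[0].n_channels == 2

    def test_outside_window_two_spindles(self):
        out = lam.group_cooccurring([ev(10.0, "ch1"), ev(10.6, "ch2")], 0.5)
        assert len(out) == 2

    def test_transitive_chaining(self):
        out = lam.group_cooccurring(
            [ev(10.0, "a"), ev(10.4, "b"), ev(10.8, "c")], 0.5)
        assert len(out) == 1 and out[0].n_channels == 3

    def test_max_oq_assigned(self):
        events = [ev(10.0, "a", 0.925, 1), ev(10.2, "b", 0.96, 4)]
        (u,) = lam.group_cooccurring(events, 0.5)
        assert u.max_oq == 4 and u.max_r == 0.96
        assert u.max_oq_channel == "b"

    def test_matches_brute_force_closure(self, rng):
        centers = np.sort(rng.uniform(0, 500, size=1000))
        events = [ev(c, f"ch{i % 8}") for i, c in enumerate(centers)]
        mine = lam.group_cooccurring(events, 0.5)
        mine_sets = sorted(sorted(events.index(m) for m in u.members)
                           for u in mine)
        assert mine_sets == brute_force_groups(centers, 0.5)


class TestSpatialExtent:
    GEOM = {f"ch{i}": (100.0 * i,) for i in range(16)}

    def test_single_channel(self):
        (u,) = lam.group_cooccurring([ev(10.0, "ch3")], 0.5)
        frac, radius = lam.spatial_extent(u, 16, self.GEOM)
        assert frac == 1 / 16 and radius == 0.0

    def test_radius_from_max_oq_channel(self):
        events = [ev(10.0, f"ch{i}", 0.93, 1) for i in (0, 1, 3, 4)]
        events.append(ev(10.1, "ch2", 0.97, 4))
        (u,) = lam.group_cooccurring(events, 0.5)
        frac, radius = lam.spatial_extent(u, 16, self.GEOM)
        assert radius == 200.0  # ch2 -> ch0 or ch4
        assert frac == 5 / 16

    def test_no_geometry_fraction_only(self):
        (u,) = lam.group_cooccurring([ev(10.0, "ch3")], 0.5)
        frac, radius = lam.spatial_extent(u, 16, None)
        assert frac == 1 / 16 and radius is None


class TestCSD:
    def test_affine_potential_zero_csd(self):
        depth = np.arange(8)[:, None]
        v = 3.0 * depth + 1.0 + np.zeros((8, 100))
        _, out = lam.csd(v, 100.0, smooth_factor=1)
        np.testing.assert_allclose(out, 0.0, atol=1e-9)

    def test_quadratic_potential_constant_csd(self):
        depth = np.arange(8, dtype=float)[:, None]
        v = depth**2 + np.zeros((8, 50))
        _, out = lam.csd(v, 1.0, smooth_factor=1)
        np.testing.assert_allclose(out, -2.0, atol=1e-9)

    def test_dipole_source_sink_pair(self):
        # gaussian sink at channel 5, source at channel 10
        z = np.arange(16, dtype=float)
        profile = np.exp(-((z - 5) ** 2) / 2) - np.exp(-((z - 10) ** 2) / 2)
        # potential = double spatial integral of -CSD; build directly:
        v = np.cumsum(np.cumsum(-profile)) [:, None] + np.zeros((16, 10))
        depths, out = lam.csd(v, 1.0, smooth_factor=1)
        prof = out[:, 0]
        # discrete double integral shifts the grid by two channels
        assert prof.argmax() == np.argmax(profile) - 2
        assert prof.argmin() == np.argmin(profile) - 2

    def test_smoothing_refines_depth_grid(self):
        v = np.random.default_rng(0).standard_normal((8, 20))
        depths, out = lam.csd(v, 100.0, smooth_factor=10)
        assert len(depths) == (6 - 1) * 10 + 1
        assert out.shape == (len(depths), 20)

    def test_too_few_channels(self):
        with pytest.raises(ValueError):
            lam.csd(np.zeros((2, 10)), 100.0)


class TestLaminarRMS:
    def test_constant_signal(self):
        out = lam.laminar_rms(np.full((2, 1000), -3.0), 256.0, ["L4", "L5"])
        assert out == {"L4": 3.0, "L5": 3.0}

    def test_unit_sinusoid_rms(self):
        fs = 256.0
        t = np.arange(int(2 * fs)) / fs
        x = np.sin(2 * np.pi * 12.5 * t)[None, :]
        out = lam.laminar_rms(x, fs, ["L4"])
        assert out["L4"] == pytest.approx(1 / np.sqrt(2), rel=0.01)

    def test_layer_gain_profile_recovered(self, rng):
        gains = {"L2/3": 1.0, "L4": 3.0, "L5": 2.0}
        base = rng.standard_normal(512)
        epoch = np.stack([g * base for g in gains.values()])
        out = lam.laminar_rms(epoch, 256.0, list(gains))
        ratios = np.array(list(out.values())) / out["L2/3"]
        np.testing.assert_allclose(ratios, [1.0, 3.0, 2.0], rtol=1e-6)


class TestProfilePCA:
    def test_rank_one_profiles(self, rng):
        template = np.array([1.0, 3.0, 2.0, 0.5])
        profiles = np.outer(rng.uniform(0.5, 2.0, 50), template)
        out = lam.profile_pca(profiles)
        assert out["explained_variance_ratio"][0] == pytest.approx(1.0)

    def test_two_template_mixture(self, rng):
        a = np.array([1.0, 0.0, 0.0, 0.0])
        b = np.array([0.0, 1.0, 0.0, 0.0])
        profiles = (np.sqrt(0.8) * rng.standard_normal((4000, 1)) * a
                    + np.sqrt(0.2) * rng.standard_normal((4000, 1)) * b)
        evr = lam.profile_pca(profiles)["explained_variance_ratio"]
        np.testing.assert_allclose(evr[:2], [0.8, 0.2], atol=0.03)

    def test_isotropic_noise_flat_spectrum(self, rng):
        evr = lam.profile_pca(rng.standard_normal((5000, 6)))[
            "explained_variance_ratio"]
        np.testing.assert_allclose(evr, 1 / 6, atol=0.03)


class TestSpikePhase:
    def test_all_spikes_one_phase(self):
        t = np.arange(0, 10, 1 / 256)
        phase = np.angle(np.exp(1j * 2 * np.pi * 12.5 * t))
        # spike exactly when phase = pi/4
        spikes = (1 / 8 + np.arange(5, 100)) / 12.5
        spikes = spikes[spikes < t[-1]]
        st = lam.spike_phase_coupling(spikes, t, phase)
        assert st.resultant_length > 0.99
        assert abs(st.mean_angle - np.pi / 4) < 0.05

    def test_uniform_phases_null(self, rng):
        angles = rng.uniform(-np.pi, np.pi, 10000)
        # feed angles directly through a dense phase series
        t = np.linspace(0, 1, len(angles))
        st = lam.spike_phase_coupling(t, t, angles)
        assert st.resultant_length < 0.05

    def test_rayleigh_uniform_rarely_significant(self, rng):
        n_sig = 0
        for _ in range(100):
            p = lam.rayleigh_test(rng.uniform(-np.pi, np.pi, 50))
            n_sig += p < 0.05
        assert n_sig <= 10

    def test_von_mises_concentration_matches_bessel_ratio(self, rng):
        kappa = 2.0
        angles = rng.vonmises(0.7, kappa, size=5000)
        _, R = lam.circular_mean_resultant(angles)
        mean, _ = lam.circular_mean_resultant(angles)
        assert abs(R - i1(kappa) / i0(kappa)) < 0.05
        assert abs(mean - 0.7) < 0.1

    def test_rayleigh_matches_pingouin(self, rng):
        from pingouin import circ_rayleigh

        for n in (10, 30, 200):
            a = rng.vonmises(0.0, 0.5, size=n)
            z, p_ref = circ_rayleigh(a)
            p = lam.rayleigh_test(a)
            assert p == pytest.approx(p_ref, rel=0.05, abs=5e-3)

    def test_rotation_equivariance(self, rng):
        a = rng.vonmises(0.3, 1.0, size=500)
        t = np.linspace(0, 1, 500)
        base = lam.spike_phase_coupling(t, t, a)
        rot = lam.spike_phase_coupling(t, t, np.mod(a + 1.0 + np.pi,
                                                    2 * np.pi) - np.pi)
        assert rot.resultant_length == pytest.approx(base.resultant_length,
                                                     abs=1e-6)
        diff = (rot.mean_angle - base.mean_angle - 1.0 + np.pi) % (2 * np.pi) - np.pi
        assert abs(diff) < 1e-6

    def test_event_window_restriction_and_empty(self):
        t = np.linspace(0, 10, 1000)
        st = lam.spike_phase_coupling([1.0, 5.0], t, np.zeros(1000),
                                      event_windows=[(4.0, 6.0)])
        assert st.n_spikes == 1
        empty = lam.spike_phase_coupling([], t, np.zeros(1000))
        assert empty.n_spikes == 0 and np.isnan(empty.resultant_length)
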