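"""Multichannel spindle analysis: co-occurrence, CSD, laminar profiles,
profile PCA, and spike-phase coupling.

Per-channel events whose centers fall within 500 ms of each other along a
transitive chain are one *unique spindle*; it inherits the maximum
o-Quality across member channels and a spatial extent.  The current source
density (CSD) is the negative second spatial derivative of the laminar LFP,
optionally cubic-interpolated across depth; laminar profiles are 1-s RMS
magnitudes per layer around the spindle center, summarised across spindles
by PCA.  Spike timing relative to the 10-15 Hz phase is quantified with
circular statistics (mean angle, resultant length, Rayleigh uniformity
test).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy.interpolate import interp1d

__all__ = [
    "UniqueSpindle", "PhaseCouplingStats", "group_cooccurring",
    "spatial_extent", "csd", "laminar_rms", "profile_pca",
    "spike_phase_coupling", "rayleigh_test",
]


@dataclass
class UniqueSpindle:
    members: list                     # OscillatoryEvent per channel
    center: float                     # consensus center (s), mean of members
    max_oq: int | None
    max_r: float
    n_channels: int

    @property
    def max_oq_channel(self) -> str:
        return max(self.members, key=lambda e: e.max_r).channel


@dataclass
class PhaseCouplingStats:
    mean_angle: float                 # radians
    resultant_length: float           # in [0, 1]
    p_value: float                    # Rayleigh uniformity test
    n_spikes: int


def group_cooccurring(events, window: float = 0.5) -> list[UniqueSpindle]:
    """Chain per-channel events into unique cross-channel spindles.

    Chaining is transitive: centers sorted in time belong to one group as
    long as each consecutive gap is at most ``window`` (equivalent to the
    transitive closure of the pairwise within-window relation on a line).
    """
    events = sorted(events, key=lambda e: e.center)
    if not events:
        return []
    groups, current = [], [events[0]]
    for e in events[1:]:
        if e.center - current[-1].center <= window:
            current.append(e)
        else:
            groups.append(current)
            current = [e]
    groups.append(current)
    out = []
    for g in groups:
        oqs = [e.oq for e in g if getattr(e, "oq", None) is not None]
        out.append(UniqueSpindle(
            members=list(g),
            center=float(np.mean([e.center for e in g])),
            max_oq=max(oqs) if oqs else None,
            max_r=float(max(e.max_r for e in g)),
            n_channels=len({e.channel for e in g})))
    return out


def spatial_extent(us: UniqueSpindle, n_total: int,
                   geometry: dict | None = None):
    """Channel fraction and spread radius (µm) of a unique spindle.

    ``geometry`` maps channel label -> position (scalar depth or 2-D tuple,
    µm).  Radius is the maximum distance of any member channel from the
    maximum-r channel; without geometry only the fraction is returned.
    """
    fraction = us.n_channels / n_total
    if geometry is None:
        return fraction, None
    ref = np.atleast_1d(np.asarray(geometry[us.max_oq_channel], dtype=float))
    radius = 0.0
    for e in us.members:
        pos = np.atleast_1d(np.asarray(geometry[e.channel], dtype=float))
        radius = max(radius, float(np.linalg.norm(pos - ref)))
    return fraction, radius


def csd(epoch: np.ndarray, spacing: float, *, smooth_factor: int = 10,
        sigma: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    """Current source density of a laminar LFP epoch.

    CSD_i = -sigma * (V_{i-1} - 2 V_i + V_{i+1}) / h^2 for interior
    channels (one-sided edge estimates are dropped rather than fabricated);
    with ``smooth_factor`` > 1 the profile is cubic-interpolated onto a
    depth grid that many times denser.

    Returns (depths relative to the first channel in the same units as
    ``spacing``, csd array of shape (n_depths, n_times)).
    """
    v = np.atleast_2d(np.asarray(epoch, dtype=float))
    if v.shape[0] < 3:
        raise ValueError("CSD needs at least 3 channels")
    raw = -sigma * (v[:-2] - 2 * v[1:-1] + v[2:]) / spacing**2
    depths = spacing * np.arange(1, v.shape[0] - 1)
    if smooth_factor and smooth_factor > 1 and raw.shape[0] >= 4:
        fine = np.linspace(depths[0], depths[-1],
                           (len(depths) - 1) * smooth_factor + 1)
        raw = interp1d(depths, raw, axis=0, kind="cubic")(fine)
        depths = fine
    return depths, raw


def laminar_rms(epoch: np.ndarray, fs: float, layer_map: list[str],
                center: float | None = None, window: float = 1.0) -> dict:
    """Per-layer RMS magnitude in a window centered on the spindle.

    ``epoch`` is (n_channels, n_samples); ``layer_map`` labels each channel
    row; ``center`` is seconds into the epoch (middle when None).  Per-layer
    value = mean over that layer's channels of each channel's RMS.
    """
    v = np.atleast_2d(np.asarray(epoch, dtype=float))
    if len(layer_map) != v.shape[0]:
        raise ValueError("layer_map must label every channel")
    n = v.shape[1]
    c = n / 2 if center is None else center * fs
    half = window * fs / 2
    i0, i1 = max(0, int(round(c - half))), min(n, int(round(c + half)))
    if i1 <= i0:
        raise ValueError("window does not overlap the epoch")
    rms = np.sqrt(np.mean(v[:, i0:i1] ** 2, axis=1))
    out = {}
    for layer in dict.fromkeys(layer_map):      # preserve order
        idx = [i for i, l in enumerate(layer_map) if l == layer]
        out[layer] = float(rms[idx].mean())
    return out


def profile_pca(profiles: np.ndarray) -> dict:
    """PCA of laminar magnitude profiles across spindles.

    ``profiles`` is (n_spindles, n_layers).  Returns explained-variance
    fractions (descending), the component loadings, and the eigenvalues of
    the profile covariance; zero-variance dimensions are retained (they
    contribute zero-variance components).
    """
    x = np.atleast_2d(np.asarray(profiles, dtype=float))
    if x.shape[0] < 2:
        raise ValueError("need at least 2 profiles")
    from sklearn.decomposition import PCA

    pca = PCA()
    pca.fit(x)
    return {"explained_variance_ratio": pca.explained_variance_ratio_,
            "components": pca.components_,
            "eigenvalues": pca.explained_variance_}


def circular_mean_resultant(angles: np.ndarray) -> tuple[float, float]:
    z = np.exp(1j * np.asarray(angles, dtype=float)).mean()
    return float(np.angle(z)), float(np.abs(z))


def rayleigh_test(angles: np.ndarray) -> float:
    """Rayleigh uniformity test p-value.

    Uses the exact-style small-sample expression
    p = exp(sqrt(1 + 4n + 4(n^2 - Rn^2)) - (1 + 2n)) for n < 50 and the
    large-sample approximation p = exp(-n R^2) otherwise.
    """
    angles = np.asarray(angles, dtype=float)
    n = len(angles)
    if n == 0:
        raise ValueError("no angles")
    _, R = circular_mean_resultant(angles)
    Rn = n * R
    if n < 50:
        p = np.exp(np.sqrt(1 + 4 * n + 4 * (n**2 - Rn**2)) - (1 + 2 * n))
    else:
        p = np.exp(-n * R**2)
    return float(min(max(p, np.finfo(float).tiny), 1.0))


def spike_phase_coupling(spike_times, phase_times, phase_series,
                         event_windows=None) -> PhaseCouplingStats:
    """Circular statistics of spike times against the sigma-band phase.

    The instantaneous phase (from the Hilbert transform of the 10-15 Hz
    filtered trace) is linearly interpolated at each spike time; with
    ``event_windows`` (list of (lo, hi)) only spikes inside those windows
    are used, e.g. within 1 s of each spindle center.
    """
    spikes = np.asarray(spike_times, dtype=float)
    if event_windows is not None:
        mask = np.zeros(len(spikes), dtype=bool)
        for lo, hi in event_windows:
            mask |= (spikes >= lo) & (spikes <= hi)
        spikes = spikes[mask]
    if len(spikes) == 0:
        return PhaseCouplingStats(np.nan, np.nan, np.nan, 0)
    pt = np.asarray(phase_times, dtype=float)
    unwrapped = np.unwrap(np.asarray(phase_series, dtype=float))
    phases = np.mod(np.interp(spikes, pt, unwrapped) + np.pi, 2 * np.pi) - np.pi
    mean_angle, R = circular_mean_resultant(phases)
    return PhaseCouplingStats(mean_angle=mean_angle, resultant_length=R,
                              p_value=rayleigh_test(phases),
                              n_spikes=len(spikes))
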