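"""Synthetic NREM recordings with known ground truth.

The generator emulates the statistical structure the analyses assume:
1/f-like background activity, transient spindle bursts realized as
stochastically driven second-order resonators whose AR pole (radius r0,
frequency f0) is the ground-truth parameter the detector should recover,
high-amplitude 0.5-4 Hz slow waves that can precede bursts with a
configurable lag and per-radius coupling probability, spatial decay of
burst amplitude across laminar channels with an extent that grows with r0,
an EMG channel with stimulus-evoked variance transients, and REM-like
theta segments for gating tests.  Everything scheduled is logged in a
SyntheticGroundTruth so recovery can be scored exactly.

Burst synthesis uses a driven resonator rather than an enveloped sinusoid
so that the generating process has a well-defined true AR pole — the
quantity the whole damping analysis estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ChannelInfo, Hypnogram, Recording

__all__ = [
    "SimulationConfig", "ScheduledBurst", "ScheduledSlowWave",
    "SyntheticGroundTruth", "gen_background", "gen_burst", "gen_recording",
    "draw_burst_parameters",
]


@dataclass(frozen=True)
class SimulationConfig:
    fs: float = 256.0                 # Hz, acquisition rate
    analysis_fs: float = 128.0        # Hz at which pole radii are defined
    duration: float = 300.0           # s
    n_lfp: int = 8                    # laminar LFP channels
    spacing_um: float = 100.0         # inter-channel spacing
    with_eeg: bool = True             # add frontal + occipital EEG
    with_emg: bool = True
    # background: power spectral density ~ 1/f^slope
    background_slope: float = 1.0
    background_sd: float = 10.0       # µV
    shared_fraction: float = 0.3      # channel-shared background component
    # burst schedule (NREM only)
    burst_rate_per_min: float = 8.0
    burst_duration_mean: float = 0.9  # s (lognormal, sigma below)
    burst_duration_sigma: float = 0.3
    r0_range: tuple[float, float] = (0.90, 0.99)
    f0_range: tuple[float, float] = (10.0, 15.0)
    amplitude_median: float = 30.0    # µV (lognormal)
    amplitude_sigma: float = 0.4      # lognormal shape
    r2_amplitude_coupling: float = 0.08  # weak r-amplitude association
    # spatial extent: channels spanned grows linearly with r0 over r0_range
    extent_min_channels: int = 1
    # slow waves
    sw_rate_per_min: float = 10.0
    sw_amplitude: float = 60.0        # µV typical peak
    sw_freq: float = 1.0              # Hz of the wave shape
    sw_spindle_lag: float = 0.1       # s, SW peak -> coupled burst onset
    sw_coupling_prob: tuple[float, float, float, float] = (0.0, 0.0, 0.0, 0.0)
    # hypnogram: repeating template of per-epoch labels
    epoch_length: float = 4.0
    hypnogram_template: tuple[str, ...] = tuple(
        ["NREM"] * 40 + ["REM"] * 5 + ["Wake"] * 5)
    # EMG / theta
    emg_sd: float = 5.0               # µV baseline
    emg_twitch_gain: float = 5.0      # variance multiplier during a twitch
    emg_twitch_duration: float = 0.2  # s
    theta_freq: float = 7.5           # Hz in REM epochs (occipital EEG)
    theta_amplitude: float = 25.0     # µV
    seed: int = 0


@dataclass(frozen=True)
class ScheduledBurst:
    onset: float                      # s
    duration: float
    r0: float
    f0: float
    amplitude: float                  # µV RMS-equivalent peak (RMS * sqrt 2)
    channels: tuple[str, ...]
    coupled_to_sw: bool = False


@dataclass(frozen=True)
class ScheduledSlowWave:
    peak_time: float
    amplitude: float


@dataclass
class SyntheticGroundTruth:
    bursts: list[ScheduledBurst]
    slow_waves: list[ScheduledSlowWave]
    stimuli: list[float] = field(default_factory=list)
    config: SimulationConfig | None = None

    def bursts_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "onset": b.onset, "duration": b.duration, "r0": b.r0,
            "f0": b.f0, "amplitude": b.amplitude,
            "n_channels": len(b.channels), "coupled": b.coupled_to_sw,
        } for b in self.bursts])


def gen_background(n_samples: int, fs: float, slope: float = 1.0,
                   sd: float = 10.0, rng=None) -> np.ndarray:
    """Stationary 1/f^slope Gaussian noise scaled to a target SD (µV)."""
    rng = np.random.default_rng(rng)
    white = rng.standard_normal(n_samples)
    if slope == 0:
        return sd * white
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n_samples, 1 / fs)
    scale = np.ones_like(f)
    scale[1:] = f[1:] ** (-slope / 2)
    scale[0] = 0.0
    x = np.fft.irfft(spec * scale, n=n_samples)
    s = x.std()
    return sd * x / s if s > 0 else x


def gen_burst(r0: float, f0: float, duration: float, amplitude: float,
              fs: float, rng=None, taper: float = 0.05) -> np.ndarray:
    """A damped-oscillator burst: driven AR(2) resonator waveform.

    The resonator x_n = a1 x_{n-1} + a2 x_{n-2} + w_n with
    a1 = 2 r0 cos(2 pi f0 / fs), a2 = -r0^2 has its AR pole exactly at
    (r0, f0).  The waveform is scaled so its RMS equals
    ``amplitude``/sqrt(2) (sinusoid-equivalent peak amplitude) and given
    short cosine edge ramps (``taper`` seconds) to avoid insertion clicks.
    """
    if not 0 < r0 < 1:
        raise ValueError("pole radius r0 must be in (0, 1)")
    if f0 >= fs / 2:
        raise ValueError("burst frequency must be below Nyquist")
    n = int(round(duration * fs))
    if n == 0 or amplitude == 0:
        return np.zeros(n)
    rng = np.random.default_rng(rng)
    from scipy import signal as sps

    a1 = 2 * r0 * np.cos(2 * np.pi * f0 / fs)
    a2 = -(r0**2)
    burn = int(round(4.0 / (1 - r0)))   # samples to reach stationarity
    w = rng.standard_normal(n + burn)
    x = sps.lfilter([1.0], [1.0, -a1, -a2], w)[burn:]
    rms = x.std()
    if rms > 0:
        x = x * (amplitude / np.sqrt(2)) / rms
    ramp = int(round(taper * fs))
    if ramp > 0 and 2 * ramp < n:
        win = 0.5 * (1 - np.cos(np.pi * np.arange(ramp) / ramp))
        x[:ramp] *= win
        x[-ramp:] *= win[::-1]
    return x


def draw_burst_parameters(cfg: SimulationConfig, rng, n: int = 1):
    """Draw (r0, f0, duration, amplitude) arrays for n scheduled bursts.

    Radii are uniform over ``r0_range``, frequencies uniform over
    ``f0_range``, durations lognormal (clipped to 0.4-2.5 s), amplitudes
    lognormal with a population log-scale correlation to r0 set by
    ``r2_amplitude_coupling`` (the weak r-amplitude association).
    """
    rng = np.random.default_rng(rng)
    r0 = rng.uniform(*cfg.r0_range, size=n)
    f0 = rng.uniform(*cfg.f0_range, size=n)
    dur = np.exp(rng.normal(np.log(cfg.burst_duration_mean),
                            cfg.burst_duration_sigma, size=n))
    dur = np.clip(dur, 0.4, 2.5)
    rho = np.sqrt(np.clip(cfg.r2_amplitude_coupling, 0.0, 1.0))
    z_r = (r0 - np.mean(cfg.r0_range)) / (
        (cfg.r0_range[1] - cfg.r0_range[0]) / np.sqrt(12))
    z = rho * z_r + np.sqrt(1 - rho**2) * rng.standard_normal(n)
    amp = cfg.amplitude_median * np.exp(cfg.amplitude_sigma * z)
    return r0, f0, dur, amp


def _sw_waveform(amplitude: float, freq: float, fs: float) -> np.ndarray:
    """One negative-positive-negative slow-wave cycle, positive peak = amplitude."""
    n = int(round(fs / freq * 1.5))
    t = np.linspace(0, 1.5 / freq, n, endpoint=False)
    shape = np.sin(2 * np.pi * freq * t + np.pi)  # starts negative
    shape *= np.hanning(n)
    peak = shape.max()
    return amplitude * shape / peak if peak > 0 else shape


def _oq_of_r0(r0: float) -> int:
    return int(min(np.searchsorted([0.92, 0.93, 0.94, 0.95], r0, side="right"), 4))


def gen_recording(config: SimulationConfig = SimulationConfig(),
                  stimulus_times=None):
    """Generate a (Recording, Hypnogram, SyntheticGroundTruth) triple.

    Bursts arrive as a Poisson process at ``burst_rate_per_min`` within
    NREM epochs; each draws an independent pole radius, frequency,
    duration, and a lognormal amplitude correlated with the radius at the
    configured population R^2.  The burst is placed on a contiguous block
    of LFP channels whose size grows linearly with r0 (spatial extent
    rule), with amplitude decaying away from a random center channel, and
    is mirrored at reduced gain onto the frontal EEG.  Slow waves arrive
    independently at ``sw_rate_per_min``; with per-oQ probability a burst
    is additionally inserted at lag ``sw_spindle_lag`` after a wave's peak.
    REM epochs receive occipital theta; stimuli evoke EMG variance
    transients.  All randomness derives from ``config.seed``.
    """
    cfg = config
    fs = cfg.fs
    n = int(round(cfg.duration * fs))
    ss = np.random.SeedSequence(cfg.seed)
    r_bg, r_sched, r_burst, r_sw, r_emg = [np.random.default_rng(s)
                                           for s in ss.spawn(5)]

    # hypnogram from repeating template
    n_epochs = int(np.ceil(cfg.duration / cfg.epoch_length))
    template = list(cfg.hypnogram_template)
    labels = [template[i % len(template)] for i in range(n_epochs)]
    hyp = Hypnogram(labels=labels, epoch_length=cfg.epoch_length)

    chan_info = [ChannelInfo(label=f"LFP{i}", modality="LFP", site="S1",
                             depth=cfg.spacing_um * i)
                 for i in range(cfg.n_lfp)]
    if cfg.with_eeg:
        chan_info += [ChannelInfo("EEG Frontal", "EEG", "frontal"),
                      ChannelInfo("EEG Occipital", "EEG", "occipital")]
    if cfg.with_emg:
        chan_info.append(ChannelInfo("EMG", "EMG", "nuchal"))
    n_ch = len(chan_info)
    labels_all = [c.label for c in chan_info]

    shared = gen_background(n, fs, cfg.background_slope, 1.0, r_bg)
    data = np.empty((n_ch, n))
    for i, ci in enumerate(chan_info):
        if ci.modality == "EMG":
            data[i] = cfg.emg_sd * r_bg.standard_normal(n)
            continue
        own = gen_background(n, fs, cfg.background_slope, 1.0, r_bg)
        mix = (np.sqrt(cfg.shared_fraction) * shared
               + np.sqrt(1 - cfg.shared_fraction) * own)
        data[i] = cfg.background_sd * mix / mix.std()

    # NREM epoch spans for scheduling
    nrem_spans = [(i * cfg.epoch_length, min((i + 1) * cfg.epoch_length, cfg.duration))
                  for i, l in enumerate(labels) if l == "NREM"
                  if i * cfg.epoch_length < cfg.duration]
    nrem_seconds = sum(b - a for a, b in nrem_spans)

    def sample_nrem_time(rng) -> float:
        tau = rng.uniform(0, nrem_seconds)
        for a, b in nrem_spans:
            if tau < b - a:
                return a + tau
            tau -= b - a
        return nrem_spans[-1][1] - 1e-6

    def draw_burst_params(rng):
        r0, f0, dur, amp = draw_burst_parameters(cfg, rng, 1)
        return float(r0[0]), float(f0[0]), float(dur[0]), float(amp[0])

    def extent_channels(r0, rng):
        lo, hi = cfg.r0_range
        frac = (r0 - lo) / (hi - lo)
        n_span = cfg.extent_min_channels + int(round(frac * (cfg.n_lfp - cfg.extent_min_channels)))
        n_span = int(np.clip(n_span, 1, cfg.n_lfp))
        c0 = int(rng.integers(0, cfg.n_lfp - n_span + 1))
        return list(range(c0, c0 + n_span))

    def insert_burst(onset, r0, f0, dur, amp, rng) -> ScheduledBurst | None:
        i0 = int(round(onset * fs))
        # r0 is defined at the analysis rate; a pole radius is
        # exp(-gamma/fs), so the acquisition-rate radius is a power of it
        r_acq = r0 ** (cfg.analysis_fs / fs)
        wave = gen_burst(r_acq, f0, dur, amp, fs, rng)
        if i0 + len(wave) > n or len(wave) == 0:
            return None
        idx = extent_channels(r0, rng)
        center = idx[len(idx) // 2]
        for ch in idx:
            gain = np.exp(-abs(ch - center) / max(len(idx) / 2, 1))
            data[ch, i0 : i0 + len(wave)] += gain * wave
        if cfg.with_eeg:
            data[labels_all.index("EEG Frontal"), i0 : i0 + len(wave)] += 0.5 * wave
        return ScheduledBurst(onset=onset, duration=dur, r0=r0, f0=f0,
                              amplitude=amp,
                              channels=tuple(f"LFP{c}" for c in idx))

    # independent burst schedule
    bursts: list[ScheduledBurst] = []
    n_bursts = r_sched.poisson(cfg.burst_rate_per_min * nrem_seconds / 60.0)
    onsets = np.sort([sample_nrem_time(r_sched) for _ in range(n_bursts)])
    last_end = -np.inf
    for onset in onsets:
        r0, f0, dur, amp = draw_burst_params(r_sched)
        if onset < last_end + 0.2:    # oversubscribed schedule: prune overlap
            continue
        b = insert_burst(onset, r0, f0, dur, amp, r_burst)
        if b is not None:
            bursts.append(b)
            last_end = onset + dur

    # slow waves, optionally followed by a coupled burst
    sws: list[ScheduledSlowWave] = []
    n_sw = r_sched.poisson(cfg.sw_rate_per_min * nrem_seconds / 60.0)
    sw_shape = _sw_waveform(1.0, cfg.sw_freq, fs)
    peak_off = int(np.argmax(sw_shape))
    for peak_t in np.sort([sample_nrem_time(r_sw) for _ in range(n_sw)]):
        amp = cfg.sw_amplitude * float(np.exp(r_sw.normal(0, 0.25)))
        i0 = int(round(peak_t * fs)) - peak_off
        if i0 < 0 or i0 + len(sw_shape) > n:
            continue
        for i, ci in enumerate(chan_info):
            if ci.modality in ("LFP", "EEG") and ci.site != "occipital":
                data[i, i0 : i0 + len(sw_shape)] += amp * sw_shape
        sws.append(ScheduledSlowWave(peak_time=peak_t, amplitude=amp))
        r0, f0, dur, amp_b = draw_burst_params(r_sw)
        p = cfg.sw_coupling_prob[max(_oq_of_r0(r0), 1) - 1]
        if r_sw.random() < p:
            onset = peak_t + cfg.sw_spindle_lag
            b = insert_burst(onset, r0, f0, dur, amp_b, r_burst)
            if b is not None:
                bursts.append(ScheduledBurst(**{**b.__dict__, "coupled_to_sw": True}))

    # REM theta on the occipital EEG
    if cfg.with_eeg:
        occ = labels_all.index("EEG Occipital")
        t = np.arange(n) / fs
        theta = cfg.theta_amplitude * np.sin(2 * np.pi * cfg.theta_freq * t)
        for i, lab in enumerate(labels):
            if lab == "REM":
                a = int(i * cfg.epoch_length * fs)
                bnd = min(int((i + 1) * cfg.epoch_length * fs), n)
                data[occ, a:bnd] += theta[a:bnd]

    # stimulus-evoked EMG twitches
    stim_list = []
    if stimulus_times is not None and cfg.with_emg:
        emg_i = labels_all.index("EMG")
        ntw = int(round(cfg.emg_twitch_duration * fs))
        for st in stimulus_times:
            i0 = int(round(st * fs))
            if i0 + ntw <= n:
                data[emg_i, i0 : i0 + ntw] += (
                    cfg.emg_sd * np.sqrt(cfg.emg_twitch_gain - 1)
                    * r_emg.standard_normal(ntw))
                stim_list.append(float(st))

    bursts.sort(key=lambda b: b.onset)
    rec = Recording(data=data, fs=fs, channels=chan_info)
    gt = SyntheticGroundTruth(bursts=bursts, slow_waves=sws,
                              stimuli=stim_list, config=cfg)
    return rec, hyp, gt
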