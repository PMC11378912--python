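"""Causal emulation of the closed-loop (real-time) spindle detector.

The online detector band-boosts the LFP with a second-order parametric
(peaking) filter centered at 12.5 Hz with a 0.4-octave fractional
bandwidth, squares it, smooths the power with an exponential kernel, and
declares a spindle when the smoothed power crosses 4.5 times its running
mean.  Detection is vetoed while either gate is active: elevated EMG power
(movement) or elevated occipital theta power (REM).  Every computation
uses only past samples, so truncating the input cannot change earlier
outputs.  Stimulus scheduling honours a minimum interstimulus interval and
logs whether each stimulus fell during or outside a spindle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

__all__ = [
    "RealtimeConfig", "StimulusLog", "parametric_bandpass_coeffs",
    "causal_detect", "comparative_sensitivity", "emg_response",
    "schedule_stimuli",
]


@dataclass(frozen=True)
class RealtimeConfig:
    center_freq: float = 12.5         # Hz
    bandwidth_octaves: float = 0.4    # -3 dB fractional bandwidth
    smoothing_tau: float = 0.1        # s, exponential power smoothing
    threshold_multiplier: float = 4.5
    baseline_horizon: float = 60.0    # s of gate-clear signal for the running mean
    emg_gate_multiplier: float = 4.0  # x running EMG power -> movement veto
    theta_gate_multiplier: float = 4.0
    theta_center: float = 7.5         # Hz, occipital REM theta
    theta_bandwidth_octaves: float = 0.6
    refractory: float = 3.0           # s, minimum gap between detections

    def __post_init__(self) -> None:
        if self.threshold_multiplier <= 0 or self.center_freq <= 0:
            raise ValueError("thresholds and center frequency must be positive")


@dataclass
class StimulusLog:
    times: np.ndarray
    condition: np.ndarray             # 'sound' | 'sham'
    context: np.ndarray               # 'during' | 'outside'

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.times, "condition": self.condition,
                             "context": self.context})


def parametric_bandpass_coeffs(center: float, bw_octaves: float, fs: float):
    """Constant-peak-gain band-pass biquad (audio-EQ parametric topology).

    Unit gain at ``center``; the -3 dB edges sit ``bw_octaves`` apart
    geometrically around the center.
    """
    if center >= fs / 2:
        raise ValueError("center frequency must be below Nyquist")
    w0 = 2 * np.pi * center / fs
    alpha = np.sin(w0) * np.sinh(np.log(2) / 2 * bw_octaves * w0 / np.sin(w0))
    b = np.array([alpha, 0.0, -alpha])
    a = np.array([1 + alpha, -2 * np.cos(w0), 1 - alpha])
    return b / a[0], a / a[0]


def _exp_smooth(x: np.ndarray, fs: float, tau: float) -> np.ndarray:
    """Causal exponential smoothing y[n] = a x[n] + (1-a) y[n-1]."""
    a = 1.0 - np.exp(-1.0 / (fs * tau))
    return sps.lfilter([a], [1.0, -(1.0 - a)], x)


def _trailing_mean(x: np.ndarray, include: np.ndarray, n_window: int):
    """Causal mean of ``x`` over included samples in the trailing window.

    Value at n uses samples 0..n (inclusive) limited to the last
    ``n_window``; NaN until at least one included sample is seen.
    """
    xi = np.where(include, x, 0.0)
    ci = include.astype(float)
    cs_x = np.concatenate(([0.0], np.cumsum(xi)))
    cs_c = np.concatenate(([0.0], np.cumsum(ci)))
    n = len(x)
    idx = np.arange(n)
    lo = np.maximum(idx + 1 - n_window, 0)
    tot = cs_x[idx + 1] - cs_x[lo]
    cnt = cs_c[idx + 1] - cs_c[lo]
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(cnt > 0, tot / np.where(cnt > 0, cnt, 1), np.nan)


def causal_detect(lfp: np.ndarray, fs: float, emg: np.ndarray | None = None,
                  occ_eeg: np.ndarray | None = None,
                  config: RealtimeConfig = RealtimeConfig(),
                  return_debug: bool = False):
    """Real-time spindle detection timestamps from time-aligned signals.

    Strictly causal: parametric band-pass -> squared signal -> exponential
    smoothing -> upward crossings of ``threshold_multiplier`` x the running
    mean of the smoothed sigma power over the preceding gate-clear
    ``baseline_horizon`` seconds, vetoed while the EMG or theta gate is
    active and subject to the refractory gap.  Missing gate channels
    disable the corresponding gate.
    """
    lfp = np.asarray(lfp, dtype=float)
    n = len(lfp)
    b, a = parametric_bandpass_coeffs(config.center_freq,
                                      config.bandwidth_octaves, fs)
    sigma_pow = _exp_smooth(sps.lfilter(b, a, lfp) ** 2, fs, config.smoothing_tau)

    gate = np.zeros(n, dtype=bool)
    horizon = int(round(config.baseline_horizon * fs))
    if emg is not None:
        emg_pow = _exp_smooth(np.asarray(emg, dtype=float) ** 2, fs,
                              config.smoothing_tau)
        emg_base = _trailing_mean(emg_pow, np.ones(n, dtype=bool), horizon)
        gate |= emg_pow > config.emg_gate_multiplier * emg_base
    if occ_eeg is not None:
        tb, ta = parametric_bandpass_coeffs(config.theta_center,
                                            config.theta_bandwidth_octaves, fs)
        th_pow = _exp_smooth(sps.lfilter(tb, ta, np.asarray(occ_eeg, dtype=float)) ** 2,
                             fs, config.smoothing_tau)
        th_base = _trailing_mean(th_pow, np.ones(n, dtype=bool), horizon)
        gate |= th_pow > config.theta_gate_multiplier * th_base

    baseline = _trailing_mean(sigma_pow, ~gate, horizon)
    with np.errstate(invalid="ignore"):
        above = sigma_pow > config.threshold_multiplier * baseline
    above &= ~gate
    crossings = np.flatnonzero(above[1:] & ~above[:-1]) + 1
    if len(above) and above[0]:
        crossings = np.concatenate(([0], crossings))

    detections, last = [], -np.inf
    min_gap = config.refractory * fs
    for c in crossings:
        if c - last >= min_gap:
            detections.append(c / fs)
            last = c
    det = np.array(detections)
    if return_debug:
        return det, {"sigma_power": sigma_pow, "baseline": baseline, "gate": gate}
    return det


def comparative_sensitivity(rt_times, offline_events, match_window: float = 0.25):
    """Percent of real-time detections confirmed by offline AR events.

    A timestamp matches when it falls within [t1 - w, t2 + w] of any
    offline event.  Returns NaN (undefined) for an empty detection list.
    """
    rt_times = np.asarray(rt_times, dtype=float)
    if len(rt_times) == 0:
        return np.nan
    offline_events = list(offline_events)
    if not offline_events:
        return 0.0
    starts = np.array([e.t1 - match_window for e in offline_events])
    ends = np.array([e.t2 + match_window for e in offline_events])
    order = np.argsort(starts)
    starts, ends = starts[order], ends[order]
    run_end = np.maximum.accumulate(ends)
    idx = np.searchsorted(starts, rt_times, side="right") - 1
    hit = (idx >= 0) & (rt_times <= run_end[np.maximum(idx, 0)])
    return 100.0 * float(np.mean(hit))


def emg_response(emg: np.ndarray, fs: float, stimuli: StimulusLog,
                 baseline_epochs, response_window: float = 0.2) -> pd.DataFrame:
    """Stimulus-evoked EMG variance normalized to unstimulated NREM.

    Per stimulus the EMG variance in [t, t + response_window] is divided by
    the mean variance over the baseline epochs (list of (lo, hi) second
    pairs, typically unstimulated NREM), then aggregated by condition x
    spindle context.
    """
    emg = np.asarray(emg, dtype=float)
    if not list(baseline_epochs):
        raise ValueError("need at least one unstimulated baseline epoch")
    base_vars = []
    for lo, hi in baseline_epochs:
        seg = emg[int(lo * fs) : int(hi * fs)]
        if len(seg) > 1:
            base_vars.append(np.var(seg))
    base = float(np.mean(base_vars))
    rows = []
    nwin = int(round(response_window * fs))
    for t, cond, ctx in zip(stimuli.times, stimuli.condition, stimuli.context):
        i0 = int(round(t * fs))
        seg = emg[i0 : i0 + nwin]
        if len(seg) < 2:
            continue
        v = float(np.var(seg))
        norm = v / base if base > 0 else (0.0 if v == 0 else np.nan)
        rows.append({"time": t, "condition": cond, "context": ctx,
                     "norm_variance": norm})
    df = pd.DataFrame(rows)
    agg = (df.groupby(["condition", "context"])["norm_variance"]
             .agg(["mean", "std", "count"]).reset_index())
    agg.attrs["per_stimulus"] = df
    return agg


def schedule_stimuli(detection_times, duration: float, seed=None, *,
                     min_gap: float = 3.0, p_during: float = 0.5,
                     condition: str = "sound",
                     rng=None) -> StimulusLog:
    """Pseudo-random interleaving of during- and outside-spindle stimuli.

    Walks the recording, at each opportunity drawing whether to stimulate
    at the next spindle detection ('during') or at a random spindle-free
    moment ('outside'), always honouring the minimum interstimulus gap.
    """
    rng = np.random.default_rng(seed) if rng is None else rng
    det = np.sort(np.asarray(detection_times, dtype=float))
    times, ctx = [], []
    t = min_gap
    while t < duration:
        stim = None
        if rng.random() < p_during:
            i = int(np.searchsorted(det, t))
            if i < len(det) and det[i] < duration:
                stim, label = float(det[i]), "during"
        else:
            cand = t + float(rng.uniform(0, 2 * min_gap))
            far = len(det) == 0 or float(np.min(np.abs(det - cand))) > min_gap / 2
            if cand < duration and far:
                stim, label = cand, "outside"
        if stim is None:
            t += min_gap
            continue
        times.append(stim)
        ctx.append(label)
        t = stim + min_gap
    times = np.array(times)
    return StimulusLog(times=times,
                       condition=np.array([condition] * len(times)),
                       context=np.array(ctx))
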