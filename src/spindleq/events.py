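"""Oscillatory-event detection from pole tracks and the o-Quality metric.

An event begins when the in-band inverse-damping series r crosses the upper
threshold r_b (default 0.92) and ends when it falls back below it.
Consecutive supra-threshold runs are merged into one event as long as r
never falls below the lower hysteresis threshold r_a (default 0.90) in
between; a dip below r_a splits them.  Each event is tagged with its
maximum r, the pole frequency at that maximum, and a duration-weighted mean
frequency; events with mean frequency in 10-15 Hz are putative spindles.
Events are binned into o-Quality groups oQ1-oQ4 at r edges
0.92/0.93/0.94/0.95 (top bin closed below, unbounded above).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ar import PoleTrack, band_max_series
from .io import EpochSpectra, Hypnogram

__all__ = [
    "DetectionConfig", "OscillatoryEvent", "band_pole_series",
    "detect_events", "assign_oquality", "select_spindles",
    "event_statistics", "conditioned_spectra", "events_to_frame",
]


@dataclass(frozen=True)
class DetectionConfig:
    r_b: float = 0.92                 # upper (detection) threshold on r
    r_a: float = 0.90                 # lower (merge/split) threshold
    band: tuple[float, float] = (10.0, 15.0)
    oq_edges: tuple[float, ...] = (0.92, 0.93, 0.94, 0.95)
    min_duration: float = 0.0         # s; none imposed by default

    def __post_init__(self) -> None:
        if not self.r_a < self.r_b:
            raise ValueError("require r_a < r_b")
        if not self.band[0] < self.band[1]:
            raise ValueError("band must be (f_lo, f_hi) with f_lo < f_hi")
        edges = np.asarray(self.oq_edges)
        if not np.all(np.diff(edges) > 0):
            raise ValueError("oq_edges must be strictly increasing")
        if edges[0] != self.r_b:
            raise ValueError("first oq edge must equal r_b")


@dataclass
class OscillatoryEvent:
    channel: str
    t1: float                         # s, half-open [t1, t2)
    t2: float
    max_r: float
    f_at_max: float                   # Hz, pole frequency at the r maximum
    mean_f: float                     # Hz, duration-weighted mean
    oq: int | None = None             # 1..4
    state: str | None = None

    @property
    def duration(self) -> float:
        return self.t2 - self.t1

    @property
    def center(self) -> float:
        return 0.5 * (self.t1 + self.t2)


def band_pole_series(track: PoleTrack, band=(10.0, 15.0)):
    """Per-window (times, r, f) of the least-damped in-band oscillator pole.

    Windows without an in-band oscillator carry r = 0 and f = NaN.
    """
    return band_max_series(track, band)


def detect_events(times, r_series, f_series=None,
                  config: DetectionConfig = DetectionConfig(), *,
                  channel: str = "", interpolate: bool = False) -> list[OscillatoryEvent]:
    """Hysteresis detection of oscillatory events on an r-value series.

    Supra-threshold runs (r >= r_b) become events delimited by the upward
    and downward r_b crossings; runs separated by a dip that never fell
    below r_a are merged into one continuous event.  With ``interpolate``
    (recommended when the series is decimated, stride > 1) boundaries are
    linearly interpolated between window centers; otherwise t1 is the first
    supra-threshold window center and t2 the center of the first window
    back below threshold.
    """
    times = np.asarray(times, dtype=float)
    r = np.asarray(r_series, dtype=float)
    if len(times) < 2:
        return []
    if f_series is None:
        f_series = np.full_like(r, np.nan)
    f = np.asarray(f_series, dtype=float)
    dt = times[1] - times[0]

    supra = r >= config.r_b
    if not supra.any():
        return []
    edges = np.diff(supra.astype(int))
    starts = list(np.flatnonzero(edges == 1) + 1)
    ends = list(np.flatnonzero(edges == -1) + 1)   # first index below threshold
    if supra[0]:
        starts.insert(0, 0)
    if supra[-1]:
        ends.append(len(r))

    # merge runs whose inter-run minimum never fell below r_a
    merged = [[starts[0], ends[0]]]
    for s, e in zip(starts[1:], ends[1:]):
        gap_min = r[merged[-1][1]: s].min()
        if gap_min >= config.r_a:
            merged[-1][1] = e
        else:
            merged.append([s, e])

    events = []
    for s, e in merged:
        seg_r = r[s:e]
        # windows inside a merged event may dip below r_b; max is over all
        imax = s + int(np.argmax(seg_r))
        if interpolate:
            if s > 0 and r[s] != r[s - 1]:
                frac = (config.r_b - r[s - 1]) / (r[s] - r[s - 1])
                t1 = times[s - 1] + frac * dt
            else:
                t1 = times[s]
            if e < len(r) and r[e] != r[e - 1]:
                frac = (r[e - 1] - config.r_b) / (r[e - 1] - r[e])
                t2 = times[e - 1] + frac * dt
            else:
                t2 = times[min(e, len(r) - 1)]
        else:
            t1 = times[s]
            t2 = times[e] if e < len(times) else times[-1] + dt
        in_ev = f[s:e]
        good = np.isfinite(in_ev)
        mean_f = float(in_ev[good].mean()) if good.any() else np.nan
        ev = OscillatoryEvent(channel=channel, t1=float(t1), t2=float(t2),
                              max_r=float(r[imax]), f_at_max=float(f[imax]),
                              mean_f=mean_f)
        if ev.duration >= config.min_duration:
            events.append(ev)
    for ev in events:
        ev.oq = assign_oquality(ev, config)
    return events


def assign_oquality(event: OscillatoryEvent,
                    config: DetectionConfig = DetectionConfig()) -> int:
    """o-Quality bin (1..4) of an event by half-open r edges; top bin open above."""
    if event.max_r < config.r_b:
        raise ValueError(f"event max_r {event.max_r} below detection threshold")
    oq = int(np.searchsorted(config.oq_edges, event.max_r, side="right"))
    return min(oq, len(config.oq_edges))


def select_spindles(events, band=(10.0, 15.0)) -> list[OscillatoryEvent]:
    """Events whose mean frequency lies in the sigma band: putative spindles."""
    lo, hi = band
    return [e for e in events
            if np.isfinite(e.mean_f) and lo <= e.mean_f <= hi]


def events_to_frame(events) -> pd.DataFrame:
    """Flat event table (channel, t1, t2, max_r, f_at_max, mean_f, oQ, state)."""
    return pd.DataFrame(
        [(e.channel, e.t1, e.t2, e.duration, e.max_r, e.f_at_max, e.mean_f,
          e.oq, e.state) for e in events],
        columns=["channel", "t1", "t2", "duration", "max_r", "f_at_max",
                 "mean_f", "oq", "state"])


def event_statistics(events, hypnogram: Hypnogram, *, state: str = "NREM",
                     time_bins=None) -> dict:
    """Incidence and distribution summaries of detected events.

    Incidence is events per minute spent in ``state``; with ``time_bins``
    (edges in seconds) the per-oQ counts are additionally given per bin as
    a percentage of each bin total.  Bins with zero state-minutes have NaN
    (undefined) incidence, never zero.
    """
    events = list(events)
    minutes = hypnogram.minutes_in(state)
    out = {
        "n_events": len(events),
        "state_minutes": minutes,
        "incidence_per_min": (len(events) / minutes) if minutes > 0 else np.nan,
        "durations": np.array([e.duration for e in events]),
        "max_r": np.array([e.max_r for e in events]),
        "frequencies": np.array([e.f_at_max for e in events]),
        "oq_counts": {q: sum(1 for e in events if e.oq == q) for q in (1, 2, 3, 4)},
    }
    if time_bins is not None:
        edges = np.asarray(time_bins, dtype=float)
        rows = []
        for lo, hi in zip(edges[:-1], edges[1:]):
            in_bin = [e for e in events if lo <= e.center < hi]
            mins = hypnogram.minutes_in(state, lo, hi)
            row = {"t_lo": lo, "t_hi": hi, "n": len(in_bin),
                   "incidence_per_min": len(in_bin) / mins if mins > 0 else np.nan}
            for q in (1, 2, 3, 4):
                nq = sum(1 for e in in_bin if e.oq == q)
                row[f"oq{q}_pct"] = 100.0 * nq / len(in_bin) if in_bin else np.nan
            rows.append(row)
        out["per_bin"] = pd.DataFrame(rows)
    return out


def conditioned_spectra(target: EpochSpectra, events, *,
                        hypnogram: Hypnogram | None = None,
                        state: str = "NREM") -> np.ndarray:
    """Spectral ratio of event epochs to event-free epochs, in percent.

    Classifies the target channel's epochs by whether any event midpoint
    (events typically detected on a *different* channel) falls inside, then
    returns mean(power | event) / mean(power | no event) x 100 per frequency
    bin.  Restricting to a vigilance state requires a hypnogram.
    """
    n_ep = target.power.shape[0]
    has_event = np.zeros(n_ep, dtype=bool)
    t0 = target.epoch_times
    for e in events:
        mid = e.center
        idx = int((mid - t0[0]) // target.epoch_length)
        if 0 <= idx < n_ep:
            has_event[idx] = True
    usable = np.ones(n_ep, dtype=bool)
    if hypnogram is not None:
        for i, t in enumerate(t0):
            usable[i] = hypnogram.state_at(t + target.epoch_length / 2) == state
    if not (has_event & usable).any():
        raise ValueError("no usable epochs contain an event")
    if not (~has_event & usable).any():
        raise ValueError("no event-free epochs to normalize against")
    with_ev = target.power[has_event & usable].mean(axis=0)
    without = target.power[~has_event & usable].mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        return 100.0 * with_ev / without
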