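"""End-to-end convenience: trace in, spindle events out."""

from __future__ import annotations

import numpy as np

from .ar import sliding_decomposition
from .events import (DetectionConfig, band_pole_series, detect_events,
                     select_spindles)
from .io import Hypnogram, resample_signal, restrict_to_state

__all__ = ["detect_spindles"]


def detect_spindles(trace: np.ndarray, fs: float,
                    config: DetectionConfig = DetectionConfig(), *,
                    hypnogram: Hypnogram | None = None, state: str = "NREM",
                    analysis_fs: float = 128.0, stride: int = 1,
                    order: int = 8, channel: str = ""):
    """Full damping-based spindle detection on one channel.

    Resamples to the analysis rate (128 Hz), slides 1-s AR(8) windows,
    tracks the least-damped 10-15 Hz pole, applies the r_b/r_a hysteresis
    detector, keeps events with in-band mean frequency, and optionally
    restricts to a vigilance state.
    """
    x = resample_signal(np.asarray(trace, dtype=float), fs, analysis_fs)
    track = sliding_decomposition(x, fs=analysis_fs, stride=stride,
                                  order=order, channel=channel)
    times, r, f = band_pole_series(track, config.band)
    events = detect_events(times, r, f, config, channel=channel,
                           interpolate=stride > 1)
    spindles = select_spindles(events, config.band)
    if hypnogram is not None:
        spindles = restrict_to_state(spindles, hypnogram, state)
        for e in spindles:
            e.state = state
    return spindles
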