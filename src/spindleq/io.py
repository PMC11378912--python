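"""Recording / hypnogram containers, EDF round-trip, resampling, spectra.

Conventions used throughout the package: time is seconds from recording
start, 0-based; event boundaries are half-open [t1, t2); signal amplitudes
are microvolts; the hypnogram is a per-epoch (default 4 s) sequence of
vigilance-state labels, and epochs labelled Artifact are excluded from all
downstream statistics.
"""

from __future__ import annotations

import json
import struct
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

__all__ = [
    "ChannelInfo", "Recording", "Hypnogram", "EpochSpectra",
    "load_recording", "write_edf", "save_array_bundle",
    "resample_signal", "compute_epoch_spectra", "restrict_to_state",
    "STATES",
]

STATES = ("Wake", "NREM", "REM", "Artifact", "BriefAwakening")


@dataclass
class ChannelInfo:
    label: str
    modality: str = "EEG"             # EEG | LFP | EMG
    site: str = ""
    depth: float | None = None        # µm below pia, laminar probes
    position: tuple[float, float] | None = None  # optional 2-D geometry (µm)


@dataclass
class Recording:
    """Multichannel trace block with per-channel metadata (µV)."""

    data: np.ndarray                  # (n_channels, n_samples)
    fs: float
    channels: list[ChannelInfo]

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.data.shape[0] != len(self.channels):
            raise ValueError("channel metadata count must match data rows")
        labels = [c.label for c in self.channels]
        if len(set(labels)) != len(labels):
            raise ValueError("channel labels must be unique")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    @property
    def labels(self) -> list[str]:
        return [c.label for c in self.channels]

    def channel(self, label: str) -> np.ndarray:
        return self.data[self.labels.index(label)]

    def meta(self, label: str) -> ChannelInfo:
        return self.channels[self.labels.index(label)]


@dataclass
class Hypnogram:
    """Per-epoch vigilance labels; scored in fixed-length (default 4 s) epochs."""

    labels: list[str]
    epoch_length: float = 4.0

    def __post_init__(self) -> None:
        if self.epoch_length <= 0:
            raise ValueError("epoch_length must be positive")
        bad = set(self.labels) - set(STATES)
        if bad:
            raise ValueError(f"unknown vigilance labels: {sorted(bad)}")

    @property
    def duration(self) -> float:
        return len(self.labels) * self.epoch_length

    def epoch_of(self, t: float) -> int:
        idx = int(t // self.epoch_length)
        if t < 0 or idx >= len(self.labels):
            raise IndexError(f"time {t:.3f} s outside hypnogram (0-{self.duration} s)")
        return idx

    def state_at(self, t: float) -> str:
        return self.labels[self.epoch_of(t)]

    def minutes_in(self, state: str, t_lo: float | None = None,
                   t_hi: float | None = None) -> float:
        """Minutes spent in ``state`` within [t_lo, t_hi)."""
        t_lo = 0.0 if t_lo is None else t_lo
        t_hi = self.duration if t_hi is None else t_hi
        total = 0.0
        for i, lab in enumerate(self.labels):
            e0, e1 = i * self.epoch_length, (i + 1) * self.epoch_length
            if lab == state:
                total += max(0.0, min(e1, t_hi) - max(e0, t_lo))
        return total / 60.0

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# epoch_length={self.epoch_length}\n")
            fh.write("\n".join(self.labels) + "\n")

    @classmethod
    def from_file(cls, path) -> "Hypnogram":
        lines = Path(path).read_text().splitlines()
        epoch_length = 4.0
        labels = []
        for ln in lines:
            ln = ln.strip()
            if not ln:
                continue
            if ln.startswith("#"):
                if "epoch_length=" in ln:
                    epoch_length = float(ln.split("epoch_length=")[1])
                continue
            labels.append(ln)
        return cls(labels=labels, epoch_length=epoch_length)


@dataclass
class EpochSpectra:
    """One-sided per-epoch power spectral densities (µV²/Hz)."""

    frequencies: np.ndarray           # Hz grid, step = 1/epoch_length
    power: np.ndarray                 # (n_epochs, n_freqs), >= 0
    epoch_times: np.ndarray           # epoch start times (s)
    epoch_length: float = 4.0

    @property
    def resolution(self) -> float:
        return float(self.frequencies[1] - self.frequencies[0])


# ---------------------------------------------------------------------------
# EDF round-trip.  Reading goes through MNE; writing uses a minimal EDF
# encoder (16-bit, 1-s data records) because no installed library exports EDF.

def write_edf(rec: Recording, path) -> None:
    """Write a Recording as a plain EDF file (16-bit, 1-s records).

    Physical units are microvolts; requires an integer sampling rate.
    """
    fs = int(round(rec.fs))
    if abs(fs - rec.fs) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    ns = len(rec.channels)
    n_rec = int(np.ceil(rec.n_samples / fs))
    data = np.zeros((ns, n_rec * fs))
    data[:, : rec.n_samples] = rec.data

    phys_min = np.minimum(data.min(axis=1), -1.0)
    phys_max = np.maximum(data.max(axis=1), 1.0)
    dig_min, dig_max = -32768, 32767

    def pad(s: str, n: int) -> bytes:
        return s[:n].ljust(n).encode("ascii")

    hdr = b"".join([
        pad("0", 8), pad("X X X X", 80), pad("Startdate X X X X", 80),
        pad("01.01.00", 8), pad("00.00.00", 8),
        pad(str(256 * (ns + 1)), 8), pad("", 44),
        pad(str(n_rec), 8), pad("1", 8), pad(str(ns), 4),
    ])
    hdr += b"".join(pad(c.label, 16) for c in rec.channels)
    hdr += b"".join(pad("", 80) for _ in rec.channels)           # transducer
    hdr += b"".join(pad("uV", 8) for _ in rec.channels)
    hdr += b"".join(pad(f"{phys_min[i]:.4f}"[:8], 8) for i in range(ns))
    hdr += b"".join(pad(f"{phys_max[i]:.4f}"[:8], 8) for i in range(ns))
    hdr += b"".join(pad(str(dig_min), 8) for _ in rec.channels)
    hdr += b"".join(pad(str(dig_max), 8) for _ in rec.channels)
    hdr += b"".join(pad("", 80) for _ in rec.channels)           # prefiltering
    hdr += b"".join(pad(str(fs), 8) for _ in rec.channels)
    hdr += b"".join(pad("", 32) for _ in rec.channels)

    pmin = np.array([float(f"{v:.4f}"[:8]) for v in phys_min])
    pmax = np.array([float(f"{v:.4f}"[:8]) for v in phys_max])
    gain = (pmax - pmin) / (dig_max - dig_min)
    dig = np.round((data - pmin[:, None]) / gain[:, None]) + dig_min
    dig = np.clip(dig, dig_min, dig_max).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(hdr)
        for r in range(n_rec):
            for ch in range(ns):
                fh.write(dig[ch, r * fs : (r + 1) * fs].tobytes())


def _read_edf(path) -> Recording:
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    labels = list(raw.ch_names)
    if len(set(labels)) != len(labels):
        raise ValueError("EDF contains duplicate channel labels")
    # MNE scales voltage channels to volts internally; recover µV.
    data = raw.get_data() * 1e6
    chans = []
    for lab in labels:
        mod = "EMG" if "EMG" in lab.upper() else (
            "LFP" if "LFP" in lab.upper() else "EEG")
        chans.append(ChannelInfo(label=lab, modality=mod))
    return Recording(data=data, fs=float(raw.info["sfreq"]), channels=chans)


def save_array_bundle(rec: Recording, path) -> None:
    """Write a Recording as an .npz bundle with a JSON metadata entry."""
    meta = [{"label": c.label, "modality": c.modality, "site": c.site,
             "depth": c.depth, "position": c.position} for c in rec.channels]
    np.savez(path, data=rec.data, fs=rec.fs, meta=json.dumps(meta))


def _read_bundle(path) -> Recording:
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["meta"]))
        chans = [ChannelInfo(label=m["label"], modality=m["modality"],
                             site=m.get("site", ""), depth=m.get("depth"),
                             position=tuple(m["position"]) if m.get("position") else None)
                 for m in meta]
        return Recording(data=z["data"], fs=float(z["fs"]), channels=chans)


def load_recording(path, format: str | None = None) -> Recording:
    """Load an EDF file or .npz array bundle into a Recording."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "edf" if path.suffix.lower() == ".edf" else "array-bundle"
    if format == "edf":
        return _read_edf(path)
    if format == "array-bundle":
        return _read_bundle(path)
    raise ValueError(f"unknown recording format: {format}")


# ---------------------------------------------------------------------------

def resample_signal(trace: np.ndarray, fs_in: float, fs_out: float) -> np.ndarray:
    """Rate-convert with polyphase FIR anti-aliasing.

    Chosen over Fourier resampling for band-limited fidelity around the
    10-15 Hz band.  Identity rates return the input unchanged.
    """
    if fs_in <= 0 or fs_out <= 0:
        raise ValueError("sampling rates must be positive")
    trace = np.asarray(trace, dtype=float)
    if trace.size == 0:
        return trace.copy()
    if fs_in == fs_out:
        return trace
    frac = Fraction(fs_out / fs_in).limit_denominator(1000)
    return sps.resample_poly(trace, frac.numerator, frac.denominator)


def compute_epoch_spectra(trace: np.ndarray, fs: float,
                          epoch_length: float = 4.0) -> EpochSpectra:
    """Hanning-windowed one-sided PSD of consecutive fixed-length epochs.

    With 4-s epochs the frequency grid has the 0.25 Hz step used for all
    spectral summaries.  A trailing partial epoch is dropped (non-integer
    epoch sample counts truncate to floor).
    """
    trace = np.asarray(trace, dtype=float)
    nper = int(np.floor(epoch_length * fs))
    if len(trace) < nper:
        raise ValueError("trace shorter than one epoch")
    n_ep = len(trace) // nper
    segs = trace[: n_ep * nper].reshape(n_ep, nper)
    freqs, power = sps.periodogram(segs, fs=fs, window="hann", axis=1,
                                   detrend=False, scaling="density")
    times = np.arange(n_ep) * nper / fs
    return EpochSpectra(frequencies=freqs, power=power, epoch_times=times,
                        epoch_length=epoch_length)


def restrict_to_state(items, hypnogram: Hypnogram, state: str = "NREM"):
    """Keep items whose midpoint falls in epochs of the requested state.

    ``items`` may be an iterable of objects with t1/t2, of (t1, t2) pairs, or
    of scalar times.  Epochs labelled Artifact are always excluded.
    Timestamps beyond the hypnogram raise IndexError.
    """
    kept = []
    for it in items:
        if hasattr(it, "t1"):
            mid = 0.5 * (it.t1 + it.t2)
        elif np.ndim(it) == 1 and len(it) == 2:
            mid = 0.5 * (it[0] + it[1])
        else:
            mid = float(it)
        lab = hypnogram.state_at(mid)
        if lab == state and lab != "Artifact":
            kept.append(it)
    return kept
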