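"""Autoregressive pole decomposition of sliding signal windows.

The analysis models an electrophysiological trace as a superposition of
stochastically driven damped harmonic oscillators and relaxators.  Each
1-s window (at 128 Hz) is fitted with an AR(p) model

    x(t_n) = sum_{i=1..p} a_i x(t_{n-i}) + eps(t_n)

via the Burg (maximum-entropy) recursion, and the characteristic polynomial

    z^p - sum_{k=1..p} a_k z^{p-k} = prod_k (z - z_k),   z_k = r_k e^{i phi_k}

is factored into poles.  A complex-conjugate pair is one *oscillator* with
frequency f_k = phi_k / (2 pi Delta) and inverse-damping magnitude r_k; a
positive real root is a *relaxator* (f = 0).  The pole magnitude relates to
the damping coefficient by r = exp(-gamma * Delta): r = 1 means an undamped
(sustained) oscillation, smaller r means faster decay.  Counting follows
p = 2m + n with m oscillators and n relaxators, so an order-8 model yields
at most four oscillatory poles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ARFit",
    "Pole",
    "PoleTrack",
    "fit_burg",
    "burg_batch",
    "poles_from_coefficients",
    "sliding_decomposition",
    "r_from_gamma",
    "gamma_from_r",
]

DEFAULT_ORDER = 8


@dataclass
class ARFit:
    """An AR(p) model of one window, predictive sign convention."""

    coefficients: np.ndarray          # a_1..a_p, x_n ~ sum a_i x_{n-i}
    residual_variance: float          # µV²
    window_center_time: float         # s
    delta: float                      # sampling interval (s)

    @property
    def order(self) -> int:
        return len(self.coefficients)


@dataclass(frozen=True)
class Pole:
    """One root of the AR characteristic polynomial.

    ``r`` is the pole magnitude (inverse damping, dimensionless, < 1 for a
    stable fit), ``f`` the oscillation frequency in Hz (0 for relaxators),
    ``phase_angle`` the root's complex argument, and ``gamma`` the damping
    coefficient in 1/s with r = exp(-gamma * delta).
    """

    r: float
    f: float
    phase_angle: float
    delta: float
    multiplicity: int = 1             # 2 for a collapsed conjugate pair

    @property
    def gamma(self) -> float:
        return gamma_from_r(self.r, self.delta)

    @property
    def is_oscillator(self) -> bool:
        return self.f > 0


@dataclass
class PoleTrack:
    """Pole decomposition of overlapping windows slid along one channel.

    ``roots`` holds the complex characteristic roots per window,
    shape (n_windows, order); windows skipped over NaN samples are flagged
    in ``valid`` and carry NaN roots.
    """

    times: np.ndarray                 # window centers (s), strictly increasing
    roots: np.ndarray                 # complex, (n_windows, order)
    delta: float                      # sampling interval of the analysed trace
    stride: int                       # samples between consecutive windows
    window_length: float              # s
    channel: str = ""
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.valid is None:
            self.valid = np.ones(len(self.times), dtype=bool)
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("window center times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def order(self) -> int:
        return self.roots.shape[1]

    def poles(self, i: int) -> list[Pole]:
        """Pole list of window ``i``, conjugate pairs collapsed."""
        return roots_to_poles(self.roots[i], self.delta)

    def to_dataframe(self) -> pd.DataFrame:
        """Long-format (time, pole_index, r, f) table for inspection."""
        rows = []
        for i, t in enumerate(self.times):
            for j, p in enumerate(self.poles(i)):
                rows.append((t, j, p.r, p.f))
        return pd.DataFrame(rows, columns=["time", "pole_index", "r", "f"])


def r_from_gamma(gamma, delta: float):
    """Pole magnitude r = exp(-gamma * delta); gamma = 0 gives r = 1."""
    gamma = np.asarray(gamma, dtype=float)
    if np.any(gamma < 0):
        raise ValueError("damping coefficient gamma must be >= 0")
    out = np.exp(-gamma * delta)
    return float(out) if out.ndim == 0 else out


def gamma_from_r(r, delta: float):
    """Damping coefficient gamma = -ln(r)/delta; r = 0 maps to +inf."""
    r = np.asarray(r, dtype=float)
    if np.any((r < 0) | (r > 1)):
        raise ValueError("pole magnitude r must lie in [0, 1]")
    with np.errstate(divide="ignore"):
        out = -np.log(r) / delta
    return float(out) if out.ndim == 0 else out


def burg_batch(segments: np.ndarray, order: int, demean: bool = True):
    """Burg AR fit of many equal-length windows at once.

    Parameters
    ----------
    segments : (n_windows, n_samples) array
    order : AR model order p
    demean : subtract each window's mean before fitting

    Returns
    -------
    coeffs : (n_windows, order) predictive coefficients a_1..a_p
    sigma2 : (n_windows,) residual variances

    Constant (zero-variance) windows yield all-zero coefficients, i.e. all
    roots at the origin — maximally damped — rather than an error, so flat
    artifact stretches do not abort batch runs.
    """
    x = np.atleast_2d(np.asarray(segments, dtype=float))
    n_win, n = x.shape
    if n <= order:
        raise ValueError(f"window length {n} must exceed AR order {order}")
    if not np.all(np.isfinite(x)):
        raise ValueError("segments must be finite-valued")
    raw_scale = np.mean(x**2, axis=1)
    if demean:
        x = x - x.mean(axis=1, keepdims=True)
    # numerically flat windows (constant up to rounding) get an all-zero
    # model: every root at the origin, maximum damping
    flat = np.mean(x**2, axis=1) <= 1e-24 * np.maximum(raw_scale, 1.0)
    x = np.where(flat[:, None], 0.0, x)

    # a holds the monic polynomial 1, c_1..c_m with x_n + sum c_i x_{n-i} = e_n
    a = np.zeros((n_win, order + 1))
    a[:, 0] = 1.0
    fwd = x.copy()
    bwd = x.copy()
    sigma2 = np.mean(x**2, axis=1)
    for m in range(1, order + 1):
        ff = fwd[:, 1:]
        bb = bwd[:, :-1]
        den = np.einsum("ij,ij->i", ff, ff) + np.einsum("ij,ij->i", bb, bb)
        num = -2.0 * np.einsum("ij,ij->i", ff, bb)
        k = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
        if m > 1:
            prev = a[:, 1:m].copy()
            a[:, 1:m] = prev + k[:, None] * prev[:, ::-1]
        a[:, m] = k
        fwd = ff + k[:, None] * bb
        bwd = bb + k[:, None] * ff
        sigma2 = sigma2 * (1.0 - k**2)
    return -a[:, 1:], np.maximum(sigma2, 0.0)


def fit_burg(segment: np.ndarray, order: int = DEFAULT_ORDER, *,
             delta: float = 1.0 / 128.0, center_time: float = 0.0,
             demean: bool = True) -> ARFit:
    """Fit an AR(p) model to one window with the Burg recursion.

    The Burg estimator minimises the summed forward and backward prediction
    error and guarantees all characteristic roots inside the unit circle.
    """
    coeffs, sigma2 = burg_batch(np.asarray(segment)[None, :], order, demean=demean)
    return ARFit(coefficients=coeffs[0], residual_variance=float(sigma2[0]),
                 window_center_time=center_time, delta=delta)


def characteristic_roots(coefficients: np.ndarray) -> np.ndarray:
    """Roots of z^p - a_1 z^{p-1} - ... - a_p via companion-matrix eigenvalues."""
    poly = np.concatenate(([1.0], -np.asarray(coefficients, dtype=float)))
    return np.roots(poly)


def roots_batch(coeffs: np.ndarray) -> np.ndarray:
    """Characteristic roots for a batch of coefficient rows, (n, p) complex.

    Uses one batched eigenvalue call on the stacked companion matrices.
    """
    coeffs = np.atleast_2d(coeffs)
    n_win, p = coeffs.shape
    comp = np.zeros((n_win, p, p))
    comp[:, 0, :] = coeffs
    idx = np.arange(p - 1)
    comp[:, idx + 1, idx] = 1.0
    return np.linalg.eigvals(comp)


def roots_to_poles(roots: np.ndarray, delta: float) -> list[Pole]:
    """Collapse conjugate root pairs into oscillator poles.

    Complex pairs become one oscillator with f = phi/(2 pi delta); positive
    real roots are relaxators (f = 0); negative real roots are Nyquist-rate
    oscillators at f = 1/(2 delta).
    """
    poles = []
    for z in roots:
        if np.imag(z) < 0:
            continue  # conjugate partner of a reported oscillator
        r = float(np.abs(z))
        phi = float(np.angle(z))
        mult = 1
        if np.imag(z) > 0:
            f = phi / (2 * np.pi * delta)
            mult = 2
        elif np.real(z) < 0:
            f = 1.0 / (2 * delta)  # single real root oscillating at Nyquist
        else:
            f, phi = 0.0, 0.0
        poles.append(Pole(r=r, f=f, phase_angle=phi, delta=delta,
                          multiplicity=mult))
    return sorted(poles, key=lambda p: p.f)


def poles_from_coefficients(fit: ARFit) -> list[Pole]:
    """Factor an ARFit into its pole list (Eq.-2 style decomposition)."""
    return roots_to_poles(characteristic_roots(fit.coefficients), fit.delta)


def sliding_decomposition(trace: np.ndarray, fs: float = 128.0, *,
                          window_length: float = 1.0, stride: int = 1,
                          order: int = DEFAULT_ORDER, demean: bool = True,
                          channel: str = "", batch: int = 65536) -> PoleTrack:
    """Decompose overlapping windows along a trace into a PoleTrack.

    Windows of ``window_length`` seconds are shifted by ``stride`` samples
    and each is Burg-fitted and factored into poles.  Windows containing
    NaN samples are skipped and flagged invalid.

    ``batch`` bounds how many windows are materialised at once so memory
    stays flat on long recordings.
    """
    trace = np.asarray(trace, dtype=float)
    delta = 1.0 / fs
    wlen = int(round(window_length * fs))
    if stride < 1:
        raise ValueError("stride must be >= 1 sample")
    if len(trace) < wlen:
        raise ValueError("trace shorter than one analysis window")
    starts = np.arange(0, len(trace) - wlen + 1, stride)
    times = (starts + (wlen - 1) / 2.0) * delta

    nan_mask = ~np.isfinite(trace)
    if nan_mask.any():
        bad_cum = np.concatenate(([0], np.cumsum(nan_mask)))
        valid = (bad_cum[starts + wlen] - bad_cum[starts]) == 0
    else:
        valid = np.ones(len(starts), dtype=bool)

    all_roots = np.full((len(starts), order), np.nan, dtype=complex)
    windows = np.lib.stride_tricks.sliding_window_view(
        np.nan_to_num(trace), wlen)[::stride]
    good = np.flatnonzero(valid)
    for lo in range(0, len(good), batch):
        sel = good[lo : lo + batch]
        coeffs, _ = burg_batch(windows[sel], order, demean=demean)
        all_roots[sel] = roots_batch(coeffs)
    return PoleTrack(times=times, roots=all_roots, delta=delta, stride=stride,
                     window_length=window_length, channel=channel, valid=valid)


def band_max_series(track: PoleTrack, band: tuple[float, float] = (10.0, 15.0)):
    """Per-window (r, f) of the least-damped in-band oscillator.

    Windows with no oscillator pole inside ``band`` get r = 0 and f = NaN;
    invalid (NaN-skipped) windows likewise.  Negative real roots (Nyquist
    oscillations) land at f = 1/(2 delta) and are excluded by any band below
    Nyquist.

    Returns (times, r_series, f_series).
    """
    lo, hi = band
    with np.errstate(invalid="ignore"):
        z = track.roots
        mag = np.abs(z)
        f = np.angle(z) / (2 * np.pi * track.delta)
        osc = np.imag(z) > 0
        neg_real = (np.imag(z) == 0) & (np.real(z) < 0)
        f = np.where(neg_real, 1.0 / (2 * track.delta), f)
        in_band = (osc | neg_real) & (f >= lo) & (f <= hi) & np.isfinite(mag)
    mag_masked = np.where(in_band, mag, -np.inf)
    best = np.argmax(mag_masked, axis=1)
    rows = np.arange(len(track.times))
    r_series = mag_masked[rows, best]
    f_series = f[rows, best]
    none = ~np.isfinite(r_series) | (r_series == -np.inf)
    r_series = np.where(none, 0.0, r_series)
    f_series = np.where(none, np.nan, f_series)
    r_series[~track.valid] = 0.0
    f_series[~track.valid] = np.nan
    return track.times, r_series, f_series
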