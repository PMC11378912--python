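"""IAAFT surrogate signals and surrogate-based threshold calibration.

An IAAFT surrogate shares the original signal's amplitude distribution
exactly (it is a permutation of the sample values) and its power spectrum
approximately, while destroying any nonlinear or nonstationary structure
such as transient spindle bursts.  An ensemble of n surrogates supports a
one-sided rank test at level 1/(n+1); the conventional n = 19 gives 5%.
Comparing the distribution of in-band pole magnitudes r between a real
signal and its surrogates calibrates the detection threshold r_b: genuine
oscillatory events produce excess mass at high r that surrogates lack.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ar import sliding_decomposition, band_max_series

__all__ = [
    "SurrogateEnsemble", "iaaft", "surrogate_ensemble", "threshold_calibration",
]


@dataclass
class SurrogateEnsemble:
    surrogates: np.ndarray            # (n, len(trace))
    iterations: np.ndarray            # per-surrogate iteration counts
    spectral_errors: np.ndarray       # final relative L2 spectral error
    seed: int

    @property
    def n(self) -> int:
        return self.surrogates.shape[0]

    @property
    def rank_test_level(self) -> float:
        """One-sided rank-test significance level 1/(n+1)."""
        return 1.0 / (self.n + 1)


def _spectral_error(candidate_amp: np.ndarray, target_amp: np.ndarray) -> float:
    denom = float(np.linalg.norm(target_amp))
    return float(np.linalg.norm(candidate_amp - target_amp)) / max(denom, 1e-300)


def iaaft(trace: np.ndarray, max_iter: int = 1000, tol: float = 0.01,
          seed=None, return_info: bool = False):
    """One iterative amplitude-adjusted Fourier-transform surrogate.

    Alternates (i) imposing the original Fourier amplitudes on the current
    iterate while keeping its phases and (ii) rank-replacing the values
    with the sorted original samples, so the value multiset is exact after
    every iteration.  Stops when the relative L2 error between the
    surrogate's and the original's spectral amplitudes drops below ``tol``
    or stops improving (the best iterate is returned, making the recorded
    error trajectory non-increasing); hitting ``max_iter`` returns the best
    iterate with its residual error recorded.
    """
    x = np.asarray(trace, dtype=float)
    if len(x) < 2 or not np.all(np.isfinite(x)):
        raise ValueError("need a finite trace of length >= 2")
    rng = np.random.default_rng(seed)
    sorted_x = np.sort(x)
    target_amp = np.abs(np.fft.rfft(x))

    s = rng.permutation(x)
    best, best_err, errors = s, np.inf, []
    for it in range(1, max_iter + 1):
        spec = np.fft.rfft(s)
        phases = np.angle(spec)
        s = np.fft.irfft(target_amp * np.exp(1j * phases), n=len(x))
        ranks = np.argsort(np.argsort(s, kind="stable"), kind="stable")
        s = sorted_x[ranks]
        err = _spectral_error(np.abs(np.fft.rfft(s)), target_amp)
        if err >= best_err - 1e-12:          # converged / stopped improving
            if err < best_err:
                best, best_err = s, err
                errors.append(err)
            break
        best, best_err = s, err
        errors.append(err)
        if err < tol:
            break
    info = {"iterations": len(errors), "spectral_error": best_err,
            "error_trajectory": np.array(errors)}
    return (best, info) if return_info else best


def surrogate_ensemble(trace: np.ndarray, n: int = 19, seed=None,
                       max_iter: int = 1000, tol: float = 0.01,
                       segment_length: float | None = 600.0,
                       fs: float | None = None) -> SurrogateEnsemble:
    """n independent IAAFT surrogates of a trace (or a random segment of it).

    Surrogates are computed on a randomly chosen ``segment_length``-second
    segment when ``fs`` is given and the trace is longer; shorter inputs
    use the full trace.  n = 19 gives a one-sided 5% rank-test level.
    """
    if n < 1:
        raise ValueError("need n >= 1 surrogates")
    x = np.asarray(trace, dtype=float)
    ss = np.random.SeedSequence(seed)
    seg_rng = np.random.default_rng(ss.spawn(1)[0])
    if fs is not None and segment_length is not None and len(x) > segment_length * fs:
        nseg = int(segment_length * fs)
        start = int(seg_rng.integers(0, len(x) - nseg + 1))
        x = x[start : start + nseg]
    child_seeds = ss.spawn(n)
    surrs, iters, errs = [], [], []
    for cs in child_seeds:
        s, info = iaaft(x, max_iter=max_iter, tol=tol,
                        seed=np.random.default_rng(cs), return_info=True)
        surrs.append(s)
        iters.append(info["iterations"])
        errs.append(info["spectral_error"])
    return SurrogateEnsemble(surrogates=np.array(surrs),
                             iterations=np.array(iters),
                             spectral_errors=np.array(errs),
                             seed=seed if isinstance(seed, int) else -1)


def threshold_calibration(trace: np.ndarray, ensemble: SurrogateEnsemble,
                          fs: float = 128.0, band=(10.0, 15.0), *,
                          r_bins=None, stride: int = 4,
                          ratio_min: float = 1.92, order: int = 8) -> dict:
    """Real-versus-surrogate distribution of in-band pole magnitudes.

    Histograms the per-window band-maximum r of the real trace against the
    pooled surrogates and forms their per-bin ratio (surrogate counts
    scaled to one trace).  The suggested detection threshold is the
    smallest bin edge from which the ratio stays at or above ``ratio_min``
    for all higher occupied bins; None when no such excess exists.  Bins
    unoccupied by surrogates have an undefined (NaN) ratio.
    """
    if r_bins is None:
        r_bins = np.arange(0.80, 1.0001, 0.01)
    r_bins = np.asarray(r_bins)

    def in_band_r(x):
        track = sliding_decomposition(x, fs=fs, stride=stride, order=order)
        _, r, _ = band_max_series(track, band)
        return r[r > 0]

    real_r = in_band_r(np.asarray(trace, dtype=float))
    surr_r = np.concatenate([in_band_r(s) for s in ensemble.surrogates])
    real_counts, _ = np.histogram(real_r, bins=r_bins)
    surr_counts, _ = np.histogram(surr_r, bins=r_bins)
    surr_scaled = surr_counts / ensemble.n
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(
            surr_scaled > 0,
            real_counts / np.where(surr_scaled > 0, surr_scaled, 1),
            np.where(real_counts > 0, np.inf, np.nan))

    # suggestion from cumulative tail mass: the smallest edge above which
    # the real signal carries at least `min_tail` windows and exceeds the
    # pooled surrogates by the configured factor
    min_tail = max(10, int(0.001 * len(real_r)))
    real_tail = np.cumsum(real_counts[::-1])[::-1].astype(float)
    surr_tail = np.cumsum(surr_scaled[::-1])[::-1]
    suggested = None
    for i in range(len(real_counts)):
        if real_tail[i] < min_tail:
            break
        tail_ratio = real_tail[i] / surr_tail[i] if surr_tail[i] > 0 else np.inf
        if tail_ratio >= ratio_min:
            suggested = float(r_bins[i])
            break
    return {"r_bins": r_bins, "real_counts": real_counts,
            "surrogate_counts": surr_scaled, "ratio": ratio,
            "suggested_r_b": suggested}
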