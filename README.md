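# spindleq

Damping-based detection and characterisation of sleep spindles in EEG/LFP
recordings, for sleep and systems neuroscientists who want a spindle metric
that does not reduce to amplitude.

## The method

NREM electrophysiological signals are modelled as a superposition of
stochastically driven damped harmonic oscillators.  Overlapping 1-s windows
of the 128 Hz signal, shifted by one sample, are fitted with an
autoregressive model of order p = 8 (Burg):

```
x(t_n) = Σ_{i=1..p} a_i x(t_{n-i}) + ε(t_n)
```

The characteristic polynomial z^p − Σ a_k z^{p−k} factors into poles
z_k = r_k e^{iφ_k}.  A complex-conjugate pair is an oscillator with
frequency f_k = φ_k/(2πΔ) and inverse-damping magnitude
r_k = exp(−γ_k Δ): r = 1 is a sustained (undamped) oscillation, smaller r
decays faster.  An order-8 model carries at most four oscillatory poles
(p = 2m + n over m oscillators and n relaxators).

Tracking the least-damped 10–15 Hz pole over time, an **oscillatory event**
starts when r crosses the upper threshold r_b = 0.92 and ends when it falls
back below; runs are merged while r stays above the hysteresis threshold
r_a = 0.90.  Events with in-band mean frequency are putative spindles and
are graded into **o-Quality** bins at r edges 0.92/0.93/0.94/0.95
(oQ1 weakest … oQ4 ≥ 0.95).  No band-pass filtering or waveform assumption
enters the detection.

Companion analyses, each its own module:

- `amplitude` — the classical comparator: 10–15 Hz Hilbert envelope, event
  amplitudes, Amp1–Amp4 categories count-matched to the oQ groups, and the
  r-vs-amplitude R².
- `slowwave` — Chebyshev-II (0.5–4 Hz, stopband 0.3/8 Hz, forward-backward)
  slow-wave detection (positive deflections between sub-zero minima ≥ 0.1 s
  apart, above-median amplitude), coupling within a 125-ms forward window,
  and the 700-ms shift control.
- `surrogates` — IAAFT surrogates (exact amplitude multiset, matched
  spectrum; n = 19 → one-sided 5% rank test) and the real-vs-surrogate
  calibration of r_b.
- `laminar` — 500-ms cross-channel co-occurrence into unique spindles with
  max-oQ assignment and spatial extent, current source density with cubic
  depth smoothing, 1-s laminar RMS profiles with PCA, and spike–phase
  circular statistics (mean angle, resultant length, Rayleigh test).
- `realtime` — strictly causal emulation of the closed-loop detector
  (12.5 Hz parametric biquad, 0.4-octave bandwidth, squared + exponentially
  smoothed power, 4.5× running-mean threshold, EMG/theta gates, 3-s
  refractory), comparative sensitivity against the offline detector, and
  stimulus-evoked EMG variance.
- `synth` — a ground-truth generator: 1/f background, driven-resonator
  bursts with known pole (r₀, f₀), slow waves with configurable coupling,
  laminar amplitude decay, REM theta, EMG twitches.

## Worked example

```sh
python examples/detect_spindles.py
```

```
scheduled bursts (all channels): 31
detected spindle events on LFP4: 55 (12.7 per NREM minute)
oQ bin counts: {1: 7, 2: 6, 3: 7, 4: 35}
median duration 0.03 s, median frequency 13.4 Hz, max r observed 0.992

channel     t1     t2  duration  max_r  f_at_max  mean_f  oq state
   LFP4 19.965 20.230     0.266  0.963    14.221  14.237   4  NREM
   LFP4 20.441 20.949     0.508  0.949    11.084  10.927   3  NREM
   ...
```

Each row is one detected event on the chosen laminar channel: half-open
[t1, t2) boundaries in seconds, `max_r` the least-damped 10–15 Hz pole
magnitude at the event's peak, `f_at_max` the pole frequency there, and
`oq` the quality bin.  Many brief, low-quality events alongside fewer long
high-oQ events is the expected shape of the distribution — spindles are
graded, not all-or-none.  The other scripts in `examples/` walk through the
amplitude comparator, slow-wave coupling, surrogate calibration, laminar
profiles, and the real-time emulation the same way.

A `spindleq` command-line interface wraps the same functions for shell use
(`spindleq detect|amplitude|slowwaves|couple|surrogate|laminar|realtime-eval|simulate`);
recordings are EDF or `.npz` bundles, hypnograms plain text (one label per
4-s epoch).

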