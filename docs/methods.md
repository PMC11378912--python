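# Methods

This note documents the models, parameter choices, numerical decisions and
known limitations of `spindleq`.  It states no empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Signal model and the o-Quality metric

The analysis treats an EEG/LFP trace as locally stationary output of a set
of stochastically driven damped harmonic oscillators plus relaxators.  Each
1-s window (128 Hz, shifted by one sample by default) is fitted with an
AR(8) model by the Burg recursion, which minimises the summed forward and
backward prediction error and guarantees all characteristic roots strictly
inside the unit circle.  The characteristic polynomial's roots are obtained
as companion-matrix eigenvalues (degree 8 is numerically benign; the batch
path stacks companion matrices into one LAPACK call).  A conjugate root
pair is one oscillator with frequency f = φ/(2πΔ) and magnitude
r = exp(−γΔ); positive real roots are relaxators (f = 0); negative real
roots are reported as single Nyquist-frequency oscillations — they carry
multiplicity 1 in the p = 2m + n accounting and can never fall in a
sub-Nyquist band of interest.

Windows are demeaned before fitting (switchable).  Numerically constant
windows return an all-zero model — all roots at the origin, maximum
damping — so flat artifact stretches do not abort batch runs or masquerade
as DC "oscillations".  Windows are timestamped at their centers
(symmetric latency for event boundaries).

Detection operates on the per-window maximum-r pole within 10–15 Hz
(band-maximum tracking; with at most four oscillators and a narrow band
this is equivalent to per-pole tracking except when two in-band poles
coexist, a pathological case).  Hysteresis: an event spans from the upward
r_b = 0.92 crossing to the downward crossing; consecutive supra-threshold
runs merge while the dip never falls below r_a = 0.90 (a dip exactly at
r_a merges — only falling *below* splits).  Crossing uses r ≥ r_b so the
event invariant max_r ≥ r_b is native.  At stride 1 boundaries are window
centers; at larger strides the r_b crossing is linearly interpolated
between centers.  No minimum duration is imposed by default (configurable),
so many one-window events appear at the low-oQ end; this is the expected
graded shape.  An event's mean frequency is the unweighted mean of its
windows' in-band pole frequencies (windows contribute equally at uniform
stride); both `mean_f` and `f_at_max` are emitted since either is a
defensible frequency tag.  o-Quality bins are half-open at
0.92/0.93/0.94/0.95 with the top bin closed below and unbounded above.

## Preprocessing

Resampling uses polyphase FIR anti-aliasing (`scipy.signal.resample_poly`),
chosen for band-limited fidelity near 10–15 Hz.  Epoch spectra are
one-sided Hanning-windowed periodograms of consecutive 4-s epochs (0.25 Hz
grid); density normalisation compensates the window power, and because all
spectral conclusions in this package are ratios (event vs event-free
epochs), they are normalisation-invariant.  Non-integer epoch sample
counts truncate to floor.  Event/epoch state restriction uses the midpoint
rule — an epoch "contains" an event when the event midpoint falls inside —
and Artifact epochs are always excluded.  Time is seconds from recording
start, boundaries half-open [t1, t2).

EDF reading goes through MNE; EDF writing is a minimal 16-bit encoder
(1-s records, µV physical units) because no installed library exports EDF.
Round-tripping is exact to the 16-bit quantisation step.

## Amplitude comparator

The envelope is the analytic-signal magnitude of the 4th-order zero-phase
Butterworth 10–15 Hz band-pass, computed at the acquisition rate (256 Hz)
rather than the 128 Hz analysis stream to preserve band fidelity.  The
stand-alone amplitude detector thresholds a moving-average-smoothed
envelope (0.2 s, in the style of classical RMS-envelope detectors; the
smoothing bridges the brief dips of a stochastically waxing-waning burst)
at 4.5× the mean envelope with a 0.5-s minimum duration — both mirrors of
common amplitude criteria and fully configurable, since no canonical
parameterisation exists.  Amp1–Amp4 categories are assigned by sorting
events by amplitude and cutting at the cumulative oQ-group counts, an
order-preserving partition.

The r-vs-amplitude association is the squared Pearson correlation.  Note a
measurement effect the synthetic experiments expose: low-amplitude bursts
are estimated with more noise-induced damping bias, so event-level R²
exceeds the generating population coupling.  Conclusions about dissociation
should quote both (the examples do).

## Slow waves and coupling

The slow-wave filter is a forward-backward Chebyshev II band-pass designed
by `cheb2ord` for a 0.5–4 Hz passband with stopband edges 0.3/8 Hz
(20 dB stopband per pass, squared by filtfilt; passband monotone).
Negative deflections are sub-zero local minima of the filtered trace;
candidate waves are positive maxima between consecutive minima ≥ 0.1 s
apart, and the default selection keeps amplitudes above the candidate
median (computed on the NREM-restricted candidate set when a hypnogram is
supplied).  The coupling anchor is the positive peak (configurable to the
trailing negative deflection); a slow wave counts as followed by a spindle
when a spindle onset lies in (anchor, anchor + 125 ms] — the right end
closed, so a lag of exactly the window couples — and the spindle-side
definition mirrors it.  The 700-ms shift control repeats the computation
with every slow-wave timestamp offset.  Detected-event onsets lag the true
burst onset by up to a few hundred ms (the sliding window must accumulate
evidence), which dilutes strict-window coupling percentages relative to
the generator's scheduled lags; the shift control and per-oQ gradients are
the robust readouts.

## IAAFT surrogates and threshold calibration

Standard IAAFT: alternate imposing the original Fourier amplitudes and
rank-replacing values with the sorted originals, so every iterate is an
exact permutation of the data (amplitude multiset preserved by
construction).  Iteration stops when the relative L2 spectral error drops
below 1% or stops improving; the best iterate is returned, so the recorded
error trajectory is non-increasing.  Defaults: max 1000 iterations, 10-min
random segments for long recordings (segment choice seeded), n = 19
surrogates for the one-sided 5% ensemble rank test.

Calibration compares histograms of in-band per-window r between the real
trace and pooled surrogates.  The suggested r_b is the smallest bin edge
above which the real signal's cumulative tail count both exceeds a minimum
mass (10 windows or 0.1%, guarding against empty surrogate bins) and
exceeds the surrogate tail by a configurable factor (default 1.92, i.e. a
92% excess).  A caveat the synthetic experiments make explicit: a
*stationary* surrogate inherits the sigma spectral bump and can cross a
fixed threshold near 0.92 *more* often than the original when bursts carry
a large share of total power; the real/surrogate separation is robust in
the high-r tail (r ≥ 0.95), which is what the calibration and the
surrogate-null tests use.  Emulated NREM test signals therefore keep the
sigma share small, as in real sleep spectra.

## Laminar and network analyses

Co-occurrence chaining is transitive: events sorted by center belong to one
unique spindle while consecutive gaps stay within 500 ms (provably equal to
the transitive closure of the pairwise relation on a line; a brute-force
union-find oracle pins the semantics in tests).  The unique spindle takes
the maximum oQ/r across members and its spatial extent is the member count
fraction plus the maximum distance from the max-r channel when geometry is
known.  CSD is the negative second spatial difference over depth; edge
channels are dropped rather than extrapolated, and cubic interpolation
(default 10× channel density) smooths across depth.  Laminar profiles are
per-channel 1-s RMS values averaged within layers; PCA of profiles uses
scikit-learn.  Spike phases come from linear interpolation of the unwrapped
10–15 Hz Hilbert phase at spike times; circular statistics use the exact
small-sample Rayleigh formula p = exp(√(1+4n+4(n²−(nR)²)) − (1+2n)) for
n < 50 and exp(−nR²) otherwise (cross-checked against pingouin in tests).

## Real-time emulation

The online path is strictly causal: a constant-peak-gain band-pass biquad
(audio-EQ parametric topology; center 12.5 Hz, −3 dB fractional bandwidth
0.4 octaves, response verified against the analytic design), squared
signal, exponential smoothing (τ = 0.1 s ≈ one spindle cycle, unstated in
closed-loop practice and configurable), and an upward crossing of 4.5× the
running mean of the smoothed power over the preceding 60 s of gate-clear
samples.  EMG and occipital-theta gates veto detections when their smoothed
power exceeds k× their own running baselines (k = 4 default — per-animal
manual settings have no canonical value).  Detections respect a 3-s
refractory.  Comparative sensitivity counts a real-time timestamp as
confirmed when it falls within [t1 − 0.25 s, t2 + 0.25 s] of an offline
event.  EMG responses are per-stimulus variances over 200 ms normalised to
the mean variance of unstimulated NREM epochs.

## Synthetic data: what it emulates and what it does not

Bursts are **driven AR(2) resonators**, not enveloped sinusoids, so each
burst has a well-defined true pole — the quantity the whole analysis
estimates.  Pole radii are defined at the 128 Hz analysis interval (the
damping coefficient γ is the physical quantity; at the 256 Hz acquisition
rate the generator uses r^(1/2)).  Defaults, chosen once as plausible NREM
conditions: burst rate 8/min of NREM with radii uniform on [0.90, 0.99]
and frequencies uniform on 10–15 Hz; durations lognormal around 0.9 s
(clipped 0.4–2.5 s); amplitudes lognormal (median 30 µV, shape 0.4 — many
neurophysiological quantities are lognormal) with a weak log-scale
population coupling to the radius (R² = 0.08); 1/f background (slope 1,
10 µV SD, 30% channel-shared); slow waves 10/min at ~60 µV with a 0.1-s
peak-to-burst lag and per-oQ coupling probabilities (0 by default; raised
explicitly in coupling experiments); spatial extent growing linearly in r₀
with exponential amplitude decay away from a center channel; REM theta at
7.5 Hz on the occipital channel; EMG white noise with 5× variance
transients for 200 ms after stimuli.  SNR is defined as burst RMS divided
by the background RMS within 10–15 Hz.

Not emulated: waveform asymmetries and travelling-wave dynamics, true
thalamo-cortical circuitry, state transitions with gradual spectra,
movement and electrode artifacts, and the heavy low-frequency
non-stationarity of real NREM.  Passing recovery tests therefore shows the
estimator chain is correct under its own assumptions, not that real-data
performance matches any particular figure.

## Numerical choices and test problem sizes

Sliding decomposition batches windows (default 65 536 per chunk) to keep
memory flat; a 5-min channel at stride 1 fits and factors ~38 000 windows
in a few seconds.  The test suite uses 3–10-min synthetic recordings,
500-trial estimator experiments on 16-s stationary segments, and 10⁴-fit
structural checks; these sizes give stable statistics at interactive run
times.  Estimator accuracy under additive background noise is
bias-limited: observation noise flattens the spectrum and biases the
fitted pole radius downward (about −0.1 at in-band SNR 3, shrinking to
near zero above SNR ≈ 15 for whole-segment fits), while max-over-windows
event statistics are biased upward by selection.  The recovery tests
document both effects; detection sensitivity for strong bursts is robust
to them.

## Known limitations

- Pole identity across windows is implicit (band-maximum tracking); two
  simultaneous in-band oscillators alias into one series.
- The amplitude comparator's parameters are conventions, not a reference
  standard; comparisons against it are relative.
- The IAAFT null is a stationary linear Gaussian process under a monotone
  static transform; it does not test against non-Gaussian stationary
  alternatives.
- Real-time gate thresholds are homogeneous multiples of running power; in
  practice per-subject manual calibration differs.
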