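# Methods

## Signal model

`gaitefs` analyses single-channel electrostatic-field-sensing (EFS) gait
recordings: the voltage induced on a remote electrode by the moving charge
of a walking body. Each step produces one smooth field excursion — a rise
to a local maximum as the foot leaves the ground (foot-off) and a fall to a
local minimum as it strikes the ground (foot-contact) — with the two feet
alternating at a cadence of roughly 1–2 steps/s. The acquisition chain is
assumed to sample at 1 kHz behind a 20 Hz hardware anti-interference
low-pass, so recordings reaching the package are already band-limited.

## Synthetic data generator

Clinical EFS recordings are not freely available, so the package ships a
generator that emulates the phenomenology rather than the electrostatics.
Each step is a positive Gaussian lobe (foot-off peak) followed by a
negative lobe (foot-contact trough). The lobes are placed antipodally —
peak at 25 % and trough at 75 % of the step period, sigma 7 % of the
period. Antipodal spacing cancels the even harmonics of the pulse train,
which keeps the step band spectrally compact; the ≥7-sigma gap between
adjacent-step lobes keeps inter-pulse leakage below 1e-11 of the peak
amplitude, so amplitude ratios measured on the waveform equal the
programmed asymmetry essentially exactly. Additive noise is white noise
band-passed to 10–20 Hz (zero-phase Butterworth) and scaled to a target RMS
relative to the unit foot-A amplitude. Only pulses whose full support fits
inside the trial are emitted, so no step is clipped by the window.

The tunable parameters, with defaults:

| parameter            | meaning                                   | default |
|----------------------|-------------------------------------------|---------|
| `step_freq_hz`       | cadence (steps/s)                         | 1.5     |
| `asymmetry`          | foot-B/foot-A amplitude scale, ≥ 1        | 1.0     |
| `timing_jitter_sd_s` | SD of the per-step period perturbation    | 0.0     |
| `hf_noise_amp`       | RMS of 10–20 Hz noise vs step amplitude   | 0.0     |
| `duration_s`         | trial length (s)                          | 30      |
| `sampling_rate_hz`   | sampling rate                             | 1000    |

The `asymmetry` dial scales pulse *amplitude* only (duration is left
unchanged) so that the peak-ratio contract is exact.

Cohort presets encode hemiparetic (HP) versus healthy-control (HC)
phenomenology: HP `asymmetry 1.6, jitter 0.04 s, hf_noise 0.40`; HC
`1.05, 0.01 s, 0.04`. Both cohorts share the 1.5 Hz nominal cadence, with
each subject drawing its own cadence within ±10 % and perturbing asymmetry
excess and noise amplitude by ±20 %, so repeat trials of a subject
correlate and the cohorts cannot be separated on cadence alone. The HP
noise amplitude is deliberately high (noise ≈ 38 % of signal power): the
hemiparetic signature the stability index responds to is precisely a large
high-frequency share of total energy, and at lower noise levels the
empirical-mode spectrum of the pulse train is dominated by pulse harmonics
rather than by the noise, which buries the cohort difference. All
randomness flows from a single integer seed through `SeedSequence.spawn`,
so a cohort is a pure function of its parameter sets.

What the generator does *not* emulate: electrode physics, body-electrode
distance and angle effects, amplitude drift, within-step shape variation
beyond amplitude scaling, double-support plateaus, and pathological
waveform morphologies beyond the three dials. Passing tests therefore show
that the pipeline recovers planted effects of these three kinds; they do
not validate the features against clinical recordings.

## Preprocessing

Two seconds are trimmed from each end of every trial (gait is not yet
steady at the start and end of a walk), then the retained segment is
z-scored, removing offset and amplitude so downstream features compare gait
shape only. The order trim → normalize is fixed: statistics are computed on
the steady-state segment. An optional zero-phase 4th-order Butterworth
low-pass is available for inputs that did not pass a hardware filter; it is
off by default. Constant sequences are rejected as degenerate rather than
silently propagated.

## Segmentation

Foot-off and foot-contact events are the local maxima and minima of the
waveform, found with a peak search constrained by a minimum same-type
separation (`min_period_s`, default 0.3 s ≈ max cadence 3.3 steps/s) and a
minimum prominence (0.3 in normalized units). Extrema are located on a
zero-phase low-passed copy of the signal, cut at `2 / min_period_s`
(≈ 6.7 Hz, comfortably above any plausible step band): without this,
high-frequency fluctuation at hemiparetic noise levels spawns spurious
extrema between steps. Event indices refer to the raw samples, and any
same-type run left after matching maxima and minima is reduced to its
strongest member, so the event sequence strictly alternates.

A gait cycle is the segment between consecutive foot-contact minima; `n`
contacts give `n − 1` contiguous cycles whose concatenation (plus leading
and trailing remainders) reconstructs the trial exactly. Cycles are
labelled A, B, A, B, …. Absolute left/right identity is unrecoverable from
a single channel; every downstream use is invariant to swapping the labels.

## Features

**Symmetry — dynamic time warping.** The DTW distance between two
sequences is the minimal cumulative cost over monotone alignments, with
local cost `|l_i − r_j|` and the standard step set {(1,0), (0,1), (1,1)},
unwindowed. The trial-level feature is the mean DTW distance over
consecutive cycle pairs — each pair opposes an A-step and a B-step, making
the mean invariant to relabelling and robust to unequal step counts; a
whole-concatenation mode (`mode="concat"`) is available behind a flag.
Larger values mean a less symmetric gait. Cycles are deliberately not
length-normalized before warping — accommodating duration differences is
what DTW is for. The dynamic program is numba-compiled; its global
optimality is checked against exhaustive path enumeration in the tests.

**Complexity — sample entropy.** SampEn(m, r) = −ln(B_{m+1}/B_m), the
negative log conditional probability that templates matching for m points
(Chebyshev distance ≤ r, self-matches excluded) still match at m+1. Both
match counts run over the same N − m template start points, which
guarantees B_{m+1} ≤ B_m and hence SampEn ≥ 0; the ratio cancels any common
normalising constant. Defaults are the physiological conventions m = 2,
r = 0.2·SD. The trial-level feature first decimates to 100 Hz (zero-phase,
anti-aliased): the signal band ends at 20 Hz, so no information is lost,
and the O(N²) template counting shrinks hundredfold. Note that SampEn is
systematically oversampling-dependent even for band-limited signals
(adjacent templates of a heavily oversampled signal are trivially similar,
and r = 0.2·SD does not compensate temporal correlation), so the decimation
rate is part of the feature's definition; what decimation preserves is the
ordering between less and more complex signals. r is taken from the SD of
the decimated sequence. When no template pair
matches at one of the lengths the value is undefined and reported as a
missing value, not ±∞.

**Stability — empirical mode decomposition.** EMD sifts the signal into
intrinsic mode functions (IMFs) ordered high → low frequency: each sift
subtracts the mean of the upper and lower natural-cubic-spline envelopes of
the extrema, with boundaries handled by mirroring two extrema per side.
Sifting of one mode stops when the Cauchy-type criterion
Σ(h_prev − h)² / Σh_prev² < 0.2 is met and the candidate satisfies the IMF
extrema/zero-crossing balance (±1), or after 100 iterations; extraction
stops when the residual has fewer than 3 extrema or 8 modes (configurable)
were extracted. The sum of IMFs plus residual reconstructs the input
exactly by construction. Eight modes is treated as an empirical observation
on long clinical recordings, not a requirement; the index below needs four.

The instantaneous amplitude (IA) of an IMF is the time-averaged magnitude
of its analytic (Hilbert) signal, with 5 % of samples at each edge excluded
to suppress end effects. Mean, sum and RMS aggregates are all positively
homogeneous, so the choice does not affect the ordering properties of the
ratio below; the mean is used. The stability index is

    SI = (IA₃ + IA₄) / (IA₁ + IA₂)

— large when the step band (modes 3–4) dominates high-frequency
fluctuation (modes 1–2), i.e. for a stable gait. SI is invariant to global
rescaling of the input, so it is indifferent to whether it is computed
before or after normalization.

## Group statistics

Each feature is compared between cohorts with a two-sided Mann–Whitney U
test: the exact permutation distribution for pooled samples of ≤ 16
tie-free observations, otherwise the normal approximation with tie and
continuity corrections. Significance is declared at p < 0.05 with no
multiplicity correction across the three features. The default unit of
analysis is the trial; a per-subject mode (trials averaged within subject
first) is available because repeat trials of a subject are not independent.

## Classification

The (symmetry, SampEn, SI) vector feeds four classifiers — RBF-kernel SVM
(C = 1, γ = 1/(3·var), i.e. scikit-learn's `scale`), decision tree (Gini,
no depth cap), kNN (k = 5) and a one-hidden-layer MLP (10 units,
backpropagation, ≤ 500 epochs, seed-pinned) — under stratified tenfold
cross-validation. Folds are subject-grouped by default so the five repeat
trials of a subject can never straddle the train/test boundary; ungrouped
trial-level folds are available behind a flag, and with repeat trials they
measure something weaker (recognition of seen subjects). Features are
standardized inside each fold, fit on the training split only. Decision
scores from all test folds are pooled into one ROC summarised by the AUC,
computed as the rank statistic U/(n₊n₋) with midrank ties; a per-fold-mean
AUC is available behind a flag.

## Numerical and design notes

- Determinism: every stochastic component (generator, fold shuffling,
  MLP/tree initialisation) derives from explicit integer seeds; a full run
  from one `RunConfig` is bit-reproducible.
- The generator's zero-mean contract is met by construction (mean
  subtraction of an already near-zero-mean pulse train).
- Event detection is invariant to constant offsets; prominence-based
  thresholds are expressed in normalized units.
- Degenerate inputs fail loudly with typed exceptions (constant sequences,
  too-short trials, fewer than four detected steps, undefined entropy,
  fewer than four IMFs, single-class folds). In cohort extraction these
  become flagged missing rows, never silent numbers; a run aborts only if
  every trial fails.
- Monotonicity experiments: the symmetry-vs-asymmetry grid uses one
  deterministic noise-free trial per point. The noise-driven grids (SampEn
  up, SI down) compare means over a fixed 5-realization ensemble per
  amplitude, because a single EMD run can split the step band across
  IMF3/IMF4 (ordinary EMD mode-splitting — deeper sifting aggravates
  rather than cures it), perturbing individual SI values without affecting
  the trend.
- Problem sizes: the default study is 2 × 15 subjects × 5 trials × 30 s at
  1 kHz (150 sequences), matching the reference study layout; unit tests
  and examples use reduced cohorts (e.g. 5–6 subjects × 2 trials × 12–20 s)
  that exercise identical code paths.

## Known limitations

- EMD mode allocation is data-adaptive: which numbered IMF carries the
  step band depends on cadence, noise level and realization. SI inherits
  this (see the ensemble note above); cohort-level comparisons are stable,
  single-trial SI values are noisy.
- The DTW symmetry feature scales with cycle length and sampling rate, so
  its magnitude is comparable only within a fixed acquisition protocol.
- SampEn magnitudes depend on the decimation rate; comparisons should fix
  the `SampEnConfig`.
- The Mann–Whitney exact mode is limited to small tie-free samples; beyond
  that the asymptotic approximation is used (accurate at the default
  cohort sizes).
- With five trials per subject the trial-level test overstates
  independence; the per-subject mode is the conservative alternative.
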