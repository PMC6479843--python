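"""Synthetic electrostatic gait-signal generator.

Real EFS gait recordings are quasi-periodic: each step produces one smooth
excursion of the body-charge field, rising to a local maximum as the foot
leaves the ground (foot-off) and falling to a local minimum as it strikes
the ground again (foot-contact), with the two feet alternating at a cadence
of roughly 1–2 steps per second.  Hemiparetic gait differs from healthy gait
in three ways that the generator exposes as independent dials:

* **asymmetry** — the paretic-side step produces a smaller (here: foot B a
  larger, the ratio is what matters) field excursion than the sound side;
* **timing jitter** — step-to-step period fluctuation (loss of rhythmicity);
* **high-frequency noise** — broadband fluctuation above the step band,
  reflecting tremor-like and sensor noise.

Each step is modelled as a positive Gaussian lobe (foot-off peak) followed
by a negative Gaussian lobe (foot-contact trough); foot-B steps are scaled
in amplitude by ``asymmetry``.  Additive noise is white noise band-passed to
10–20 Hz (the acquisition chain low-passes at 20 Hz), scaled to an RMS of
``hf_noise_amp`` relative to the unit foot-A step amplitude.  All randomness
derives from ``SynthParams.seed``; identical parameters give bit-identical
output.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import butter, filtfilt

from .errors import ParameterError
from .trial import RawTrial

# Pulse geometry, as fractions of the nominal step period: the foot-off lobe
# peaks 25% into the step, the foot-contact trough at 75%, both with a width
# (Gaussian sigma) of 7% of the period.  Antipodal lobe spacing (half a
# period) cancels the even harmonics of the pulse train, keeping the step
# band spectrally compact; the >7-sigma gap between adjacent-step lobes
# keeps inter-pulse leakage below 1e-11 of the peak amplitude, so peak
# ratios measured on the waveform equal the programmed asymmetry exactly.
_PEAK_FRAC = 0.25
_TROUGH_FRAC = 0.75
_SIGMA_FRAC = 0.07


@dataclass(frozen=True)
class SynthParams:
    """Parameters of one synthetic trial.

    Attributes
    ----------
    step_freq_hz
        Cadence in steps per second; physiological band is 1–2 Hz.
    asymmetry
        Amplitude scale of foot-B steps relative to foot-A steps, >= 1.
        1 means a perfectly symmetric gait.
    timing_jitter_sd_s
        Standard deviation (seconds) of the Gaussian perturbation applied to
        each step period, >= 0.
    hf_noise_amp
        RMS of the 10–20 Hz band-limited additive noise relative to the
        foot-A step amplitude, >= 0.
    duration_s
        Total trial length in seconds, > 0.
    sampling_rate_hz
        Samples per second (default 1000, matching the EFS acquisition).
    seed
        Integer RNG seed; all randomness flows from it.
    """

    step_freq_hz: float = 1.5
    asymmetry: float = 1.0
    timing_jitter_sd_s: float = 0.0
    hf_noise_amp: float = 0.0
    duration_s: float = 30.0
    sampling_rate_hz: float = 1000.0
    seed: int = 0

    def validate(self) -> None:
        if not self.sampling_rate_hz > 0:
            raise ParameterError("sampling_rate_hz must be > 0")
        if not 0 < self.step_freq_hz < self.sampling_rate_hz / 2:
            raise ParameterError(
                f"step_freq_hz must lie in (0, sampling_rate/2), got {self.step_freq_hz}"
            )
        if self.asymmetry < 1:
            raise ParameterError(f"asymmetry must be >= 1, got {self.asymmetry}")
        if self.timing_jitter_sd_s < 0:
            raise ParameterError("timing_jitter_sd_s must be >= 0")
        if self.hf_noise_amp < 0:
            raise ParameterError("hf_noise_amp must be >= 0")
        if not self.duration_s > 0:
            raise ParameterError("duration_s must be > 0")


# Default cohort presets: hemiparetic gait is markedly asymmetric, more
# irregular in timing, and carries far more high-frequency fluctuation than
# healthy gait.  Both cohorts share a nominal 1.5 Hz cadence (subjects draw
# their own within +/-10%), so no feature can separate the groups on
# cadence alone.
HP_PRESET = SynthParams(
    step_freq_hz=1.5, asymmetry=1.6, timing_jitter_sd_s=0.04, hf_noise_amp=0.40
)
HC_PRESET = SynthParams(
    step_freq_hz=1.5, asymmetry=1.05, timing_jitter_sd_s=0.01, hf_noise_amp=0.04
)


def _step_times(params: SynthParams, rng: np.random.Generator) -> np.ndarray:
    """Step onset times covering the trial, periods jittered N(0, sd^2).

    Only steps whose full pulse support (peak/trough lobes out to 9 sigma)
    fits inside the trial are emitted, so no pulse is clipped by the trial
    window and every step's waveform carries its programmed amplitude.
    """
    period = 1.0 / params.step_freq_hz
    start = (9.0 * _SIGMA_FRAC - _PEAK_FRAC + 0.03) * period
    last = params.duration_s - (_TROUGH_FRAC + 9.0 * _SIGMA_FRAC + 0.03) * period
    n_steps = max(0, int(np.floor((last - start) / period)) + 1)
    jitter = rng.normal(0.0, params.timing_jitter_sd_s, size=max(n_steps, 1))
    # Never let a jittered period collapse below 30% of nominal.
    periods = np.clip(period + jitter, 0.3 * period, None)
    onsets = start + np.concatenate([[0.0], np.cumsum(periods[:-1])])
    return onsets[onsets <= last + 1e-12]


def generate_trial(
    params: SynthParams,
    subject_id: str = "S00",
    group: str = "UNKNOWN",
    trial_id: str = "T00",
) -> RawTrial:
    """Generate one synthetic EFS gait trial.

    Returns a zero-mean quasi-periodic waveform of alternating step pulses
    (foot A at even step indices, foot B — scaled by ``params.asymmetry`` —
    at odd ones), with per-step period jitter and band-limited noise.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    fs = params.sampling_rate_hz
    n = int(round(params.duration_s * fs))
    t = np.arange(n) / fs
    period = 1.0 / params.step_freq_hz
    sigma = _SIGMA_FRAC * period

    x = np.zeros(n)
    onsets = _step_times(params, rng)
    half = 9.0 * sigma  # evaluation window half-width per lobe (tails < 1e-17)
    for k, t0 in enumerate(onsets):
        amp = params.asymmetry if k % 2 else 1.0
        for frac, sign in ((_PEAK_FRAC, 1.0), (_TROUGH_FRAC, -1.0)):
            c = t0 + frac * period
            lo = max(0, int((c - half) * fs))
            hi = min(n, int((c + half) * fs) + 1)
            if lo < hi:
                x[lo:hi] += sign * amp * np.exp(-((t[lo:hi] - c) ** 2) / (2 * sigma**2))

    # Noise is always drawn so the jitter stream is unaffected by its amplitude.
    white = rng.standard_normal(n)
    if fs > 2 * 20.0:
        b, a = butter(4, [10.0, 20.0], btype="bandpass", fs=fs)
        band = filtfilt(b, a, white)
    else:  # degenerate low-rate case: keep everything above 10 Hz that exists
        b, a = butter(4, 10.0, btype="highpass", fs=fs)
        band = filtfilt(b, a, white)
    rms = float(np.sqrt(np.mean(band**2)))
    if rms > 0:
        x = x + params.hf_noise_amp / rms * band

    x -= x.mean()
    return RawTrial(
        samples=x,
        sampling_rate_hz=fs,
        subject_id=subject_id,
        group=group,
        trial_id=trial_id,
    )


def generate_cohort(
    n_subjects: int,
    trials_per_subject: int,
    params_hp: SynthParams = HP_PRESET,
    params_hc: SynthParams = HC_PRESET,
) -> list[RawTrial]:
    """Generate a two-group cohort of labelled synthetic trials.

    Each subject draws its own deterministic perturbation of the cohort
    parameters (cadence uniform within ±10%, asymmetry excess scaled by
    ±20%, noise amplitude by ±20%), so the trials of one subject correlate
    and the cohorts are not trivially separable.  The full cohort is a pure
    function of the two parameter sets.
    """
    if n_subjects < 1 or trials_per_subject < 1:
        raise ParameterError("n_subjects and trials_per_subject must be >= 1")
    trials: list[RawTrial] = []
    for group, params in (("HP", params_hp), ("HC", params_hc)):
        params.validate()
        root = np.random.SeedSequence(params.seed)
        subject_seqs = root.spawn(n_subjects)
        for s, seq in enumerate(subject_seqs):
            srng = np.random.default_rng(seq)
            cadence = params.step_freq_hz * srng.uniform(0.9, 1.1)
            asym = 1.0 + (params.asymmetry - 1.0) * srng.uniform(0.8, 1.2)
            noise = params.hf_noise_amp * srng.uniform(0.8, 1.2)
            subject_id = f"{group}{s + 1:02d}"
            trial_seqs = seq.spawn(trials_per_subject)
            for r, tseq in enumerate(trial_seqs):
                tparams = replace(
                    params,
                    step_freq_hz=cadence,
                    asymmetry=asym,
                    hf_noise_amp=noise,
                    seed=int(tseq.generate_state(1)[0] % 2**31),
                )
                trials.append(
                    generate_trial(
                        tparams,
                        subject_id=subject_id,
                        group=group,
                        trial_id=f"{subject_id}_t{r + 1}",
                    )
                )
    return trials
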