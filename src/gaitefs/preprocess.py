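"""Trial preprocessing: edge trimming and amplitude normalization.

Subjects need an adjustment period before settling into steady gait, so a
fixed margin (2 s by default) is removed from both ends of every recording.
Each sequence is then z-scored so that downstream features compare gait
*shape* rather than absolute field amplitude, which depends on clothing,
humidity and electrode distance rather than on gait.  The pipeline order is
fixed: trim first, then normalize (statistics are computed on the retained
steady-state segment only).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, filtfilt

from .errors import DegenerateInputError, ParameterError, TrialTooShortError
from .trial import RawTrial


@dataclass(frozen=True)
class PreprocessConfig:
    """Preprocessing settings.

    ``trim_s`` seconds are dropped at each end (default 2).  ``normalization``
    is ``"zscore"`` or ``"none"``.  ``lowpass_hz`` optionally applies a
    zero-phase 4th-order Butterworth low-pass for inputs that were not
    hardware-filtered (the EFS front end already cuts at 20 Hz, so the
    default is no digital filter).
    """

    trim_s: float = 2.0
    normalization: str = "zscore"
    lowpass_hz: float | None = None

    def validate(self) -> None:
        if self.trim_s < 0:
            raise ParameterError("trim_s must be >= 0")
        if self.normalization not in ("zscore", "none"):
            raise ParameterError(f"unknown normalization {self.normalization!r}")
        if self.lowpass_hz is not None and not self.lowpass_hz > 0:
            raise ParameterError("lowpass_hz must be > 0 when given")


def trim(trial: RawTrial, trim_s: float = 2.0) -> RawTrial:
    """Remove ``trim_s`` seconds from both ends of the trial.

    Raises :class:`TrialTooShortError` if the trial is not strictly longer
    than ``2 * trim_s``.
    """
    if trim_s < 0:
        raise ParameterError("trim_s must be >= 0")
    if trim_s == 0:
        return trial
    k = int(round(trim_s * trial.sampling_rate_hz))
    if 2 * k >= trial.n_samples:
        raise TrialTooShortError(
            f"trial {trial.trial_id} ({trial.duration_s:.2f} s) too short to trim "
            f"{trim_s} s at each end"
        )
    return trial.with_samples(trial.samples[k : trial.n_samples - k])


def normalize(trial: RawTrial) -> RawTrial:
    """Z-score the trial: output has sample mean 0 and (population) SD 1.

    Idempotent and invariant to affine rescaling of the input.  A constant
    sequence has no amplitude structure to normalize and raises
    :class:`DegenerateInputError`.
    """
    x = trial.samples
    sd = float(np.std(x))
    if sd == 0:
        raise DegenerateInputError(f"trial {trial.trial_id} is constant; cannot normalize")
    return trial.with_samples((x - np.mean(x)) / sd)


def lowpass(trial: RawTrial, cutoff_hz: float, order: int = 4) -> RawTrial:
    """Zero-phase Butterworth low-pass, for inputs without hardware filtering."""
    if not 0 < cutoff_hz < trial.sampling_rate_hz / 2:
        raise ParameterError("cutoff_hz must lie in (0, Nyquist)")
    b, a = butter(order, cutoff_hz, btype="lowpass", fs=trial.sampling_rate_hz)
    return trial.with_samples(filtfilt(b, a, trial.samples))


def preprocess(trial: RawTrial, cfg: PreprocessConfig = PreprocessConfig()) -> RawTrial:
    """Apply the full preprocessing chain: trim -> (optional lowpass) -> normalize."""
    cfg.validate()
    out = trim(trial, cfg.trim_s)
    if cfg.lowpass_hz is not None:
        out = lowpass(out, cfg.lowpass_hz)
    if cfg.normalization == "zscore":
        out = normalize(out)
    return out
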