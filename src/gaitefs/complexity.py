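"""Sample-entropy gait-complexity feature.

Sample entropy (SampEn) quantifies the irregularity of a time series as the
negative log of the conditional probability that two segments matching for
``m`` points (Chebyshev distance <= r, self-matches excluded) still match
at length ``m + 1``:

    SampEn(m, r, N) = -ln( B_{m+1}(r) / B_m(r) )

A perfectly repetitive signal has SampEn 0; broadband noise is high.  The
conventional parameters for physiological signals are used by default:
m = 2 and r = 0.2 times the sequence's standard deviation.

The trial-level feature decimates the 1 kHz sequence to 100 Hz first (the
signal is hardware-band-limited to 20 Hz, so this preserves the full band
while making the O(N^2) template counting cheap); the tolerance r is taken
from the SD of the decimated sequence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.signal import decimate

from .errors import ParameterError, UndefinedEntropyError
from .trial import RawTrial

_CHUNK = 256  # rows of the pairwise distance block computed at once


@dataclass(frozen=True)
class SampEnConfig:
    """Sample-entropy settings: embedding m, tolerance factor, decimation."""

    m: int = 2
    r_factor: float = 0.2
    downsample_to_hz: float | None = 100.0

    def validate(self, sampling_rate_hz: float | None = None) -> None:
        if self.m < 1:
            raise ParameterError("m must be >= 1")
        if not self.r_factor > 0:
            raise ParameterError("r_factor must be > 0")
        if (
            self.downsample_to_hz is not None
            and sampling_rate_hz is not None
            and self.downsample_to_hz > sampling_rate_hz
        ):
            raise ParameterError("downsample_to_hz cannot exceed the sampling rate")


def _match_counts(x: np.ndarray, m: int, r: float) -> tuple[int, int]:
    """Count template pairs matching at lengths m and m+1.

    Both counts run over the same N-m template start points (the standard
    convention, which guarantees an (m+1)-match implies an m-match and hence
    SampEn >= 0).  Pairs are unordered, i < j; the ratio is unaffected.
    """
    n_t = x.size - m  # templates of length m+1 starting at 0..n_t-1
    w = sliding_window_view(x, m + 1)[:n_t]  # (n_t, m+1)
    b = a = 0
    for lo in range(0, n_t, _CHUNK):
        hi = min(lo + _CHUNK, n_t)
        # distances of templates lo..hi-1 against all later templates
        diff = np.abs(w[lo:hi, None, :] - w[None, lo:, :])  # (hi-lo, n_t-lo, m+1)
        d_m = diff[:, :, :m].max(axis=2)
        d_m1 = np.maximum(d_m, diff[:, :, m])
        iu = np.triu_indices(hi - lo, k=1, m=n_t - lo)
        b += int(np.count_nonzero(d_m[iu] <= r))
        a += int(np.count_nonzero(d_m1[iu] <= r))
    return a, b


def sample_entropy(x: np.ndarray, m: int = 2, r: float | None = None) -> float:
    """SampEn of a 1-D sequence with Chebyshev matching tolerance ``r``.

    ``r`` defaults to 0.2 times the SD of ``x``.  Raises
    :class:`UndefinedEntropyError` when no template pairs match at one of
    the two lengths (the log ratio is then undefined).
    """
    x = np.asarray(x, dtype=float).ravel()
    if m < 1:
        raise ParameterError("m must be >= 1")
    if x.size < m + 2:
        raise ParameterError(f"need at least m + 2 = {m + 2} samples, got {x.size}")
    if r is None:
        r = 0.2 * float(np.std(x))
    if not r > 0:
        raise ParameterError("tolerance r must be > 0")
    a, b = _match_counts(x, m, r)
    if b == 0 or a == 0:
        raise UndefinedEntropyError(
            f"no template matches at length {'m' if b == 0 else 'm+1'} (m={m}, r={r:g})"
        )
    return float(-np.log(a / b))


def complexity_feature(trial: RawTrial, cfg: SampEnConfig = SampEnConfig()) -> float:
    """Trial-level SampEn: decimate, set r = r_factor * SD, compute.

    Expects a trimmed, normalized trial.  Decimation uses scipy's zero-phase
    anti-aliased decimator; a non-integer rate ratio is rounded to the
    nearest integer factor.
    """
    cfg.validate(trial.sampling_rate_hz)
    x = trial.samples
    if cfg.downsample_to_hz is not None:
        factor = int(round(trial.sampling_rate_hz / cfg.downsample_to_hz))
        if factor > 1:
            x = decimate(x, factor, zero_phase=True)
    r = cfg.r_factor * float(np.std(x))
    return sample_entropy(x, m=cfg.m, r=r)
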