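"""EMD-based gait-stability index.

Empirical mode decomposition (EMD) adaptively splits a non-stationary
signal into intrinsic mode functions (IMFs) ordered from high to low
frequency, by repeatedly *sifting*: subtracting the mean of the upper and
lower cubic-spline envelopes of the extrema until the component is locally
symmetric.  For a gait field signal the first IMFs carry high-frequency
fluctuation (tremor, sensor noise) while later IMFs carry the step-band
oscillation itself.

The stability index (SI) compares the Hilbert-envelope energy of the
mid-band modes against the high-frequency modes:

    SI = (IA3 + IA4) / (IA1 + IA2)

where IA_k is the time-averaged instantaneous amplitude of IMF k.  A stable
gait concentrates energy in the step band (large SI); a gait contaminated
by high-frequency fluctuation drives IA1 + IA2 up and SI down.  SI is
invariant to global rescaling of the input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import hilbert

from .errors import DegenerateInputError, ParameterError
from .trial import RawTrial


@dataclass(frozen=True)
class EMDConfig:
    """Sifting controls.

    ``sift_sd_threshold`` is the Cauchy-type stopping criterion: sifting of
    one mode stops when the relative energy of the last correction,
    sum((h_prev - h)^2) / sum(h_prev^2), drops below it (and the candidate
    satisfies the IMF extrema/zero-crossing balance), or after
    ``max_sift_iters``.  ``boundary`` extends envelopes by mirroring two
    extrema per side ("mirror" is the only method implemented).
    """

    max_imfs: int = 8
    sift_sd_threshold: float = 0.2
    max_sift_iters: int = 100
    boundary: str = "mirror"

    def validate(self) -> None:
        if self.max_imfs < 4:
            raise ParameterError("max_imfs must be >= 4 (SI needs IMF1-IMF4)")
        if not self.sift_sd_threshold > 0:
            raise ParameterError("sift_sd_threshold must be > 0")
        if self.max_sift_iters < 1:
            raise ParameterError("max_sift_iters must be >= 1")
        if self.boundary != "mirror":
            raise ParameterError("only mirror boundary extension is implemented")


@dataclass(frozen=True)
class IMFDecomposition:
    """Ordered IMFs (index 0 = highest frequency) plus the final residual."""

    imfs: list[np.ndarray]
    residual: np.ndarray
    source_length: int

    @property
    def n_imfs(self) -> int:
        return len(self.imfs)

    def reconstruct(self) -> np.ndarray:
        out = self.residual.copy()
        for imf in self.imfs:
            out += imf
        return out


def _local_extrema(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of strict local maxima and minima (plateaus take one index)."""
    d = np.diff(x)
    # collapse exact plateaus so sign changes are detectable
    s = np.sign(d)
    nz = s != 0
    if not nz.any():
        return np.array([], dtype=int), np.array([], dtype=int)
    # forward-fill zero signs with the previous non-zero sign
    idx = np.where(nz, np.arange(s.size), 0)
    np.maximum.accumulate(idx, out=idx)
    filled = s[idx]
    turn = np.where(filled[1:] != filled[:-1])[0] + 1
    maxima = turn[filled[turn] < 0]
    minima = turn[filled[turn] > 0]
    return maxima, minima


def _mirrored_spline(idx: np.ndarray, val: np.ndarray, n: int) -> np.ndarray:
    """Natural cubic spline through (idx, val), mirror-extended two knots per side."""
    pre_i = -idx[:2][::-1]
    pre_v = val[:2][::-1]
    post_i = 2 * (n - 1) - idx[-2:][::-1]
    post_v = val[-2:][::-1]
    xi = np.concatenate([pre_i, idx, post_i])
    yi = np.concatenate([pre_v, val, post_v])
    # mirroring can duplicate knot positions when an extremum sits on the edge
    xi, keep = np.unique(xi, return_index=True)
    yi = yi[keep]
    return CubicSpline(xi, yi, bc_type="natural")(np.arange(n))


def _zero_crossings(x: np.ndarray) -> int:
    s = np.sign(x)
    s = s[s != 0]
    return int(np.count_nonzero(s[1:] != s[:-1]))


def emd(x: np.ndarray, cfg: EMDConfig = EMDConfig()) -> IMFDecomposition:
    """Decompose ``x`` into IMFs by sifting with cubic-spline envelopes.

    Extraction stops when the residual has fewer than 3 extrema (or
    ``cfg.max_imfs`` modes were extracted).  The sum of the IMFs plus the
    residual reconstructs the input exactly, by construction.
    """
    cfg.validate()
    x = np.asarray(x, dtype=float).ravel()
    if x.size < 16:
        raise ParameterError(f"emd needs at least 16 samples, got {x.size}")
    if float(np.ptp(x)) == 0.0:
        raise DegenerateInputError("constant input cannot be decomposed")

    imfs: list[np.ndarray] = []
    residual = x.copy()
    n = x.size
    while len(imfs) < cfg.max_imfs:
        maxima, minima = _local_extrema(residual)
        if maxima.size + minima.size < 3 or maxima.size < 2 or minima.size < 2:
            break
        h = residual.copy()
        for _ in range(cfg.max_sift_iters):
            maxima, minima = _local_extrema(h)
            if maxima.size < 2 or minima.size < 2:
                break
            upper = _mirrored_spline(maxima, h[maxima], n)
            lower = _mirrored_spline(minima, h[minima], n)
            mean_env = 0.5 * (upper + lower)
            h_new = h - mean_env
            denom = float(np.sum(h**2))
            sd = float(np.sum((h - h_new) ** 2)) / denom if denom > 0 else 0.0
            h = h_new
            if sd < cfg.sift_sd_threshold:
                mx, mn = _local_extrema(h)
                if abs((mx.size + mn.size) - _zero_crossings(h)) <= 1:
                    break
        imfs.append(h)
        residual = residual - h
    return IMFDecomposition(imfs=imfs, residual=residual, source_length=n)


def instantaneous_amplitude(imf: np.ndarray, edge_frac: float = 0.05) -> float:
    """Time-averaged Hilbert-envelope magnitude of one IMF.

    The first and last ``edge_frac`` of the samples are excluded from the
    average to suppress the Hilbert transform's end effects.  Positively
    homogeneous: doubling the IMF doubles the result.
    """
    imf = np.asarray(imf, dtype=float).ravel()
    if imf.size == 0:
        raise ParameterError("instantaneous_amplitude needs a non-empty sequence")
    env = np.abs(hilbert(imf))
    k = int(edge_frac * imf.size)
    if imf.size - 2 * k < 1:
        k = 0
    return float(np.mean(env[k : imf.size - k]))


def stability_index_from_ia(ia: np.ndarray) -> float:
    """SI = (IA3 + IA4) / (IA1 + IA2) from per-IMF instantaneous amplitudes."""
    ia = np.asarray(ia, dtype=float).ravel()
    if ia.size < 4:
        raise ParameterError("stability index needs IA of at least 4 IMFs")
    denom = ia[0] + ia[1]
    if denom == 0:
        raise DegenerateInputError("IA1 + IA2 is zero; stability index undefined")
    return float((ia[2] + ia[3]) / denom)


def stability_index(decomp: IMFDecomposition) -> float:
    """Stability index of a decomposition (requires at least 4 IMFs)."""
    if decomp.n_imfs < 4:
        raise DegenerateInputError(
            f"stability index needs >= 4 IMFs, decomposition has {decomp.n_imfs}"
        )
    ia = np.array([instantaneous_amplitude(decomp.imfs[k]) for k in range(4)])
    return stability_index_from_ia(ia)


def stability_feature(trial: RawTrial, cfg: EMDConfig = EMDConfig()) -> float:
    """Trial-level stability index: EMD of the trial, then SI of IMFs 1-4."""
    return stability_index(emd(trial.samples, cfg))


def ia_table(decomp: IMFDecomposition, trial_id: str = ""):
    """Per-IMF instantaneous-amplitude report: trial_id, imf_index (1-based), ia."""
    import pandas as pd

    return pd.DataFrame(
        {
            "trial_id": trial_id,
            "imf_index": np.arange(1, decomp.n_imfs + 1),
            "ia": [instantaneous_amplitude(imf) for imf in decomp.imfs],
        }
    )
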