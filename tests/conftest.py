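"""Shared fixtures and independent brute-force oracles.

The oracles deliberately avoid the implementation's algorithms: DTW by
exhaustive enumeration of every monotone warping path, sample entropy by
direct triple-loop template counting, the Mann-Whitney exact p by full
enumeration of group assignments, and AUC by counting score pairs.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest

from gaitefs import RawTrial, SynthParams, generate_trial


# --------------------------------------------------------------- oracles


def dtw_brute(a, b) -> float:
    """Minimal warping cost by enumerating every monotone path."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n, m = a.size, b.size
    best = [math.inf]

    def walk(i: int, j: int, cost: float) -> None:
        cost += abs(a[i] - b[j])
        if cost >= best[0]:
            return  # cannot improve; every local cost is >= 0
        if i == n - 1 and j == m - 1:
            best[0] = cost
            return
        if i + 1 < n and j + 1 < m:
            walk(i + 1, j + 1, cost)
        if i + 1 < n:
            walk(i + 1, j, cost)
        if j + 1 < m:
            walk(i, j + 1, cost)

    walk(0, 0, 0.0)
    return best[0]


def sampen_brute(x, m: int, r: float) -> float | None:
    """Sample entropy by direct template-pair counting; None if undefined."""
    x = np.asarray(x, dtype=float)
    n_t = x.size - m  # templates considered at both lengths
    b_count = a_count = 0
    for i in range(n_t):
        for j in range(n_t):
            if i == j:
                continue
            if max(abs(x[i + k] - x[j + k]) for k in range(m)) <= r:
                b_count += 1
                if abs(x[i + m] - x[j + m]) <= r:
                    a_count += 1
    if b_count == 0 or a_count == 0:
        return None
    return -math.log(a_count / b_count)


def mannwhitney_exact_brute(a, b) -> tuple[float, float]:
    """U of the first sample and the exact two-sided p by full enumeration."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    n_a = a.size

    def u_of(sample_a, sample_b) -> float:
        return float(
            sum((x > y) + 0.5 * (x == y) for x in sample_a for y in sample_b)
        )

    u_obs = u_of(a, b)
    us = []
    for idx in itertools.combinations(range(pooled.size), n_a):
        mask = np.zeros(pooled.size, dtype=bool)
        mask[list(idx)] = True
        us.append(u_of(pooled[mask], pooled[~mask]))
    us = np.array(us)
    p_le = np.mean(us <= u_obs)
    p_ge = np.mean(us >= u_obs)
    return u_obs, min(1.0, 2.0 * min(p_le, p_ge))


def auc_brute(scores, labels) -> float:
    """AUC by counting positive-negative score pairs, ties worth one half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    pos = scores[labels]
    neg = scores[~labels]
    wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
    return float(wins) / (pos.size * neg.size)


# --------------------------------------------------------------- fixtures


@pytest.fixture(scope="session")
def clean_trial() -> RawTrial:
    """Noise-free, jitter-free, symmetric trial with a sample-exact period.

    step_freq 1.25 Hz at 1 kHz gives an 800-sample period, so every cycle
    occupies an identical sample grid.
    """
    return generate_trial(
        SynthParams(
            step_freq_hz=1.25,
            asymmetry=1.0,
            timing_jitter_sd_s=0.0,
            hf_noise_amp=0.0,
            duration_s=12.0,
            seed=7,
        )
    )


@pytest.fixture(scope="session")
def asym_trial() -> RawTrial:
    """Noise-free trial with a 2:1 foot-B/foot-A amplitude ratio."""
    return generate_trial(
        SynthParams(
            step_freq_hz=1.25,
            asymmetry=2.0,
            timing_jitter_sd_s=0.0,
            hf_noise_amp=0.0,
            duration_s=12.0,
            seed=3,
        )
    )


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
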