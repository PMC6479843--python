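"""Sample-entropy contracts and oracle agreement."""

import numpy as np
import pytest

from conftest import sampen_brute
from gaitefs import (
    ParameterError,
    RawTrial,
    SampEnConfig,
    UndefinedEntropyError,
    complexity_feature,
    sample_entropy,
)
from gaitefs.complexity import _match_counts


def test_constant_sequence_has_zero_entropy():
    # every template matches every other at both lengths: -ln(1) = 0
    assert sample_entropy(np.ones(8), m=2, r=0.2) == 0.0


def test_perfectly_repeating_pattern():
    # value frozen from the brute-force template-counting oracle
    x = np.array([1, 2, 3, 1, 2, 3, 1, 2], dtype=float)
    assert sample_entropy(x, m=2, r=0.5) == pytest.approx(0.0, abs=1e-12)
    assert sampen_brute(x, 2, 0.5) == pytest.approx(0.0, abs=1e-12)


@pytest.mark.parametrize("m", [1, 2])
def test_matches_brute_force_counting(m, rng):
    for _ in range(25):
        n = int(rng.integers(m + 3, 31))
        x = rng.integers(0, 6, size=n).astype(float)
        for r_mult in (0.2, 0.5, 1.0):
            r = r_mult * max(x.std(), 1e-9)
            expected = sampen_brute(x, m, r)
            if expected is None:
                with pytest.raises(UndefinedEntropyError):
                    sample_entropy(x, m=m, r=r)
            else:
                assert sample_entropy(x, m=m, r=r) == pytest.approx(expected, abs=1e-12)


def test_noise_more_complex_than_sinusoid(rng):
    n = 1000
    noise = rng.standard_normal(n)
    tone = np.sqrt(2.0) * np.sin(2 * np.pi * 7 * np.arange(n) / n)
    assert sample_entropy(noise, 2) > sample_entropy(tone, 2)


def test_longer_matches_never_exceed_shorter(rng):
    for _ in range(20):
        x = rng.standard_normal(int(rng.integers(10, 60)))
        a, b = _match_counts(x, 2, 0.3)
        assert a <= b


def test_affine_invariance_when_r_tracks_sd(rng):
    x = rng.standard_normal(200)
    y = 3.7 * x - 11.0
    sa = sample_entropy(x, 2, 0.2 * x.std())
    sb = sample_entropy(y, 2, 0.2 * y.std())
    assert sa == pytest.approx(sb, abs=1e-9)


def test_undefined_when_no_templates_match():
    x = np.arange(0.0, 100.0, 10.0)  # all templates > r apart
    with pytest.raises(UndefinedEntropyError):
        sample_entropy(x, m=2, r=0.5)


def test_input_validation():
    with pytest.raises(ParameterError):
        sample_entropy(np.ones(3), m=2)
    with pytest.raises(ParameterError):
        sample_entropy(np.ones(10), m=0)


def test_oversampling_effect_systematic_and_ordering_preserved(rng):
    # SampEn of a band-limited signal falls as oversampling grows (adjacent
    # templates become trivially similar), so the feature is defined at a
    # fixed decimation rate; what decimation must preserve is the ordering
    # between less and more complex signals
    from scipy.signal import butter, filtfilt

    from gaitefs import SynthParams, generate_trial, preprocess

    fs = 1000.0
    b, a = butter(4, 8.0, btype="lowpass", fs=fs)
    x = filtfilt(b, a, rng.standard_normal(int(8 * fs)))
    x = (x - x.mean()) / x.std()
    tr = RawTrial(x, fs)
    vals = [
        complexity_feature(tr, SampEnConfig(downsample_to_hz=hz))
        for hz in (500.0, 250.0, 100.0)
    ]
    assert vals[0] < vals[1] < vals[2]

    clean = preprocess(generate_trial(
        SynthParams(step_freq_hz=1.5, hf_noise_amp=0.02, duration_s=10.0, seed=2)))
    noisy = preprocess(generate_trial(
        SynthParams(step_freq_hz=1.5, hf_noise_amp=0.3, duration_s=10.0, seed=2)))
    for hz in (250.0, 100.0):
        cfg = SampEnConfig(downsample_to_hz=hz)
        assert complexity_feature(noisy, cfg) > complexity_feature(clean, cfg)


def test_config_validation():
    with pytest.raises(ParameterError):
        SampEnConfig(r_factor=0.0).validate()
    with pytest.raises(ParameterError):
        SampEnConfig(downsample_to_hz=2000.0).validate(1000.0)
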