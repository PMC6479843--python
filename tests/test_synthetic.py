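"""Generator contracts: determinism, pulse geometry, cohort layout."""

import dataclasses

import numpy as np
import pytest
from scipy.signal import find_peaks, welch

from gaitefs import ParameterError, SynthParams, generate_cohort, generate_trial


def test_identical_params_give_bit_identical_trials():
    p = SynthParams(step_freq_hz=1.5, timing_jitter_sd_s=0.03, hf_noise_amp=0.1, seed=7)
    a = generate_trial(p)
    b = generate_trial(p)
    assert np.array_equal(a.samples, b.samples)


def test_trial_length_matches_duration():
    p = SynthParams(duration_s=10.0, sampling_rate_hz=1000.0)
    tr = generate_trial(p)
    assert abs(tr.n_samples - 10_000) <= 1
    assert abs(np.mean(tr.samples)) < 1e-12  # zero-mean by construction


def test_symmetric_noise_free_trial_is_periodic(clean_trial):
    # 1.25 Hz at 1 kHz: the period is exactly 800 samples
    x = clean_trial.samples
    lag = 800
    core = slice(1000, x.size - 1000 - lag)
    assert np.allclose(x[core], x[core.start + lag : core.stop + lag], atol=1e-9)
    # even- and odd-indexed step pulses are identical: equal peak heights
    peaks, _ = find_peaks(x, prominence=0.3)
    assert np.ptp(x[peaks]) < 1e-9


def test_peak_ratio_equals_asymmetry(asym_trial):
    peaks, _ = find_peaks(asym_trial.samples, prominence=0.3)
    vals = asym_trial.samples[peaks]
    ratio = vals[1::2].mean() / vals[0::2].mean()
    assert ratio == pytest.approx(2.0, abs=1e-9)


def test_autocorrelation_recovers_step_period():
    p = SynthParams(step_freq_hz=1.6, duration_s=20.0, seed=2)
    x = generate_trial(p).samples
    x = x - x.mean()
    ac = np.correlate(x, x, "full")[x.size - 1 :]
    fs = p.sampling_rate_hz
    lo, hi = int(0.5 / 1.6 * fs), int(1.5 / 1.6 * fs)
    lag = lo + int(np.argmax(ac[lo:hi]))
    assert abs(lag - fs / p.step_freq_hz) <= 1.0


def test_noise_amplitude_monotone_in_highband_power():
    base = SynthParams(step_freq_hz=1.5, duration_s=15.0, seed=5)
    powers = []
    for amp in (0.0, 0.1, 0.2, 0.3):
        tr = generate_trial(dataclasses.replace(base, hf_noise_amp=amp))
        f, pxx = welch(tr.samples, fs=tr.sampling_rate_hz, nperseg=4096)
        powers.append(float(pxx[f > 10.0].sum()))
    assert all(p1 < p2 for p1, p2 in zip(powers, powers[1:]))


def test_cohort_count_matches_study_layout():
    trials = generate_cohort(15, 5)
    assert len(trials) == 150
    assert sum(t.group == "HP" for t in trials) == 75
    assert len({t.trial_id for t in trials}) == 150


def test_minimal_cohort_and_determinism():
    a = generate_cohort(1, 1)
    b = generate_cohort(1, 1)
    assert len(a) == 2 and {t.group for t in a} == {"HP", "HC"}
    assert all(np.array_equal(x.samples, y.samples) for x, y in zip(a, b))


def test_trials_within_subject_share_cadence():
    from gaitefs import detect_events, preprocess

    trials = generate_cohort(2, 3)
    # same subject: identical drawn cadence => near-identical step counts
    by_subject = {}
    for t in trials:
        by_subject.setdefault(t.subject_id, []).append(t)
    for group in by_subject.values():
        counts = [detect_events(preprocess(t)).foot_off_idx.size for t in group]
        assert max(counts) - min(counts) <= 2


@pytest.mark.parametrize(
    "bad",
    [
        {"step_freq_hz": 0.0},
        {"step_freq_hz": 600.0},
        {"asymmetry": 0.8},
        {"timing_jitter_sd_s": -0.01},
        {"hf_noise_amp": -0.1},
        {"duration_s": 0.0},
        {"sampling_rate_hz": -1.0},
    ],
)
def test_invalid_params_rejected(bad):
    with pytest.raises(ParameterError):
        generate_trial(SynthParams(**bad))


def test_cohort_rejects_empty_layout():
    with pytest.raises(ParameterError):
        generate_cohort(0, 5)
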