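"""Generate a small synthetic hemiparetic/healthy gait cohort and look at it.

Each trial is a 30 s single-channel voltage waveform at 1 kHz: one smooth
pulse per step (local maximum = foot-off, local minimum = foot-contact),
feet alternating, with cohort-specific asymmetry, timing jitter and
high-frequency noise.
"""

import numpy as np

from gaitefs import HC_PRESET, HP_PRESET, generate_cohort

trials = generate_cohort(n_subjects=3, trials_per_subject=2)
print(f"generated {len(trials)} trials "
      f"({sum(t.group == 'HP' for t in trials)} HP, "
      f"{sum(t.group == 'HC' for t in trials)} HC)")
print(f"HP preset: asymmetry {HP_PRESET.asymmetry}, jitter {HP_PRESET.timing_jitter_sd_s}s, "
      f"noise {HP_PRESET.hf_noise_amp}")
print(f"HC preset: asymmetry {HC_PRESET.asymmetry}, jitter {HC_PRESET.timing_jitter_sd_s}s, "
      f"noise {HC_PRESET.hf_noise_amp}")

tr = trials[0]
print(f"\nfirst trial: {tr.trial_id} ({tr.group}), {tr.duration_s:.0f} s "
      f"at {tr.sampling_rate_hz:.0f} Hz, {tr.n_samples} samples")
print(f"voltage range [{tr.samples.min():.2f}, {tr.samples.max():.2f}] "
      f"(arbitrary units, zero mean: {np.mean(tr.samples):.2e})")
# The asymmetric HP waveform alternates a low foot-A pulse with a high
# foot-B pulse; the range above reflects the larger of the two.
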