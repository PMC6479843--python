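"""Extract the three gait features from one synthetic hemiparetic trial.

The pipeline is: trim 2 s from each end -> z-score -> detect foot-off /
foot-contact events -> split into per-step cycles -> compute
(1) DTW symmetry: mean warping cost between consecutive opposite-foot
    cycles (larger = less symmetric gait),
(2) sample entropy (m=2, r=0.2*SD, 100 Hz): signal irregularity,
(3) stability index: EMD mode energies (IA3+IA4)/(IA1+IA2); high when the
    step band dominates high-frequency fluctuation.
"""

import dataclasses

from gaitefs import (
    HP_PRESET,
    complexity_feature,
    detect_events,
    generate_trial,
    preprocess,
    split_cycles,
    stability_feature,
    symmetry_feature,
)

trial = generate_trial(dataclasses.replace(HP_PRESET, seed=42),
                       subject_id="HP01", group="HP", trial_id="demo")
clean = preprocess(trial)
print(f"trial: {trial.duration_s:.0f} s raw -> {clean.duration_s:.0f} s after trimming")

events = detect_events(clean)
cycles = split_cycles(clean, events)
print(f"events: {events.foot_off_idx.size} foot-off, "
      f"{events.foot_contact_idx.size} foot-contact -> {len(cycles)} gait cycles")

print(f"symmetry (DTW):   {symmetry_feature(cycles):8.2f}   (0 = perfectly symmetric)")
print(f"sample entropy:   {complexity_feature(clean):8.3f}   (higher = more irregular)")
print(f"stability index:  {stability_feature(clean):8.3f}   (higher = more stable gait)")
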