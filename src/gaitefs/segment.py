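"""Gait-event detection and cycle segmentation.

In an EFS gait waveform the local maxima mark foot-off (the foot leaving
the ground) and the local minima mark foot-contact.  Events are detected
with a minimum-separation and minimum-prominence peak search and then
reduced to a strictly alternating max/min sequence (within a run of
same-type events only the strongest survives).  A *gait cycle* here is one
step's waveform: the segment between two consecutive foot-contact minima.
Because the two feet alternate step by step, cycles are labelled A,B,A,B,…;
absolute left/right identity is unrecoverable from a single channel, and
every downstream use is invariant to swapping the labels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt, find_peaks

from .errors import InsufficientGaitError, ParameterError
from .trial import RawTrial

MIN_STEPS = 4


@dataclass(frozen=True)
class EventSeries:
    """Ordered foot-off (maxima) and foot-contact (minima) sample indices."""

    foot_off_idx: np.ndarray
    foot_contact_idx: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "foot_off_idx", np.asarray(self.foot_off_idx, dtype=int))
        object.__setattr__(
            self, "foot_contact_idx", np.asarray(self.foot_contact_idx, dtype=int)
        )


@dataclass(frozen=True)
class CycleSet:
    """Contiguous per-step waveform segments with alternating foot labels."""

    cycles: list[np.ndarray]
    foot_labels: list[str]
    sampling_rate_hz: float
    start_idx: np.ndarray | None = None  # sample index of each cycle's first sample
    trial_id: str = ""

    def __len__(self) -> int:
        return len(self.cycles)

    def by_foot(self, label: str) -> list[np.ndarray]:
        return [c for c, f in zip(self.cycles, self.foot_labels) if f == label]


def _alternate(idx_max: np.ndarray, idx_min: np.ndarray, x: np.ndarray) -> EventSeries:
    """Reduce merged events to a strictly alternating max/min sequence.

    Within a run of consecutive same-type events the strongest one (highest
    maximum / lowest minimum) is kept.
    """
    events = [(int(i), +1) for i in idx_max] + [(int(i), -1) for i in idx_min]
    events.sort()
    kept: list[tuple[int, int]] = []
    for i, kind in events:
        if kept and kept[-1][1] == kind:
            prev = kept[-1][0]
            better = x[i] > x[prev] if kind > 0 else x[i] < x[prev]
            if better:
                kept[-1] = (i, kind)
        else:
            kept.append((i, kind))
    return EventSeries(
        foot_off_idx=np.array([i for i, k in kept if k > 0], dtype=int),
        foot_contact_idx=np.array([i for i, k in kept if k < 0], dtype=int),
    )


def detect_events(
    trial: RawTrial,
    min_period_s: float = 0.3,
    min_prominence: float = 0.3,
    smooth: bool = True,
) -> EventSeries:
    """Detect foot-off maxima and foot-contact minima.

    ``min_period_s`` suppresses same-type extrema closer than one plausible
    step period (default 0.3 s, i.e. max ~3.3 steps/s); ``min_prominence``
    is in the units of the (normalized) input.  With ``smooth=True`` the
    extrema are located on a zero-phase low-passed copy of the signal (cut
    at ``2 / min_period_s``, comfortably above any plausible step band), so
    high-frequency fluctuation cannot spawn spurious events; the returned
    indices still refer to the original samples.  Raises
    :class:`InsufficientGaitError` when fewer than four steps are found.
    """
    if not min_period_s > 0:
        raise ParameterError("min_period_s must be > 0")
    x = trial.samples
    if smooth:
        cutoff = 2.0 / min_period_s
        if cutoff < 0.45 * trial.sampling_rate_hz:
            b, a = butter(4, cutoff, btype="lowpass", fs=trial.sampling_rate_hz)
            x = filtfilt(b, a, x)
    dist = max(1, int(round(min_period_s * trial.sampling_rate_hz)))
    idx_max, _ = find_peaks(x, distance=dist, prominence=min_prominence)
    idx_min, _ = find_peaks(-x, distance=dist, prominence=min_prominence)
    events = _alternate(idx_max, idx_min, x)
    if min(events.foot_off_idx.size, events.foot_contact_idx.size) < MIN_STEPS:
        raise InsufficientGaitError(
            f"trial {trial.trial_id}: only {events.foot_off_idx.size} foot-off / "
            f"{events.foot_contact_idx.size} foot-contact events detected "
            f"(need >= {MIN_STEPS})"
        )
    return events


def split_cycles(trial: RawTrial, events: EventSeries) -> CycleSet:
    """Split the trial into per-step cycles between consecutive contact minima.

    ``n`` foot-contact events yield ``n - 1`` contiguous, non-overlapping
    cycles; the first is labelled ``A`` and labels alternate thereafter.
    Concatenating the cycles (plus the remainders before the first and after
    the last contact) reconstructs the trial exactly.
    """
    contacts = events.foot_contact_idx
    if contacts.size < 2:
        raise InsufficientGaitError("need at least two foot-contact events to form a cycle")
    x = trial.samples
    cycles = [x[contacts[i] : contacts[i + 1]] for i in range(contacts.size - 1)]
    labels = ["A" if i % 2 == 0 else "B" for i in range(len(cycles))]
    return CycleSet(
        cycles=cycles,
        foot_labels=labels,
        sampling_rate_hz=trial.sampling_rate_hz,
        start_idx=contacts[:-1].copy(),
        trial_id=trial.trial_id,
    )


def segment(
    trial: RawTrial, min_period_s: float = 0.3, min_prominence: float = 0.3
) -> CycleSet:
    """Convenience: detect events then split into cycles."""
    return split_cycles(trial, detect_events(trial, min_period_s, min_prominence))


def cycles_table(cycles: CycleSet) -> pd.DataFrame:
    """Tabular cycle description: trial_id, cycle_index, foot_label, start/end sample."""
    starts = (
        cycles.start_idx
        if cycles.start_idx is not None
        else np.cumsum([0] + [c.size for c in cycles.cycles[:-1]])
    )
    return pd.DataFrame(
        {
            "trial_id": cycles.trial_id,
            "cycle_index": np.arange(len(cycles)),
            "foot_label": cycles.foot_labels,
            "start_idx": np.asarray(starts, dtype=int),
            "end_idx": np.asarray(starts, dtype=int) + [c.size for c in cycles.cycles],
        }
    )
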