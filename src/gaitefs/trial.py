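"""Core trial container and plain-text I/O.

A *trial* is one single-channel electrostatic-field-sensing (EFS) recording:
the voltage induced on a remote electrode by the charge redistribution of a
walking body, sampled at a fixed rate (1 kHz in the reference acquisition
chain).  Trials travel as ``time_s,voltage`` CSV files with a small JSON
sidecar holding subject/group/trial identifiers, so a cohort is just a
directory of CSVs plus a manifest.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParameterError

GROUPS = ("HP", "HC", "UNKNOWN")


@dataclass(frozen=True)
class RawTrial:
    """One EFS voltage sequence with its acquisition metadata.

    Parameters
    ----------
    samples
        Voltage samples (arbitrary units after amplification).
    sampling_rate_hz
        Samples per second; must be positive.
    subject_id, trial_id
        Free-form identifiers.
    group
        Cohort label: ``"HP"`` (hemiparetic patient), ``"HC"`` (healthy
        control) or ``"UNKNOWN"``.
    """

    samples: np.ndarray
    sampling_rate_hz: float
    subject_id: str = "S00"
    group: str = "UNKNOWN"
    trial_id: str = "T00"

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))
        if self.samples.ndim != 1:
            raise ParameterError("trial samples must be one-dimensional")
        if not self.sampling_rate_hz > 0:
            raise ParameterError(f"sampling_rate_hz must be > 0, got {self.sampling_rate_hz}")
        if self.group not in GROUPS:
            raise ParameterError(f"group must be one of {GROUPS}, got {self.group!r}")

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate_hz

    @property
    def time_s(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_rate_hz

    def with_samples(self, samples: np.ndarray) -> "RawTrial":
        """Return a copy of this trial with new samples, metadata preserved."""
        return replace(self, samples=np.asarray(samples, dtype=float))

    # ------------------------------------------------------------------ I/O

    def to_csv(self, path: str | Path, sidecar: bool = True) -> Path:
        """Write ``time_s,voltage`` CSV (plus a JSON metadata sidecar)."""
        path = Path(path)
        df = pd.DataFrame({"time_s": self.time_s, "voltage": self.samples})
        df.to_csv(path, index=False)
        if sidecar:
            meta = {
                "subject_id": self.subject_id,
                "group": self.group,
                "trial_id": self.trial_id,
                "sampling_rate_hz": self.sampling_rate_hz,
            }
            path.with_suffix(".json").write_text(json.dumps(meta, indent=2) + "\n")
        return path

    @classmethod
    def from_csv(
        cls,
        path: str | Path,
        subject_id: str | None = None,
        group: str | None = None,
        trial_id: str | None = None,
        sampling_rate_hz: float | None = None,
    ) -> "RawTrial":
        """Load a trial from CSV; explicit arguments override the sidecar.

        The sampling rate, when not supplied, is taken from the sidecar or
        inferred from the median spacing of the ``time_s`` column.
        """
        path = Path(path)
        df = pd.read_csv(path)
        if not {"time_s", "voltage"} <= set(df.columns):
            raise ParameterError(f"{path} lacks required columns time_s,voltage")
        meta: dict = {}
        sidecar = path.with_suffix(".json")
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
        if sampling_rate_hz is None:
            sampling_rate_hz = meta.get("sampling_rate_hz")
        if sampling_rate_hz is None:
            dt = float(np.median(np.diff(df["time_s"].to_numpy())))
            if dt <= 0:
                raise ParameterError(f"{path}: cannot infer sampling rate from time_s")
            sampling_rate_hz = 1.0 / dt
        return cls(
            samples=df["voltage"].to_numpy(dtype=float),
            sampling_rate_hz=float(sampling_rate_hz),
            subject_id=subject_id or meta.get("subject_id", "S00"),
            group=group or meta.get("group", "UNKNOWN"),
            trial_id=trial_id or meta.get("trial_id", path.stem),
        )


def write_manifest(trials: list[tuple[Path, RawTrial]], path: str | Path) -> Path:
    """Write a cohort manifest CSV: trial_path,subject_id,group,trial_id."""
    path = Path(path)
    rows = [
        {
            "trial_path": str(p),
            "subject_id": t.subject_id,
            "group": t.group,
            "trial_id": t.trial_id,
        }
        for p, t in trials
    ]
    pd.DataFrame(rows, columns=["trial_path", "subject_id", "group", "trial_id"]).to_csv(
        path, index=False
    )
    return path
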