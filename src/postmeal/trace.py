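"""Postprandial CGM trace container.

A :class:`GlucoseTrace` holds one subject's flash-glucose readings over
a single postprandial window, as (minutes since meal start, mmol/L)
pairs.  The trial grid is a reading every 15 min over 0–300 min; the
container only requires strictly increasing times with a reading at
t = 0 (the pre-meal baseline G0).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

ARMS = ("NPM-CC", "NPM-FPU", "HPFM-CC", "HPFM-FPU")


@dataclass
class GlucoseTrace:
    times: np.ndarray
    values: np.ndarray
    subject_id: str = ""
    arm: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.values.shape:
            raise ValueError("times and values must be 1-D arrays of equal length")
        if self.times.size == 0:
            raise ValueError("empty trace")
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if self.times[0] != 0.0:
            raise ValueError("a baseline reading at t=0 is required")
        if not np.all(np.isfinite(self.values)) or not np.all(self.values > 0):
            raise ValueError("glucose values must be finite and positive")

    @property
    def g0(self) -> float:
        """Baseline (t = 0) glucose, mmol/L."""
        return float(self.values[0])

    @property
    def t_end(self) -> float:
        return float(self.times[-1])

    def __len__(self) -> int:
        return int(self.times.size)

    def value_at(self, t: float) -> float:
        """Reading at exactly time ``t`` (no interpolation)."""
        idx = np.flatnonzero(self.times == t)
        if idx.size == 0:
            raise ValueError(f"no reading at t={t} min")
        return float(self.values[idx[0]])


@dataclass(frozen=True)
class Episode:
    """One hypoglycemic episode: a maximal run of sub-threshold readings."""

    onset_min: float
    end_min: float
    nadir_mmol_l: float

    def __post_init__(self) -> None:
        if self.end_min < self.onset_min:
            raise ValueError("episode end precedes onset")
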