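"""Per-patient observation containers consumed by the model fitter."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Tuple

import numpy as np

from .model import BLOOD, DEEP, ORGAN_TO_COMPARTMENT

__all__ = ["ObservedSeries", "PatientDataset"]


@dataclass(frozen=True)
class ObservedSeries:
    """One compartment's concentration-time observations (µg/mL vs min)."""

    times_min: Tuple[float, ...]
    concentrations: Tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.times_min) != len(self.concentrations):
            raise ValueError("times and concentrations differ in length")
        t = np.asarray(self.times_min)
        if t.size and (np.any(t < 0) or np.any(np.diff(t) <= 0)):
            raise ValueError("times must be strictly increasing and >= 0")
        if any(c < 0 for c in self.concentrations):
            raise ValueError("concentrations must be >= 0")

    @property
    def n(self) -> int:
        return len(self.times_min)


@dataclass(frozen=True)
class PatientDataset:
    """One patient-fraction's fit-ready data.

    ``series`` maps compartment id (``x1`` blood, ``x2`` vertebrae, ``x3``
    liver, ``x4`` spleen) to observed concentrations: blood as amount/Vd,
    organs as post-subtraction tissue amount / CT organ volume.
    ``organ_volumes_mL`` carries the CT volumes used as concentration
    denominators for the organ compartments.
    """

    patient_id: str
    fraction: str
    dose_ug: float
    series: Mapping[str, ObservedSeries]
    organ_volumes_mL: Mapping[str, float] = field(default_factory=dict)
    organ_masses_g: Mapping[str, float] = field(default_factory=dict)
    vascular_volumes_mL: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.dose_ug > 0:
            raise ValueError("dose must be > 0")
        if BLOOD not in self.series:
            raise ValueError("blood series (x1) is required")
        allowed = {BLOOD, DEEP, *ORGAN_TO_COMPARTMENT.values()}
        for comp in self.series:
            if comp not in allowed:
                raise ValueError(f"unknown observed compartment {comp}")
            if comp != BLOOD and comp not in self.organ_volumes_mL:
                raise ValueError(f"organ volume required for observed compartment {comp}")

    @property
    def n_obs(self) -> int:
        return sum(s.n for s in self.series.values())

    @property
    def observed_compartments(self) -> Tuple[str, ...]:
        return tuple(self.series.keys())
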