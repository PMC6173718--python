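"""Radioactivity-to-mass conversion for radiolabeled antibodies.

A well counter reports activity (MBq) in a blood sample drawn at time ``t``
after injection.  Decay-correcting to the injection time and dividing by the
specific activity of the radiolabel yields the mass of labeled antibody in
the sample:

    Am = (Ac / efficiency) / (exp(-ln2 * t / T_half) * MAc)

where ``Ac`` is the detected activity, ``efficiency`` the counting efficiency
of the well counter, ``T_half`` the physical half-life of the isotope and
``MAc`` the specific activity (MBq per mg of antibody).  The formula's mass is
in mg; this module also exposes it in µg since organ/blood concentrations are
reported in µg/mL.

All times are carried internally in minutes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import pandas as pd

LN2 = math.log(2.0)

__all__ = [
    "RadiolabelSpec",
    "ActivitySample",
    "amount_from_activity",
    "concentration_from_activity",
    "activity_from_amount",
    "read_well_counter_csv",
]


@dataclass(frozen=True)
class RadiolabelSpec:
    """Physical parameters linking detected activity to antibody mass.

    Parameters
    ----------
    isotope_half_life_h : float
        Physical half-life of the imaging isotope in hours.  Default is the
        67 h value conventionally used for ¹¹¹In in dosimetry work.
    counting_efficiency : float
        Well-counter efficiency, in (0, 1].  Default 0.933.
    specific_activity_MBq_per_mg : float
        Activity per unit mass of labeled antibody (MBq/mg) at injection
        time.  Default 138.
    """

    isotope_half_life_h: float = 67.0
    counting_efficiency: float = 0.933
    specific_activity_MBq_per_mg: float = 138.0

    def __post_init__(self) -> None:
        if not self.isotope_half_life_h > 0:
            raise ValueError("isotope half-life must be > 0")
        if not 0 < self.counting_efficiency <= 1:
            raise ValueError("counting efficiency must be in (0, 1]")
        if not self.specific_activity_MBq_per_mg > 0:
            raise ValueError("specific activity must be > 0")

    @property
    def isotope_half_life_min(self) -> float:
        return self.isotope_half_life_h * 60.0


@dataclass(frozen=True)
class ActivitySample:
    """One well-counter measurement.

    ``time_min`` is minutes post-injection, ``activity_MBq`` the detected
    activity and ``volume_mL`` the sample volume (optional; required only to
    derive a concentration).
    """

    time_min: float
    activity_MBq: float
    volume_mL: Optional[float] = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.time_min) or self.time_min < 0:
            raise ValueError("sample time must be finite and >= 0")
        if self.activity_MBq < 0:
            raise ValueError("activity must be >= 0")


def amount_from_activity(sample: ActivitySample, spec: RadiolabelSpec) -> float:
    """Mass (mg) of labeled antibody in a sample, decay-corrected to t=0.

    Strictly increasing in sample time for fixed activity (later counts have
    decayed more, so the same reading implies more antibody), linear in
    activity for fixed time.
    """
    decay = math.exp(-LN2 * sample.time_min / spec.isotope_half_life_min)
    return (sample.activity_MBq / spec.counting_efficiency) / (
        decay * spec.specific_activity_MBq_per_mg
    )


def activity_from_amount(mass_mg: float, time_min: float, spec: RadiolabelSpec) -> float:
    """Inverse of :func:`amount_from_activity`: expected well-counter reading
    (MBq) for a sample containing ``mass_mg`` of antibody, counted at
    ``time_min`` post-injection."""
    if mass_mg < 0:
        raise ValueError("mass must be >= 0")
    decay = math.exp(-LN2 * time_min / spec.isotope_half_life_min)
    return mass_mg * spec.counting_efficiency * decay * spec.specific_activity_MBq_per_mg


def concentration_from_activity(sample: ActivitySample, spec: RadiolabelSpec) -> float:
    """Antibody concentration in the sample, µg/mL (1000 µg per mg)."""
    if sample.volume_mL is None or not sample.volume_mL > 0:
        raise ValueError("sample volume must be present and > 0")
    return amount_from_activity(sample, spec) * 1000.0 / sample.volume_mL


_WELL_COUNTER_COLUMNS = ["patient_id", "fraction", "time_min", "activity_MBq", "volume_mL"]


def read_well_counter_csv(path, spec: RadiolabelSpec) -> pd.DataFrame:
    """Read a well-counter export and append mass/concentration columns.

    Expected columns: patient_id, fraction, time_min, activity_MBq, volume_mL.
    Returns the frame with ``amount_ug`` and ``concentration_ug_mL`` added.
    """
    df = pd.read_csv(path)
    missing = [c for c in _WELL_COUNTER_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"well-counter CSV missing columns: {missing}")
    amounts = []
    concs = []
    for row in df.itertuples(index=False):
        sample = ActivitySample(
            time_min=float(row.time_min),
            activity_MBq=float(row.activity_MBq),
            volume_mL=float(row.volume_mL),
        )
        amounts.append(amount_from_activity(sample, spec) * 1000.0)
        concs.append(concentration_from_activity(sample, spec))
    out = df.copy()
    out["amount_ug"] = amounts
    out["concentration_ug_mL"] = concs
    return out
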