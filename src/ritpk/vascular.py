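"""Intra-organ vascular compartment: blood-volume estimation and subtraction.

An organ delineated on SPECT/CT contains both antibody bound in tissue and
antibody still circulating in the organ's blood vessels.  Assuming antibody
distribution is purely vascular during the first hour after injection, the
blood volume inside an organ is estimated once per patient-fraction as

    V_blood = (whole-organ amount at 4 h) / (peripheral blood concentration at 1 h)

and the tissue constituent at any sampling time is the whole-organ amount
minus ``blood_concentration(t) * V_blood``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

ORGAN_IDS = ("vertebrae_L2L4", "liver", "spleen")

__all__ = [
    "ORGAN_IDS",
    "OrganObservation",
    "VascularEstimate",
    "TissueAmount",
    "estimate_blood_volume",
    "subtract_blood",
    "tissue_concentration",
    "interpolate_blood_concentration",
]


@dataclass(frozen=True)
class OrganObservation:
    """Whole-organ antibody amount (µg) at one imaging time."""

    organ_id: str
    time_min: float
    total_amount_ug: float
    organ_mass_g: float
    organ_volume_mL: Optional[float] = None

    def __post_init__(self) -> None:
        if self.organ_id not in ORGAN_IDS:
            raise ValueError(f"unknown organ_id {self.organ_id!r}; expected one of {ORGAN_IDS}")
        if self.total_amount_ug < 0:
            raise ValueError("total amount must be >= 0")
        if not self.organ_mass_g > 0:
            raise ValueError("organ mass must be > 0")


@dataclass(frozen=True)
class VascularEstimate:
    """Estimated blood volume inside one organ (fixed per patient-fraction)."""

    organ_id: str
    blood_volume_mL: float
    blood_volume_mL_per_g: float
    exceeds_organ_volume: bool = False


@dataclass(frozen=True)
class TissueAmount:
    """Tissue constituent after vascular subtraction; ``clamped`` marks the
    physiologically impossible negative case forced to zero."""

    organ_id: str
    time_min: float
    tissue_amount_ug: float
    clamped: bool = False


def estimate_blood_volume(
    organ_amount_4h_ug: float,
    blood_concentration_1h_ug_mL: float,
    organ_mass_g: float,
    organ_id: str = "liver",
    organ_volume_mL: Optional[float] = None,
) -> VascularEstimate:
    """Blood volume in an organ from the 4 h image / 1 h blood sample pair.

    Raises on non-positive blood concentration; flags (but does not reject)
    estimates exceeding the organ's anatomical volume.
    """
    if not blood_concentration_1h_ug_mL > 0:
        raise ValueError("blood concentration must be > 0")
    if not organ_mass_g > 0:
        raise ValueError("organ mass must be > 0")
    if organ_amount_4h_ug < 0:
        raise ValueError("organ amount must be >= 0")
    v = organ_amount_4h_ug / blood_concentration_1h_ug_mL
    exceeds = organ_volume_mL is not None and v > organ_volume_mL
    return VascularEstimate(
        organ_id=organ_id,
        blood_volume_mL=v,
        blood_volume_mL_per_g=v / organ_mass_g,
        exceeds_organ_volume=exceeds,
    )


def subtract_blood(
    obs: OrganObservation,
    est: VascularEstimate,
    blood_conc_at_t_ug_mL: float,
) -> TissueAmount:
    """Tissue amount = total amount − blood concentration × organ blood volume.

    Negative results are clamped to 0 and flagged rather than propagated to
    the fitter, which requires non-negative amounts.
    """
    if est.organ_id != obs.organ_id:
        raise ValueError(f"organ mismatch: {obs.organ_id} vs {est.organ_id}")
    tissue = obs.total_amount_ug - blood_conc_at_t_ug_mL * est.blood_volume_mL
    if tissue < 0:
        return TissueAmount(obs.organ_id, obs.time_min, 0.0, clamped=True)
    return TissueAmount(obs.organ_id, obs.time_min, tissue, clamped=False)


def tissue_concentration(tissue_amount_ug: float, organ_volume_mL: float) -> float:
    """Tissue amount divided by CT organ volume, µg/mL."""
    if not organ_volume_mL > 0:
        raise ValueError("organ volume must be > 0")
    return tissue_amount_ug / organ_volume_mL


def interpolate_blood_concentration(
    times_min: Sequence[float],
    concentrations: Sequence[float],
    at_min: float = 60.0,
) -> float:
    """Blood concentration at ``at_min``, log-linearly interpolated.

    Returns the measured value when a sample exists at the requested time.
    Log-linear interpolation matches the (near-)exponential shape of antibody
    blood curves; falls back to linear when a bracketing value is zero.
    Outside the sampled range the nearest sample is returned.
    """
    t = np.asarray(times_min, dtype=float)
    c = np.asarray(concentrations, dtype=float)
    if t.size == 0:
        raise ValueError("no blood samples")
    order = np.argsort(t)
    t, c = t[order], c[order]
    hit = np.isclose(t, at_min)
    if hit.any():
        return float(c[hit][0])
    if at_min <= t[0]:
        return float(c[0])
    if at_min >= t[-1]:
        return float(c[-1])
    i = int(np.searchsorted(t, at_min)) - 1
    t0, t1, c0, c1 = t[i], t[i + 1], c[i], c[i + 1]
    w = (at_min - t0) / (t1 - t0)
    if c0 > 0 and c1 > 0:
        return float(math.exp((1 - w) * math.log(c0) + w * math.log(c1)))
    return float((1 - w) * c0 + w * c1)
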