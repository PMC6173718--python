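"""Synthetic dosimetry cohorts emulating a fractionated RIT study design.

No public dataset exists for the trial this design mirrors, so every
pipeline stage is exercised on synthetic patients: 19 receiving a first
fraction (F1) and a 13-patient subset receiving a second (F2), imaged at
4 h, 24 h, 96 h and 168 h post-injection with an additional 1 h blood
sample.  Per-patient kinetics follow the five-compartment biodistribution
model with individual parameters drawn lognormally (mean-preserving) around
the cohort mean parameter sets reported for each fraction; organ totals are
composed as tissue amount + blood concentration × intra-organ blood volume
(the inverse of the vascular-subtraction step), and proportional measurement
noise is applied last.

The defaults below ARE the study conditions; the ground truth behind every
generated observation is returned alongside it for recovery testing.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from typing import Dict, List, Mapping, Tuple

import numpy as np
import pandas as pd

from .dataset import ObservedSeries, PatientDataset
from .model import (
    BLOOD,
    ORGAN_TO_COMPARTMENT,
    DoseEvent,
    ParameterVector,
    five_compartment_model,
    simulate,
)
from .radiolabel import RadiolabelSpec, activity_from_amount

__all__ = [
    "CohortSpec",
    "PatientTruth",
    "TruthRecord",
    "F1_POPULATION",
    "F2_POPULATION",
    "population_parameters",
    "generate_patient",
    "generate_cohort",
    "generate_activity_layer",
    "dataset_from_truth",
]

COMPARTMENT_TO_ORGAN = {v: k for k, v in ORGAN_TO_COMPARTMENT.items()}

# Cohort mean PK parameters by treatment fraction (rates min⁻¹, Vd mL).
# The deep-compartment exchange rates and the elimination rate are not
# reported for this design; defaults fix k15 = k51 = 1e-4 min⁻¹ and derive
# k_el = CL/Vd from the blood-block means (elimination is blood-only).
F1_POPULATION: Dict[str, float] = {
    "Vd": 4131.0,
    "CL_mL_min": 1.03,
    "k12": 1.11e-4,
    "k21": 1.05e-4,
    "k13": 1.80e-4,
    "k31": 2.32e-4,
    "k14": 2.11e-4,  # blood -> spleen input
    "k43": 1.26e-4,  # spleen efflux, routed to liver
    "k15": 1.0e-4,
    "k51": 1.0e-4,
}
F2_POPULATION: Dict[str, float] = {
    "Vd": 4064.8,
    "CL_mL_min": 0.74,
    "k12": 0.60e-4,
    "k21": 0.96e-4,
    "k13": 2.05e-4,
    "k31": 1.77e-4,
    "k14": 1.17e-4,
    "k43": 1.64e-4,
    "k15": 1.0e-4,
    "k51": 1.0e-4,
}

# Mean intra-organ blood volume per gram of organ (mL/g) and organ mass (g);
# masses back-solved from the cohort blood-volume means and per-gram values.
ORGAN_MEANS: Dict[str, Dict[str, float]] = {
    "vertebrae_L2L4": {"blood_mL_per_g": 0.15, "mass_g": 8.15 / 0.15},
    "liver": {"blood_mL_per_g": 0.29, "mass_g": 485.0 / 0.29},
    "spleen": {"blood_mL_per_g": 0.28, "mass_g": 81.5 / 0.28},
}
TISSUE_DENSITY_G_PER_ML = 1.0  # CT volumes approximated as mass / unit density


@dataclass(frozen=True)
class CohortSpec:
    """Study-design parameters of the synthetic cohort."""

    n_patients_F1: int = 19
    n_patients_F2: int = 13
    imaging_times_min: Tuple[float, ...] = (240.0, 1440.0, 5760.0, 10080.0)
    blood_sample_times_min: Tuple[float, ...] = (60.0, 240.0, 1440.0, 5760.0, 10080.0)
    dose_ug: float = 1000.0
    iiv_cv: float = 0.3
    noise_cv: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients_F2 > self.n_patients_F1:
            raise ValueError("F2 cohort cannot exceed F1 cohort")
        for ts in (self.imaging_times_min, self.blood_sample_times_min):
            t = np.asarray(ts)
            if np.any(t <= 0) or np.any(np.diff(t) <= 0):
                raise ValueError("sampling times must be sorted and positive")
        if self.iiv_cv < 0 or self.noise_cv < 0:
            raise ValueError("CVs must be >= 0")
        if not self.dose_ug > 0:
            raise ValueError("dose must be > 0")


@dataclass(frozen=True)
class PatientTruth:
    """Generating ground truth for one patient-fraction."""

    patient_id: str
    fraction: str
    params_flat: Dict[str, float]
    organ_masses_g: Dict[str, float]
    organ_volumes_mL: Dict[str, float]
    vascular_volumes_mL: Dict[str, float]
    dose_ug: float


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for a whole generated cohort."""

    spec: CohortSpec
    patients: Tuple[PatientTruth, ...]

    def to_json(self) -> str:
        return json.dumps(
            {"spec": asdict(self.spec), "patients": [asdict(p) for p in self.patients]},
            indent=2,
            sort_keys=True,
        )


def population_parameters(population: Mapping[str, float]) -> ParameterVector:
    """Cohort-mean ParameterVector for the five-compartment topology, with
    the elimination rate derived as CL/Vd."""
    top = five_compartment_model()
    flat = dict(population)
    flat["kel"] = flat["CL_mL_min"] / flat["Vd"]
    return ParameterVector.from_flat_dict(flat, top)


def _lognormal_factor(rng: np.random.Generator, cv: float, size=None):
    """Mean-1 lognormal multiplier with coefficient of variation ``cv``."""
    if cv == 0:
        return np.ones(size) if size else 1.0
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


def _draw_individual(
    rng: np.random.Generator, population: Mapping[str, float], iiv_cv: float
) -> Dict[str, float]:
    keys = ["Vd", "k12", "k21", "k13", "k31", "k14", "k43", "k15", "k51"]
    out = {k: float(population[k] * _lognormal_factor(rng, iiv_cv)) for k in keys}
    kel_mean = population["CL_mL_min"] / population["Vd"]
    out["kel"] = float(kel_mean * _lognormal_factor(rng, iiv_cv))
    return out


def generate_patient(
    patient_id: str,
    fraction: str,
    spec: CohortSpec,
    population: Mapping[str, float],
    rng: np.random.Generator,
) -> Tuple[pd.DataFrame, PatientTruth]:
    """One patient-fraction: observation rows + generating truth.

    Observation rows use the pipeline CSV schema (blood rows in µg/mL,
    whole-organ rows in µg).
    """
    top = five_compartment_model()
    params_flat = _draw_individual(rng, population, spec.iiv_cv)
    params = ParameterVector.from_flat_dict(params_flat, top)

    organ_masses = {
        organ: float(m["mass_g"] * _lognormal_factor(rng, spec.iiv_cv))
        for organ, m in ORGAN_MEANS.items()
    }
    organ_volumes = {o: m / TISSUE_DENSITY_G_PER_ML for o, m in organ_masses.items()}
    vascular = {
        organ: float(
            ORGAN_MEANS[organ]["blood_mL_per_g"]
            * organ_masses[organ]
            * _lognormal_factor(rng, spec.iiv_cv)
        )
        for organ in ORGAN_MEANS
    }

    all_times = sorted(set(spec.blood_sample_times_min) | set(spec.imaging_times_min))
    course = simulate(top, params, DoseEvent(amount_ug=spec.dose_ug), all_times)
    tindex = {t: i for i, t in enumerate(all_times)}
    blood_conc = course.blood_concentration(params.Vd_mL)

    rows: List[dict] = []
    for t in spec.blood_sample_times_min:
        value = blood_conc[tindex[t]]
        if spec.noise_cv > 0:
            value = max(0.0, value * (1.0 + spec.noise_cv * rng.standard_normal()))
        rows.append(
            {"patient_id": patient_id, "fraction": fraction, "region": "blood",
             "time_min": t, "value": float(value), "unit": "ug_per_mL",
             "organ_mass_g": np.nan, "organ_volume_mL": np.nan}
        )
    for organ, comp in ORGAN_TO_COMPARTMENT.items():
        tissue = course.amount(comp)
        for t in spec.imaging_times_min:
            i = tindex[t]
            total = tissue[i] + blood_conc[i] * vascular[organ]
            if spec.noise_cv > 0:
                total = max(0.0, total * (1.0 + spec.noise_cv * rng.standard_normal()))
            rows.append(
                {"patient_id": patient_id, "fraction": fraction, "region": organ,
                 "time_min": t, "value": float(total), "unit": "ug",
                 "organ_mass_g": organ_masses[organ],
                 "organ_volume_mL": organ_volumes[organ]}
            )
    truth = PatientTruth(
        patient_id=patient_id,
        fraction=fraction,
        params_flat=params_flat,
        organ_masses_g=organ_masses,
        organ_volumes_mL=organ_volumes,
        vascular_volumes_mL=vascular,
        dose_ug=spec.dose_ug,
    )
    return pd.DataFrame(rows), truth


def generate_cohort(
    spec: CohortSpec = CohortSpec(),
    population_F1: Mapping[str, float] = F1_POPULATION,
    population_F2: Mapping[str, float] = F2_POPULATION,
) -> Tuple[pd.DataFrame, TruthRecord]:
    """Full two-fraction cohort.

    The F2 subset reuses the first ``n_patients_F2`` patient ids (fractions
    are partially paired in the emulated design) but draws fresh individual
    parameters around the F2 means.
    """
    rng = np.random.default_rng(spec.seed)
    frames: List[pd.DataFrame] = []
    truths: List[PatientTruth] = []
    for i in range(spec.n_patients_F1):
        df, tr = generate_patient(f"P{i + 1:02d}", "F1", spec, population_F1, rng)
        frames.append(df)
        truths.append(tr)
    for i in range(spec.n_patients_F2):
        df, tr = generate_patient(f"P{i + 1:02d}", "F2", spec, population_F2, rng)
        frames.append(df)
        truths.append(tr)
    obs = pd.concat(frames, ignore_index=True)
    return obs, TruthRecord(spec=spec, patients=tuple(truths))


def generate_activity_layer(
    obs: pd.DataFrame,
    spec: RadiolabelSpec = RadiolabelSpec(),
    sample_volume_mL: float = 2.0,
) -> pd.DataFrame:
    """Well-counter activity table for the blood rows of an observation set.

    Applies the exact inverse of the activity→mass conversion so the
    conversion module round-trips to the generated concentrations.
    """
    blood = obs[obs["region"] == "blood"]
    rows = []
    for row in blood.itertuples(index=False):
        mass_mg = row.value * sample_volume_mL / 1000.0  # µg/mL × mL → µg → mg
        rows.append(
            {"patient_id": row.patient_id, "fraction": row.fraction,
             "time_min": row.time_min,
             "activity_MBq": activity_from_amount(mass_mg, row.time_min, spec),
             "volume_mL": sample_volume_mL}
        )
    return pd.DataFrame(rows)


def dataset_from_truth(
    truth: PatientTruth,
    spec: CohortSpec,
) -> PatientDataset:
    """Noise-free fit-ready dataset straight from a patient's ground truth
    (bypasses the observation CSV and the vascular-subtraction stage)."""
    top = five_compartment_model()
    params = ParameterVector.from_flat_dict(truth.params_flat, top)
    all_times = sorted(set(spec.blood_sample_times_min) | set(spec.imaging_times_min))
    course = simulate(top, params, DoseEvent(amount_ug=truth.dose_ug), all_times)
    tindex = {t: i for i, t in enumerate(all_times)}
    series = {
        BLOOD: ObservedSeries(
            tuple(spec.blood_sample_times_min),
            tuple(course.blood_concentration(params.Vd_mL)[tindex[t]]
                  for t in spec.blood_sample_times_min),
        )
    }
    volumes = {}
    for organ, comp in ORGAN_TO_COMPARTMENT.items():
        vol = truth.organ_volumes_mL[organ]
        volumes[comp] = vol
        series[comp] = ObservedSeries(
            tuple(spec.imaging_times_min),
            tuple(course.amount(comp)[tindex[t]] / vol for t in spec.imaging_times_min),
        )
    return PatientDataset(
        patient_id=truth.patient_id,
        fraction=truth.fraction,
        dose_ug=truth.dose_ug,
        series=series,
        organ_volumes_mL=volumes,
        organ_masses_g={ORGAN_TO_COMPARTMENT[o]: m for o, m in truth.organ_masses_g.items()},
        vascular_volumes_mL={ORGAN_TO_COMPARTMENT[o]: v
                             for o, v in truth.vascular_volumes_mL.items()},
    )
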