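"""Shared fixtures: cohort-mean parameters and dataset builders."""

from __future__ import annotations

import numpy as np
import pytest

from ritpk import (
    DoseEvent,
    FitOptions,
    ParameterVector,
    five_compartment_model,
    simulate,
)
from ritpk.cohort import F1_POPULATION, ORGAN_MEANS, population_parameters
from ritpk.dataset import ObservedSeries, PatientDataset
from ritpk.model import BLOOD, DEEP, ORGAN_TO_COMPARTMENT

BLOOD_TIMES = (60.0, 240.0, 1440.0, 5760.0, 10080.0)
IMAGING_TIMES = (240.0, 1440.0, 5760.0, 10080.0)
DEEP_PSEUDO_VOLUME_ML = 10000.0


@pytest.fixture(scope="session")
def topology():
    return five_compartment_model()


@pytest.fixture(scope="session")
def f1_params() -> ParameterVector:
    return population_parameters(F1_POPULATION)


@pytest.fixture(scope="session")
def organ_volumes() -> dict:
    return {ORGAN_TO_COMPARTMENT[o]: m["mass_g"] for o, m in ORGAN_MEANS.items()}


def build_dataset(
    params: ParameterVector,
    times,
    organ_volumes: dict,
    dose_ug: float = 1000.0,
    noise_cv: float = 0.0,
    rng: np.random.Generator | None = None,
    observe_deep: bool = False,
    organ_times=None,
) -> PatientDataset:
    """Simulate the five-compartment model and package observed series."""
    top = five_compartment_model()
    organ_times = tuple(organ_times) if organ_times is not None else tuple(times)
    all_t = np.array(sorted(set(times) | set(organ_times)))
    course = simulate(top, params, DoseEvent(amount_ug=dose_ug), all_t)
    idx = {t: i for i, t in enumerate(all_t)}
    rng = rng or np.random.default_rng(0)

    def noisy(x: float) -> float:
        if noise_cv == 0:
            return float(x)
        return float(max(0.0, x * (1.0 + noise_cv * rng.standard_normal())))

    vols = dict(organ_volumes)
    bc = course.blood_concentration(params.Vd_mL)
    series = {
        BLOOD: ObservedSeries(tuple(times), tuple(noisy(bc[idx[t]]) for t in times))
    }
    for comp in list(organ_volumes):
        cc = course.amount(comp) / organ_volumes[comp]
        series[comp] = ObservedSeries(
            organ_times, tuple(noisy(cc[idx[t]]) for t in organ_times)
        )
    if observe_deep:
        vols[DEEP] = DEEP_PSEUDO_VOLUME_ML
        cc = course.amount(DEEP) / DEEP_PSEUDO_VOLUME_ML
        series[DEEP] = ObservedSeries(
            organ_times, tuple(noisy(cc[idx[t]]) for t in organ_times)
        )
    return PatientDataset(
        patient_id="SIM", fraction="F1", dose_ug=dose_ug,
        series=series, organ_volumes_mL=vols,
    )


@pytest.fixture(scope="session")
def dense_noise_free_dataset(f1_params, organ_volumes) -> PatientDataset:
    """Noise-free curves on a dense 1 h – 168 h grid (fit oracle input)."""
    times = tuple(np.geomspace(60.0, 10080.0, 40))
    return build_dataset(f1_params, times, organ_volumes)


@pytest.fixture(scope="session")
def fast_fit_options() -> FitOptions:
    return FitOptions(n_starts=3, seed=0, ftol=1e-12, xtol=1e-12, gtol=1e-12)
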