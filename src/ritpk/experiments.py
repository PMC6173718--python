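"""Reproducible validation experiments for the pipeline.

These are the package's standard self-checks: deterministic
generate-then-refit parameter recovery on the cohort-mean parameter set,
AIC model selection on noise-free and noisy replicate cohorts, and the
empirical type-I error of the fraction comparison.  Both the test suite and
the reproduction script call them, so the numbers they report are always
recomputed from scratch.
"""

from __future__ import annotations

from typing import Dict, List, Mapping, Tuple

import numpy as np

from .cohort import F1_POPULATION, F2_POPULATION, ORGAN_MEANS, population_parameters
from .dataset import ObservedSeries, PatientDataset
from .fitting import FitOptions, FitResult, default_catalogue, fit, select_model
from .model import (
    BLOOD,
    DEEP,
    ORGAN_TO_COMPARTMENT,
    DoseEvent,
    ParameterVector,
    five_compartment_model,
    simulate,
)
from .stats import mann_whitney

__all__ = [
    "recovery_dataset",
    "parameter_recovery",
    "noise_free_model_selection",
    "cohort_selection_consistency",
    "mann_whitney_type_one_error",
]

BLOOD_TIMES = (60.0, 240.0, 1440.0, 5760.0, 10080.0)
IMAGING_TIMES = (240.0, 1440.0, 5760.0, 10080.0)
#: nominal concentration denominator for the (synthetically observable)
#: deep compartment: total-body water scale, mL
DEEP_PSEUDO_VOLUME_ML = 10000.0


def _organ_volumes() -> Dict[str, float]:
    return {ORGAN_TO_COMPARTMENT[o]: m["mass_g"] for o, m in ORGAN_MEANS.items()}


def recovery_dataset(n_times: int = 40, dose_ug: float = 1000.0) -> Tuple[PatientDataset, ParameterVector]:
    """Noise-free five-compartment curves on a dense 1 h – 168 h grid,
    generated from the F1 cohort-mean parameter set."""
    top = five_compartment_model()
    params = population_parameters(F1_POPULATION)
    times = tuple(np.geomspace(60.0, 10080.0, n_times))
    course = simulate(top, params, DoseEvent(dose_ug), times)
    vols = _organ_volumes()
    series = {
        BLOOD: ObservedSeries(times, tuple(course.blood_concentration(params.Vd_mL)))
    }
    for comp, vol in vols.items():
        series[comp] = ObservedSeries(times, tuple(course.amount(comp) / vol))
    ds = PatientDataset(
        patient_id="F1-mean", fraction="F1", dose_ug=dose_ug,
        series=series, organ_volumes_mL=vols,
    )
    return ds, params


def parameter_recovery(seed: int = 0, n_times: int = 40) -> Tuple[Dict[str, float], Dict[str, float], int]:
    """Refit the generating model to its own noise-free curves.

    Returns (fitted flat parameters, generating flat parameters, n_obs).
    """
    ds, params = recovery_dataset(n_times=n_times)
    options = FitOptions(n_starts=5, seed=seed)
    res = fit(five_compartment_model(), ds, options)
    return res.delta_params, params.to_flat_dict(), ds.n_obs


def noise_free_model_selection(seed: int = 0, n_times: int = 40) -> Tuple[str, List[FitResult]]:
    """Rank the default catalogue on the noise-free dense dataset."""
    ds, _ = recovery_dataset(n_times=n_times)
    options = FitOptions(n_starts=3, seed=seed)
    best, ranking = select_model(default_catalogue(), ds, options)
    return best.topology_id, ranking


def _noisy_patient(
    flat_means: Mapping[str, float],
    noise_cv: float,
    iiv_cv: float,
    rng: np.random.Generator,
    dose_ug: float = 1000.0,
) -> PatientDataset:
    top = five_compartment_model()
    sigma = np.sqrt(np.log(1.0 + iiv_cv**2)) if iiv_cv > 0 else 0.0
    flat = {
        k: v * (rng.lognormal(-0.5 * sigma * sigma, sigma) if sigma else 1.0)
        for k, v in flat_means.items()
    }
    params = ParameterVector.from_flat_dict(flat, top)
    all_t = np.array(sorted(set(BLOOD_TIMES) | set(IMAGING_TIMES)))
    course = simulate(top, params, DoseEvent(dose_ug), all_t)
    idx = {t: i for i, t in enumerate(all_t)}

    def noisy(x: float) -> float:
        return float(max(0.0, x * (1.0 + noise_cv * rng.standard_normal())))

    vols = _organ_volumes()
    vols[DEEP] = DEEP_PSEUDO_VOLUME_ML
    bc = course.blood_concentration(params.Vd_mL)
    series = {
        BLOOD: ObservedSeries(BLOOD_TIMES, tuple(noisy(bc[idx[t]]) for t in BLOOD_TIMES))
    }
    for comp, vol in vols.items():
        cc = course.amount(comp) / vol
        series[comp] = ObservedSeries(
            IMAGING_TIMES, tuple(noisy(cc[idx[t]]) for t in IMAGING_TIMES)
        )
    return PatientDataset(
        patient_id="SIM", fraction="F1", dose_ug=dose_ug,
        series=series, organ_volumes_mL=vols,
    )


def cohort_selection_consistency(
    n_cohorts: int = 50,
    noise_cv: float = 0.10,
    iiv_cv: float = 0.30,
    seed: int = 0,
) -> float:
    """Fraction of replicate study cohorts for which catalogue-wide AIC
    selection recovers the generating topology.

    Each replicate mirrors the study: 19 F1 and 13 F2 patients generated
    from the five-compartment model with fraction-specific means, lognormal
    between-patient variability and proportional measurement noise, every
    compartment sampled at the design times.  One model is selected per
    cohort — the way dosimetry studies establish a single structural model
    across patients and fractions — by summing each candidate's AIC over
    all patient fits.  Fits use the proportional-error (1/ŷ²) objective
    matching the generator's noise model, with a single optimizer start per
    candidate to keep the experiment tractable.
    """
    cat = default_catalogue()
    ids = cat.ids()
    true_id = five_compartment_model().topology_id
    f1 = population_parameters(F1_POPULATION).to_flat_dict()
    f2 = population_parameters(F2_POPULATION).to_flat_dict()
    rng = np.random.default_rng(seed)
    options = FitOptions(
        n_starts=1, seed=seed, weighting="1/y2",
        ftol=1e-10, xtol=1e-10, gtol=1e-10,
    )
    wins = 0
    for _ in range(n_cohorts):
        totals = np.zeros(len(ids))
        for k in range(19 + 13):
            ds = _noisy_patient(f1 if k < 19 else f2, noise_cv, iiv_cv, rng)
            _, ranking = select_model(cat, ds, options)
            aics = {r.topology_id: r.aic for r in ranking}
            totals += np.array([aics.get(tid, 1e6) for tid in ids])
        wins += ids[int(np.argmin(totals))] == true_id
    return wins / n_cohorts


def mann_whitney_type_one_error(
    n_reps: int = 2000,
    n1: int = 19,
    n2: int = 13,
    cv: float = 0.30,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Empirical rejection rate of the fraction comparison under the null
    (both groups drawn from the same lognormal parameter distribution)."""
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(np.log(1.0 + cv**2))
    rejections = 0
    for _ in range(n_reps):
        a = rng.lognormal(0.0, sigma, n1)
        b = rng.lognormal(0.0, sigma, n2)
        rejections += mann_whitney(a, b, alpha=alpha).significant
    return rejections / n_reps
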