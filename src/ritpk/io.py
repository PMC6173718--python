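"""Observation IO, vascular-partition stage and the end-to-end pipeline.

Observation CSV schema (long format, one row per measurement):

    patient_id, fraction, region, time_min, value, unit, organ_mass_g, organ_volume_mL

``region`` is ``blood`` or an organ id (``vertebrae_L2L4``, ``liver``,
``spleen``).  Blood rows carry concentrations (``ug_per_mL``) or raw
well-counter activity (``MBq``, with the sample volume in the
organ_volume_mL column); organ rows carry whole-organ amounts (``ug`` or
``MBq``).  Activities are converted to mass with the radiolabel conversion
before any further processing.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Dict, List, Literal, Mapping, Optional, Tuple

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict

from . import __version__
from .cohort import (
    CohortSpec,
    TruthRecord,
    generate_activity_layer,
    generate_cohort,
)
from .dataset import ObservedSeries, PatientDataset
from .fitting import FitOptions, FitResult, default_catalogue, fit, select_model
from .model import (
    BLOOD,
    ORGAN_TO_COMPARTMENT,
    five_compartment_model,
)
from .pkparams import summarize_fit
from .radiolabel import ActivitySample, RadiolabelSpec, amount_from_activity
from .stats import compare_fractions
from .vascular import (
    OrganObservation,
    VascularEstimate,
    estimate_blood_volume,
    interpolate_blood_concentration,
    subtract_blood,
)

__all__ = [
    "OBS_COLUMNS",
    "RunConfig",
    "read_observations",
    "write_observations",
    "build_patient_datasets",
    "run_pipeline",
]

OBS_COLUMNS = [
    "patient_id", "fraction", "region", "time_min", "value", "unit",
    "organ_mass_g", "organ_volume_mL",
]
_KNOWN_UNITS = {"ug", "ug_per_mL", "MBq"}
_REGIONS = {"blood"} | set(ORGAN_TO_COMPARTMENT)


def read_observations(
    path, radiolabel: Optional[RadiolabelSpec] = None
) -> pd.DataFrame:
    """Read and validate an observation CSV; normalize every row to µg units.

    Malformed rows are reported with their 1-based data line number; MBq
    rows require ``radiolabel`` for the activity→mass conversion.
    """
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"{path}: empty observation file")
    missing = [c for c in OBS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    errors: List[str] = []
    values = []
    units = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        unit = str(row.unit)
        if unit not in _KNOWN_UNITS:
            errors.append(f"line {i}: unknown unit {unit!r}")
            continue
        if str(row.region) not in _REGIONS:
            errors.append(f"line {i}: unknown region {row.region!r}")
            continue
        value = float(row.value)
        t = float(row.time_min)
        if not np.isfinite(value) or value < 0 or t < 0:
            errors.append(f"line {i}: non-finite or negative value/time")
            continue
        if unit == "MBq":
            if radiolabel is None:
                errors.append(f"line {i}: MBq row but no radiolabel spec supplied")
                continue
            mass_ug = amount_from_activity(ActivitySample(t, value), radiolabel) * 1000.0
            if str(row.region) == "blood":
                vol = float(row.organ_volume_mL)
                if not vol > 0:
                    errors.append(f"line {i}: blood MBq row needs sample volume > 0")
                    continue
                values.append(mass_ug / vol)
                units.append("ug_per_mL")
            else:
                values.append(mass_ug)
                units.append("ug")
        else:
            values.append(value)
            units.append(unit)
    if errors:
        raise ValueError(f"{path}: malformed rows:\n" + "\n".join(errors))
    out = df.copy()
    out["value"] = values
    out["unit"] = units
    dup = out.duplicated(subset=["patient_id", "fraction", "region", "time_min"])
    if dup.any():
        lines = (np.nonzero(dup.to_numpy())[0] + 1).tolist()
        raise ValueError(f"{path}: duplicate (patient, fraction, region, time) at lines {lines}")
    return out


def write_observations(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, columns=OBS_COLUMNS)


@dataclass(frozen=True)
class PartitionRecord:
    """Per-organ vascular-partition metadata for one patient-fraction."""

    patient_id: str
    fraction: str
    organ_id: str
    blood_volume_mL: float
    blood_volume_source: str  # "estimated" or "provided"
    blood_conc_1h_ug_mL: float
    blood_conc_1h_interpolated: bool
    n_clamped: int


def build_patient_datasets(
    obs: pd.DataFrame,
    vascular_volumes: Optional[Mapping[Tuple[str, str], Mapping[str, float]]] = None,
) -> Tuple[List[PatientDataset], List[PartitionRecord]]:
    """Vascular-partition stage: observations → fit-ready datasets.

    For each patient-fraction the intra-organ blood volume is estimated from
    the 4 h whole-organ amount and the (log-linearly interpolated if needed)
    1 h blood concentration, unless ``vascular_volumes`` supplies known
    volumes keyed by (patient_id, fraction) → {organ_id: mL}.  The blood
    constituent is subtracted at every imaging time with the same fixed
    volume; negative tissue amounts are clamped to zero and counted.
    """
    datasets: List[PatientDataset] = []
    records: List[PartitionRecord] = []
    for (pid, frac), group in obs.groupby(["patient_id", "fraction"], sort=True):
        blood = group[group["region"] == "blood"].sort_values("time_min")
        if blood.empty:
            raise ValueError(f"{pid}/{frac}: no blood samples")
        bt = blood["time_min"].to_numpy(dtype=float)
        bc = blood["value"].to_numpy(dtype=float)
        conc_1h = interpolate_blood_concentration(bt, bc, at_min=60.0)
        interpolated = not np.any(np.isclose(bt, 60.0))

        series = {BLOOD: ObservedSeries(tuple(bt), tuple(bc))}
        organ_volumes: Dict[str, float] = {}
        organ_masses: Dict[str, float] = {}
        vascular: Dict[str, float] = {}
        for organ in sorted(set(group["region"]) - {"blood"}):
            comp = ORGAN_TO_COMPARTMENT[organ]
            g = group[group["region"] == organ].sort_values("time_min")
            mass = float(g["organ_mass_g"].iloc[0])
            vol = float(g["organ_volume_mL"].iloc[0])
            supplied = vascular_volumes.get((pid, frac), {}).get(organ) if vascular_volumes else None
            if supplied is not None:
                v_blood = float(supplied)
                source = "provided"
            else:
                t4 = g.iloc[(g["time_min"] - 240.0).abs().argmin()]
                est = estimate_blood_volume(
                    float(t4["value"]), conc_1h, mass, organ_id=organ, organ_volume_mL=vol
                )
                v_blood = est.blood_volume_mL
                source = "estimated"
            est_obj = VascularEstimate(
                organ_id=organ, blood_volume_mL=v_blood,
                blood_volume_mL_per_g=v_blood / mass,
                exceeds_organ_volume=v_blood > vol,
            )
            n_clamped = 0
            times, concs = [], []
            for row in g.itertuples(index=False):
                cb_t = interpolate_blood_concentration(bt, bc, at_min=float(row.time_min))
                obs_row = OrganObservation(
                    organ_id=organ, time_min=float(row.time_min),
                    total_amount_ug=float(row.value), organ_mass_g=mass,
                    organ_volume_mL=vol,
                )
                ta = subtract_blood(obs_row, est_obj, cb_t)
                tissue_ug, clamped = ta.tissue_amount_ug, ta.clamped
                n_clamped += int(clamped)
                times.append(float(row.time_min))
                concs.append(tissue_ug / vol)
            series[comp] = ObservedSeries(tuple(times), tuple(concs))
            organ_volumes[comp] = vol
            organ_masses[comp] = mass
            vascular[comp] = v_blood
            records.append(PartitionRecord(
                patient_id=str(pid), fraction=str(frac), organ_id=organ,
                blood_volume_mL=v_blood, blood_volume_source=source,
                blood_conc_1h_ug_mL=conc_1h,
                blood_conc_1h_interpolated=interpolated, n_clamped=n_clamped,
            ))
        datasets.append(PatientDataset(
            patient_id=str(pid), fraction=str(frac), dose_ug=1000.0,
            series=series, organ_volumes_mL=organ_volumes,
            organ_masses_g=organ_masses, vascular_volumes_mL=vascular,
        ))
    return datasets, records


class RunConfig(BaseModel):
    """Schema-validated configuration of one pipeline run."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    seed: int = 0
    out_dir: str = "ritpk_run"
    # data source: synthetic cohort by default, or an observation CSV path
    observations_csv: Optional[str] = None
    dose_ug: float = 1000.0
    n_patients_F1: int = 19
    n_patients_F2: int = 13
    iiv_cv: float = 0.3
    noise_cv: float = 0.1
    # fitting
    topology: Literal["five_compartment", "select"] = "five_compartment"
    n_starts: int = 5
    weighting: Optional[Literal["1/y2"]] = None
    # vascular partition: one-sample estimation or generator truth
    vascular_volumes: Literal["estimated", "truth"] = "estimated"
    alpha: float = 0.05
    isotope_half_life_h: float = 67.0
    counting_efficiency: float = 0.933
    specific_activity_MBq_per_mg: float = 138.0


def _config_hash(config: RunConfig) -> str:
    payload = json.dumps(config.model_dump(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Execute synth-or-load → convert → partition → fit → summarize → compare.

    Writes per-stage CSV/JSON outputs under ``config.out_dir`` and returns a
    manifest dict (also written as ``manifest.json``).  Fully reproducible
    from config + seed.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    radiolabel = RadiolabelSpec(
        isotope_half_life_h=config.isotope_half_life_h,
        counting_efficiency=config.counting_efficiency,
        specific_activity_MBq_per_mg=config.specific_activity_MBq_per_mg,
    )

    truth: Optional[TruthRecord] = None
    if config.observations_csv is not None:
        obs = read_observations(config.observations_csv, radiolabel)
    else:
        spec = CohortSpec(
            n_patients_F1=config.n_patients_F1,
            n_patients_F2=config.n_patients_F2,
            dose_ug=config.dose_ug,
            iiv_cv=config.iiv_cv,
            noise_cv=config.noise_cv,
            seed=config.seed,
        )
        obs, truth = generate_cohort(spec)
        write_observations(obs, out / "obs.csv")
        generate_activity_layer(obs, radiolabel).to_csv(out / "activity.csv", index=False)
        (out / "truth.json").write_text(truth.to_json())

    vascular = None
    if config.vascular_volumes == "truth":
        if truth is None:
            raise ValueError("vascular_volumes='truth' requires the synthetic source")
        vascular = {
            (p.patient_id, p.fraction): p.vascular_volumes_mL for p in truth.patients
        }
    datasets, partition = build_patient_datasets(obs, vascular_volumes=vascular)
    datasets = [
        PatientDataset(
            patient_id=d.patient_id, fraction=d.fraction, dose_ug=config.dose_ug,
            series=d.series, organ_volumes_mL=d.organ_volumes_mL,
            organ_masses_g=d.organ_masses_g, vascular_volumes_mL=d.vascular_volumes_mL,
        )
        for d in datasets
    ]
    pd.DataFrame([asdict(r) for r in partition]).to_csv(out / "partition.csv", index=False)

    options = FitOptions(n_starts=config.n_starts, seed=config.seed,
                         weighting=config.weighting)
    topology = five_compartment_model()
    fits: List[FitResult] = []
    rank_rows: List[dict] = []
    for ds in datasets:
        if config.topology == "select":
            best, ranking = select_model(default_catalogue(), ds, options)
            fits.append(best)
            for r in ranking:
                rank_rows.append({
                    "patient_id": ds.patient_id, "fraction": ds.fraction,
                    "topology_id": r.topology_id, "n_params": r.n_params,
                    "ssr": r.ssr, "aic": r.aic, "converged": r.converged,
                })
        else:
            fits.append(fit(topology, ds, options))
    if rank_rows:
        pd.DataFrame(rank_rows).to_csv(out / "ranking.csv", index=False)
    fit_dump = [
        {"patient_id": d.patient_id, "fraction": d.fraction,
         "topology_id": f.topology_id, "params": f.delta_params,
         "ssr": f.ssr, "aic": f.aic, "converged": f.converged}
        for d, f in zip(datasets, fits)
    ]
    (out / "fits.json").write_text(json.dumps(fit_dump, indent=2, sort_keys=True))

    summary_rows: List[dict] = []
    for ds, f in zip(datasets, fits):
        summary_rows.extend(summarize_fit(f, ds).row_dicts())
    summaries = pd.DataFrame(summary_rows)
    summaries.to_csv(out / "pk_summaries.csv", index=False)

    s1 = summaries[summaries["fraction"] == "F1"]
    s2 = summaries[summaries["fraction"] == "F2"]
    comparison_rows = []
    if not s1.empty and not s2.empty:
        for row in compare_fractions(s1, s2, alpha=config.alpha):
            comparison_rows.append({
                "parameter": row.parameter,
                "F1_mean": row.f1_mean, "F1_sd": row.f1_sd,
                "F2_mean": row.f2_mean, "F2_sd": row.f2_sd,
                "U": row.u_statistic, "p_value": row.p_value,
                "significant": row.significant, "method": row.method,
            })
        pd.DataFrame(comparison_rows).to_csv(out / "comparison.csv", index=False)

    manifest = {
        "ritpk_version": __version__,
        "config": config.model_dump(),
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "aic_variant": "n*ln(SSR/n) + 2p",
        "weighting": config.weighting or "unweighted",
        "optimizer": f"least_squares(trf, log10 params, {config.n_starts} starts)",
        "spleen_rate_labels": "cohort-table spleen k13/k31 mapped to k14 (blood->spleen)"
                              " and k43 (spleen->liver)",
        "n_datasets": len(datasets),
        "n_comparisons": len(comparison_rows),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
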