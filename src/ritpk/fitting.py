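"""Least-squares fitting of compartmental topologies and AIC model selection.

A candidate topology is fitted to one patient-fraction's concentration
observations by minimizing the unweighted sum of squared residuals over all
observed compartments simultaneously (blood concentration = blood amount/Vd;
organ concentration = tissue amount / CT organ volume).  Rates and Vd are
optimized on a log10 scale, which enforces positivity and equalizes
sensitivity across parameters spanning orders of magnitude; a seeded
multi-start (default 5 starts) guards against local minima of the
multi-exponential objective.

Candidates are ranked by the least-squares Akaike Information Criterion

    AIC = n ln(SSR/n) + 2 p

with ties (including effectively perfect fits, where SSR is at floating-point
level) broken by fewer parameters, then topology id.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import product
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import least_squares

from .dataset import PatientDataset
from .model import (
    BLOOD,
    DEEP,
    LIVER,
    SPLEEN,
    VERTEBRAE,
    CompartmentTopology,
    ParameterVector,
    five_compartment_model,
    two_compartment_model,
)

__all__ = [
    "FitOptions",
    "FitResult",
    "ModelCatalogue",
    "aic",
    "fit",
    "build_catalogue",
    "default_catalogue",
    "select_model",
]

#: initial guesses: rates at the 1e-4 min⁻¹ scale typical of antibody
#: organ exchange; Vd at plasma-like 0.07 L/kg * 70 kg.
DEFAULT_K_INIT = 1e-4
DEFAULT_VD_INIT = 4900.0

LOG_K_BOUNDS = (-9.0, -1.0)
LOG_VD_BOUNDS = (1.0, 6.0)


@dataclass(frozen=True)
class FitOptions:
    """Optimizer configuration.

    ``n_starts`` seeded multi-starts (the first uses the neutral initial
    guess, the rest jitter it in log10 space); ``weighting`` is ``None``
    (unweighted SSR) or ``"1/y2"`` (relative residuals).
    """

    n_starts: int = 5
    seed: int = 0
    weighting: Optional[str] = None
    k_init: float = DEFAULT_K_INIT
    vd_init: float = DEFAULT_VD_INIT
    jitter_sd_log10: float = 0.5
    ftol: float = 1e-14
    xtol: float = 1e-14
    gtol: float = 1e-14
    max_nfev: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")
        if self.weighting not in (None, "1/y2"):
            raise ValueError("weighting must be None or '1/y2'")


@dataclass(frozen=True)
class FitResult:
    """Outcome of fitting one topology to one patient-fraction."""

    topology_id: str
    topology: CompartmentTopology
    params: ParameterVector
    ssr: float
    n_obs: int
    n_params: int
    aic: float
    converged: bool
    n_iter: int
    residuals: np.ndarray
    exact_fit: bool = False  # SSR at floating-point floor (AIC = -inf sentinel)

    @property
    def delta_params(self) -> Dict[str, float]:
        return self.params.to_flat_dict()


def aic(ssr: float, n_obs: int, n_params: int) -> float:
    """Least-squares AIC: n ln(SSR/n) + 2 p.  SSR = 0 returns -inf."""
    if n_obs <= 0:
        raise ValueError("n_obs must be > 0")
    if ssr < 0:
        raise ValueError("ssr must be >= 0")
    if ssr == 0.0:
        return float("-inf")
    return n_obs * math.log(ssr / n_obs) + 2 * n_params


def _pack_names(topology: CompartmentTopology) -> Tuple[str, ...]:
    return topology.parameter_names + ("Vd",)


def _unpack(theta_log10: np.ndarray, topology: CompartmentTopology) -> ParameterVector:
    vals = 10.0 ** np.asarray(theta_log10, dtype=float)
    names = _pack_names(topology)
    flat = dict(zip(names, vals))
    return ParameterVector.from_flat_dict(flat, topology)


def fit(
    topology: CompartmentTopology,
    dataset: PatientDataset,
    options: FitOptions = FitOptions(),
) -> FitResult:
    """Fit one topology to one patient-fraction by multi-start least squares.

    Raises when the dataset has fewer observations than free parameters, or
    when every observed concentration is zero (nothing to fit).
    """
    names = _pack_names(topology)
    n_params = len(names)
    n_obs = dataset.n_obs
    if n_obs <= n_params:
        raise ValueError(f"{n_obs} observations cannot constrain {n_params} parameters")

    all_times = sorted({t for s in dataset.series.values() for t in s.times_min})
    times = np.asarray(all_times, dtype=float)
    time_index = {t: i for i, t in enumerate(all_times)}
    obs_vecs = {
        comp: (np.asarray(s.concentrations, dtype=float),
               np.asarray([time_index[t] for t in s.times_min], dtype=int))
        for comp, s in dataset.series.items()
    }
    if all(np.all(v == 0) for v, _ in obs_vecs.values()):
        raise ValueError("all observed concentrations are zero; degenerate dataset")

    weighting = options.weighting

    # Precompiled evaluator: rates enter the system matrix through index
    # arrays and the solution uses a direct eigendecomposition, keeping the
    # per-evaluation cost flat across the thousands of calls a multi-start
    # derivative-based fit makes.
    nc = topology.n_compartments
    comp_index = {c: i for i, c in enumerate(topology.compartments)}
    edge_from = np.array([comp_index[e[0]] for e in topology.edges], dtype=int)
    edge_to = np.array([comp_index[e[1]] for e in topology.edges], dtype=int)
    elim_idx = np.array([comp_index[c] for c in topology.elimination], dtype=int)
    n_edges = len(topology.edges)
    j_in = comp_index[topology.input_compartment]
    obs_order = list(obs_vecs)
    obs_concat = np.concatenate([obs_vecs[c][0] for c in obs_order])

    def residual_fn(theta: np.ndarray) -> np.ndarray:
        vals = 10.0 ** np.asarray(theta, dtype=float)
        rates, vd = vals[:-1], vals[-1]
        A = np.zeros((nc, nc))
        np.add.at(A, (edge_to, edge_from), rates[:n_edges])
        np.add.at(A, (edge_from, edge_from), -rates[:n_edges])
        np.add.at(A, (elim_idx, elim_idx), -rates[n_edges:])
        a0 = np.zeros(nc)
        a0[j_in] = dataset.dose_ug
        try:
            w, V = np.linalg.eig(A)
            c0 = np.linalg.solve(V, a0.astype(complex))
            amounts = (V @ (np.exp(np.outer(w, times)) * c0[:, None])).real
        except np.linalg.LinAlgError:
            from scipy.linalg import expm as _expm

            amounts = np.column_stack([_expm(A * t) @ a0 for t in times])
        preds = np.empty(obs_concat.size)
        pos = 0
        for comp in obs_order:
            obs, idx = obs_vecs[comp]
            row = comp_index.get(comp)
            if row is None:
                pred = np.zeros(idx.size)
            elif comp == BLOOD:
                pred = amounts[row, idx] / vd
            else:
                pred = amounts[row, idx] / dataset.organ_volumes_mL[comp]
            preds[pos:pos + idx.size] = pred
            pos += idx.size
        r = obs_concat - preds
        if weighting == "1/y2":
            r = r / np.maximum(np.abs(preds), 1e-6)
        return r

    lb = np.array([LOG_K_BOUNDS[0]] * (n_params - 1) + [LOG_VD_BOUNDS[0]])
    ub = np.array([LOG_K_BOUNDS[1]] * (n_params - 1) + [LOG_VD_BOUNDS[1]])
    x0 = np.array([math.log10(options.k_init)] * (n_params - 1) + [math.log10(options.vd_init)])
    rng = np.random.default_rng(options.seed)

    best = None
    best_cost = np.inf
    total_nfev = 0
    any_converged = False
    for start in range(options.n_starts):
        xs = x0 if start == 0 else np.clip(
            x0 + rng.normal(0.0, options.jitter_sd_log10, size=x0.size), lb, ub
        )
        try:
            sol = least_squares(
                residual_fn,
                xs,
                bounds=(lb, ub),
                method="trf",
                ftol=options.ftol,
                xtol=options.xtol,
                gtol=options.gtol,
                max_nfev=options.max_nfev,
            )
        except Exception:
            continue
        total_nfev += sol.nfev
        any_converged = any_converged or (sol.status > 0)
        if sol.cost < best_cost:
            best_cost = sol.cost
            best = sol
    if best is None:
        raise RuntimeError("all optimizer starts failed")

    params = _unpack(best.x, topology)
    residuals = best.fun
    ssr = float(np.dot(residuals, residuals))
    scale = float(np.sqrt(np.mean(np.concatenate([v for v, _ in obs_vecs.values()]) ** 2)))
    exact = ssr <= n_obs * (1e-7 * max(scale, 1e-30)) ** 2
    score = float("-inf") if exact else aic(ssr, n_obs, n_params)
    return FitResult(
        topology_id=topology.topology_id,
        topology=topology,
        params=params,
        ssr=ssr,
        n_obs=n_obs,
        n_params=n_params,
        aic=score,
        converged=bool(any_converged and best.status > 0),
        n_iter=total_nfev,
        residuals=residuals,
        exact_fit=exact,
    )


@dataclass(frozen=True)
class ModelCatalogue:
    """Ordered collection of candidate topologies."""

    members: Tuple[CompartmentTopology, ...]

    def __post_init__(self) -> None:
        ids = [m.topology_id for m in self.members]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate topology ids in catalogue")

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self):
        return iter(self.members)

    def ids(self) -> List[str]:
        return [m.topology_id for m in self.members]


def _make_topology(
    organs: Sequence[str],
    organ_mode: Dict[str, str],
    spleen_efflux: Optional[str],
    deep: bool,
    elim_site: str,
) -> CompartmentTopology:
    comps = [BLOOD] + list(organs) + ([DEEP] if deep else [])
    edges: List[Tuple[str, str]] = []
    tags = []
    for organ in organs:
        edges.append((BLOOD, organ))
        if organ == SPLEEN:
            target = spleen_efflux
            if target is not None:
                edges.append((SPLEEN, target))
                tags.append(f"spleen>{'blood' if target == BLOOD else 'liver'}")
            else:
                tags.append("spleen1")
        else:
            name = "vert" if organ == VERTEBRAE else "liver"
            if organ_mode[organ] == "bi":
                edges.append((organ, BLOOD))
                tags.append(f"{name}2")
            else:
                tags.append(f"{name}1")
    if deep:
        edges.append((BLOOD, DEEP))
        edges.append((DEEP, BLOOD))
        tags.append("deep2")
    elim_name = {BLOOD: "blood", LIVER: "liver", SPLEEN: "spleen"}[elim_site]
    tid = "blood_" + "_".join(tags) + f"_elim-{elim_name}"
    return CompartmentTopology(
        topology_id=tid,
        compartments=tuple(comps),
        edges=tuple(edges),
        elimination=(elim_site,),
    )


def build_catalogue(
    organ_sets: Optional[Sequence[Tuple[str, ...]]] = None,
) -> ModelCatalogue:
    """Enumerate candidate topologies over structural axes.

    Axes: which organ compartments are present (optionally restricted via
    ``organ_sets``), a deep compartment present or not, each of vertebrae and
    liver exchanging bidirectionally or filling from blood only, spleen
    efflux routed to blood or (when the liver is present) to the liver, and
    a single elimination site among blood / liver / spleen.

    Every sampled-organ structure must keep the spleen one-directional on
    its input side (blood→spleen always); models without a particular organ
    simply predict no signal there.
    """
    if organ_sets is None:
        organ_sets = [
            (), (VERTEBRAE,), (LIVER,), (SPLEEN,),
            (VERTEBRAE, LIVER), (VERTEBRAE, SPLEEN), (LIVER, SPLEEN),
            (VERTEBRAE, LIVER, SPLEEN),
        ]
    members: List[CompartmentTopology] = []
    seen = set()
    for organs in organ_sets:
        for deep in (False, True):
            if not organs and not deep:
                continue
            mode_axes = []
            for organ in organs:
                if organ == SPLEEN:
                    targets = [BLOOD] + ([LIVER] if LIVER in organs else [])
                    mode_axes.append([("efflux", t) for t in targets])
                else:
                    mode_axes.append([(organ, m) for m in ("bi", "uni")])
            elim_sites = [BLOOD] + [o for o in (LIVER, SPLEEN) if o in organs]
            for combo in product(*mode_axes) if mode_axes else [()]:
                organ_mode = {k: v for k, v in combo if k != "efflux"}
                efflux = next((v for k, v in combo if k == "efflux"), None)
                for elim in elim_sites:
                    top = _make_topology(organs, organ_mode, efflux, deep, elim)
                    if top.topology_id not in seen:
                        seen.add(top.topology_id)
                        members.append(top)
    return ModelCatalogue(tuple(members))


def default_catalogue() -> ModelCatalogue:
    """Default candidate set for model selection on fully sampled data.

    Every member describing the three sampled organs (with or without a deep
    compartment, all exchange-direction and elimination-site variants) plus
    the classic central+peripheral two-compartment model.  Contains the
    selected five-compartment biodistribution topology.
    """
    full = build_catalogue(organ_sets=[(VERTEBRAE, LIVER, SPLEEN)])
    members = list(full.members)
    two = two_compartment_model()
    if two.topology_id not in {m.topology_id for m in members}:
        members.append(two)
    cat = ModelCatalogue(tuple(members))
    assert five_compartment_model().topology_id in cat.ids()
    return cat


def select_model(
    catalogue: ModelCatalogue,
    dataset: PatientDataset,
    options: FitOptions = FitOptions(),
) -> Tuple[FitResult, List[FitResult]]:
    """Fit every catalogue member and rank by AIC.

    Ties (and exact fits, which share the -inf AIC sentinel) are broken by
    fewer parameters, then topology id.  Returns (best fit, full ranking).
    """
    if len(catalogue) == 0:
        raise ValueError("empty catalogue")
    results: List[FitResult] = []
    for top in catalogue:
        try:
            results.append(fit(top, dataset, options))
        except (ValueError, RuntimeError):
            continue
    if not results:
        raise RuntimeError("every candidate fit failed")
    results.sort(key=lambda r: (r.aic, r.n_params, r.topology_id))
    return results[0], results
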