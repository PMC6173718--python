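"""Linear compartmental models of antibody biodistribution.

A topology is a directed graph over compartments (blood is the central/input
compartment) with first-order transfer rate constants k_ij (min⁻¹) on its
edges and first-order elimination from one or more compartments.  Amounts
a(t) (µg) obey the linear time-invariant system

    da/dt = A a + r(t),      A[i, j] = k_{j→i} for i ≠ j,
                             A[j, j] = −(Σ_i k_{j→i} + k_el,j)

so a bolus solves a(t) = expm(A t) a(0) exactly.  The reference solver uses
the matrix exponential (eigendecomposition with an expm fallback); an
adaptive ODE integration is provided as an independent cross-check.

The selected five-compartment biodistribution model has blood (x1) exchanging
bidirectionally with L2–L4 vertebrae (x2), liver (x3) and a deep compartment
(x5, all unsampled tissue including tumor), a unidirectional blood→spleen
(x4) input with spleen efflux routed to the liver, and first-order
elimination from blood only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
from scipy.integrate import solve_ivp
from scipy.linalg import expm

BLOOD = "x1"
VERTEBRAE = "x2"
LIVER = "x3"
SPLEEN = "x4"
DEEP = "x5"

COMPARTMENT_NAMES = {
    BLOOD: "blood",
    VERTEBRAE: "vertebrae_L2L4",
    LIVER: "liver",
    SPLEEN: "spleen",
    DEEP: "deep",
}
ORGAN_TO_COMPARTMENT = {
    "vertebrae_L2L4": VERTEBRAE,
    "liver": LIVER,
    "spleen": SPLEEN,
}

Edge = Tuple[str, str]

__all__ = [
    "BLOOD",
    "VERTEBRAE",
    "LIVER",
    "SPLEEN",
    "DEEP",
    "COMPARTMENT_NAMES",
    "ORGAN_TO_COMPARTMENT",
    "CompartmentTopology",
    "ParameterVector",
    "DoseEvent",
    "SimulatedCourse",
    "five_compartment_model",
    "two_compartment_model",
    "rate_matrix",
    "simulate",
    "simulate_ode",
    "edge_key",
]


def edge_key(edge: Edge) -> str:
    """Flat JSON key for a transfer edge: ('x1','x2') -> 'k12'."""
    return f"k{edge[0][1:]}{edge[1][1:]}"


def elimination_key(comp: str) -> str:
    return "kel" if comp == BLOOD else f"kel{comp[1:]}"


@dataclass(frozen=True)
class CompartmentTopology:
    """Directed-graph structure of a linear compartmental model."""

    topology_id: str
    compartments: Tuple[str, ...]
    edges: Tuple[Edge, ...]
    elimination: Tuple[str, ...]
    input_compartment: str = BLOOD

    def __post_init__(self) -> None:
        comps = set(self.compartments)
        if self.input_compartment not in comps:
            raise ValueError("input compartment missing from compartment list")
        if len(comps) != len(self.compartments):
            raise ValueError("duplicate compartment ids")
        for a, b in self.edges:
            if a == b:
                raise ValueError(f"self-loop {a}->{b}")
            if a not in comps or b not in comps:
                raise ValueError(f"edge {a}->{b} references unknown compartment")
        if len(set(self.edges)) != len(self.edges):
            raise ValueError("duplicate edges")
        if not self.elimination:
            raise ValueError("at least one elimination compartment required")
        for c in self.elimination:
            if c not in comps:
                raise ValueError(f"elimination from unknown compartment {c}")
        # reachability from the input compartment
        reach = {self.input_compartment}
        frontier = [self.input_compartment]
        adj: Dict[str, List[str]] = {}
        for a, b in self.edges:
            adj.setdefault(a, []).append(b)
        while frontier:
            nxt = []
            for a in frontier:
                for b in adj.get(a, ()):
                    if b not in reach:
                        reach.add(b)
                        nxt.append(b)
            frontier = nxt
        if reach != comps:
            raise ValueError("graph not connected from the input compartment")

    @property
    def n_compartments(self) -> int:
        return len(self.compartments)

    @property
    def parameter_names(self) -> Tuple[str, ...]:
        """Rate-constant names in canonical order (edges, then eliminations)."""
        names = [edge_key(e) for e in self.edges]
        names += [elimination_key(c) for c in self.elimination]
        return tuple(names)

    def index(self, comp: str) -> int:
        return self.compartments.index(comp)

    def to_json_dict(self) -> dict:
        return {
            "id": self.topology_id,
            "compartments": list(self.compartments),
            "edges": [list(e) for e in self.edges],
            "elimination": list(self.elimination),
            "input": self.input_compartment,
        }

    @staticmethod
    def from_json_dict(d: Mapping) -> "CompartmentTopology":
        return CompartmentTopology(
            topology_id=d["id"],
            compartments=tuple(d["compartments"]),
            edges=tuple((a, b) for a, b in d["edges"]),
            elimination=tuple(d["elimination"]),
            input_compartment=d.get("input", BLOOD),
        )


@dataclass(frozen=True)
class ParameterVector:
    """Rate constants (min⁻¹) and central distribution volume Vd (mL).

    ``k`` maps transfer edges to rates; ``k_el`` maps compartments to
    first-order elimination rates.
    """

    Vd_mL: float
    k: Mapping[Edge, float] = field(default_factory=dict)
    k_el: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.Vd_mL > 0:
            raise ValueError("Vd must be > 0")
        for e, v in self.k.items():
            if v < 0 or not np.isfinite(v):
                raise ValueError(f"rate {edge_key(e)} must be finite and >= 0")
        for c, v in self.k_el.items():
            if v < 0 or not np.isfinite(v):
                raise ValueError(f"elimination rate from {c} must be finite and >= 0")

    def to_flat_dict(self) -> Dict[str, float]:
        out = {edge_key(e): float(v) for e, v in self.k.items()}
        out.update({elimination_key(c): float(v) for c, v in self.k_el.items()})
        out["Vd"] = float(self.Vd_mL)
        return out

    @staticmethod
    def from_flat_dict(d: Mapping[str, float], topology: CompartmentTopology) -> "ParameterVector":
        k = {e: float(d[edge_key(e)]) for e in topology.edges}
        k_el = {c: float(d[elimination_key(c)]) for c in topology.elimination}
        return ParameterVector(Vd_mL=float(d["Vd"]), k=k, k_el=k_el)


@dataclass(frozen=True)
class DoseEvent:
    """Administered dose: bolus (duration 0) or zero-order infusion."""

    amount_ug: float
    start_min: float = 0.0
    duration_min: float = 0.0

    def __post_init__(self) -> None:
        if not self.amount_ug > 0:
            raise ValueError("dose amount must be > 0")
        if self.duration_min < 0 or self.start_min < 0:
            raise ValueError("dose start/duration must be >= 0")


@dataclass(frozen=True)
class SimulatedCourse:
    """Amount-time courses for every compartment plus the eliminated amount."""

    topology: CompartmentTopology
    times_min: np.ndarray
    amounts_ug: np.ndarray  # shape (n_compartments, n_times)
    eliminated_ug: np.ndarray

    def amount(self, comp: str) -> np.ndarray:
        return self.amounts_ug[self.topology.index(comp)]

    def blood_concentration(self, Vd_mL: float) -> np.ndarray:
        """Blood amount divided by the central distribution volume, µg/mL."""
        return self.amount(BLOOD) / Vd_mL

    def tissue_concentration(self, comp: str, organ_volume_mL: float) -> np.ndarray:
        return self.amount(comp) / organ_volume_mL


def five_compartment_model() -> CompartmentTopology:
    """The selected biodistribution topology (blood, vertebrae, liver, spleen,
    deep): bidirectional exchange with every peripheral compartment except the
    spleen, which fills from blood and drains into the liver; elimination
    from blood only."""
    return CompartmentTopology(
        topology_id="blood_vert2_liver2_spleen>liver_deep2_elim-blood",
        compartments=(BLOOD, VERTEBRAE, LIVER, SPLEEN, DEEP),
        edges=(
            (BLOOD, VERTEBRAE),
            (VERTEBRAE, BLOOD),
            (BLOOD, LIVER),
            (LIVER, BLOOD),
            (BLOOD, SPLEEN),
            (SPLEEN, LIVER),
            (BLOOD, DEEP),
            (DEEP, BLOOD),
        ),
        elimination=(BLOOD,),
    )


def two_compartment_model() -> CompartmentTopology:
    """Classic central + peripheral (deep) model with blood elimination."""
    return CompartmentTopology(
        topology_id="blood_deep2_elim-blood",
        compartments=(BLOOD, DEEP),
        edges=((BLOOD, DEEP), (DEEP, BLOOD)),
        elimination=(BLOOD,),
    )


def rate_matrix(topology: CompartmentTopology, params: ParameterVector) -> np.ndarray:
    """Assemble the system matrix A (min⁻¹).

    Column j sums to −k_el(j): transfers conserve mass, elimination leaks it.
    """
    n = topology.n_compartments
    A = np.zeros((n, n))
    for e in topology.edges:
        if e not in params.k:
            raise KeyError(f"missing rate for edge {edge_key(e)}")
        i, j = topology.index(e[1]), topology.index(e[0])
        rate = params.k[e]
        A[i, j] += rate
        A[j, j] -= rate
    for c in topology.elimination:
        if c not in params.k_el:
            raise KeyError(f"missing elimination rate for {c}")
        j = topology.index(c)
        A[j, j] -= params.k_el[c]
    return A


def _propagate(A: np.ndarray, a0: np.ndarray, times: np.ndarray) -> np.ndarray:
    """expm(A t) @ a0 for each t, via eigendecomposition when well-conditioned."""
    try:
        w, V = np.linalg.eig(A)
        cond = np.linalg.cond(V)
    except np.linalg.LinAlgError:
        cond = np.inf
    if np.isfinite(cond) and cond < 1e8:
        c0 = np.linalg.solve(V, a0.astype(complex))
        out = (V @ (np.exp(np.outer(w, times)) * c0[:, None])).real
        return out
    return np.column_stack([expm(A * t) @ a0 for t in times])


def _infusion_state(A: np.ndarray, a0: np.ndarray, r: np.ndarray, dt: float) -> np.ndarray:
    """State after time dt under constant input rate r, robust to singular A.

    Uses the augmented-matrix identity expm([[A, r], [0, 0]] dt) which yields
    expm(A dt) a0 + ∫ expm(A s) r ds without inverting A.
    """
    n = A.shape[0]
    M = np.zeros((n + 1, n + 1))
    M[:n, :n] = A
    M[:n, n] = r
    E = expm(M * dt)
    return E[:n, :n] @ a0 + E[:n, n]


def simulate(
    topology: CompartmentTopology,
    params: ParameterVector,
    dose: DoseEvent,
    times_min: Sequence[float],
) -> SimulatedCourse:
    """Exact (matrix-exponential) solution of the amount system.

    Bolus doses enter the input compartment instantaneously at
    ``dose.start_min``; infusions add a zero-order input over the stated
    duration.  Output times before the dose start hold zero amount.
    """
    t = np.asarray(times_min, dtype=float)
    if t.ndim != 1 or np.any(t < 0) or np.any(np.diff(t) < 0):
        raise ValueError("times must be a sorted, non-negative 1-D sequence")
    A = rate_matrix(topology, params)
    if not np.all(np.isfinite(A)):
        raise ValueError("non-finite rate matrix")
    n = topology.n_compartments
    j_in = topology.index(topology.input_compartment)
    amounts = np.zeros((n, t.size))

    if dose.duration_min == 0.0:
        a0 = np.zeros(n)
        a0[j_in] = dose.amount_ug
        after = t >= dose.start_min
        if after.any():
            amounts[:, after] = _propagate(A, a0, t[after] - dose.start_min)
        delivered = np.where(after, dose.amount_ug, 0.0)
    else:
        rate = dose.amount_ug / dose.duration_min
        r = np.zeros(n)
        r[j_in] = rate
        t_end = dose.start_min + dose.duration_min
        a_end = _infusion_state(A, np.zeros(n), r, dose.duration_min)
        during = (t >= dose.start_min) & (t < t_end)
        for idx in np.nonzero(during)[0]:
            amounts[:, idx] = _infusion_state(A, np.zeros(n), r, t[idx] - dose.start_min)
        after = t >= t_end
        if after.any():
            amounts[:, after] = _propagate(A, a_end, t[after] - t_end)
        delivered = np.clip((t - dose.start_min) * rate, 0.0, dose.amount_ug)

    amounts = np.clip(amounts, 0.0, None)  # suppress negative round-off
    eliminated = delivered - amounts.sum(axis=0)
    return SimulatedCourse(topology, t, amounts, eliminated)


def simulate_ode(
    topology: CompartmentTopology,
    params: ParameterVector,
    dose: DoseEvent,
    times_min: Sequence[float],
    rtol: float = 1e-10,
    atol: float = 1e-12,
) -> SimulatedCourse:
    """Adaptive ODE (LSODA) solution; independent cross-check of `simulate`.

    Bolus only (the matrix-exponential path is the reference for infusions).
    """
    if dose.duration_min != 0.0:
        raise NotImplementedError("ODE cross-check supports bolus dosing only")
    t = np.asarray(times_min, dtype=float)
    A = rate_matrix(topology, params)
    n = topology.n_compartments
    a0 = np.zeros(n)
    a0[topology.index(topology.input_compartment)] = dose.amount_ug
    amounts = np.zeros((n, t.size))
    after = t >= dose.start_min
    if after.any():
        tt = t[after] - dose.start_min
        sol = solve_ivp(
            lambda _, a: A @ a,
            (0.0, float(tt[-1]) if tt[-1] > 0 else 1.0),
            a0,
            t_eval=tt,
            method="LSODA",
            rtol=rtol,
            atol=atol,
        )
        if not sol.success:
            raise RuntimeError(f"ODE integration failed: {sol.message}")
        amounts[:, after] = sol.y
    delivered = np.where(after, dose.amount_ug, 0.0)
    return SimulatedCourse(topology, t, np.clip(amounts, 0.0, None), delivered - amounts.sum(axis=0))
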