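"""Compartment model: topology structure, rate matrix, simulation oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ritpk import (
    CompartmentTopology,
    DoseEvent,
    ParameterVector,
    five_compartment_model,
    rate_matrix,
    simulate,
    simulate_ode,
    two_compartment_model,
)
from ritpk.model import BLOOD, DEEP, LIVER, SPLEEN, VERTEBRAE


class TestTopology:
    def test_selected_model_structure(self, topology):
        assert len(topology.edges) == 8
        assert topology.elimination == (BLOOD,)
        assert topology.input_compartment == BLOOD
        # spleen fills from blood and drains to the liver, never back to blood
        assert (BLOOD, SPLEEN) in topology.edges
        assert (SPLEEN, LIVER) in topology.edges
        assert (SPLEEN, BLOOD) not in topology.edges
        for comp in (VERTEBRAE, LIVER, DEEP):
            assert (BLOOD, comp) in topology.edges and (comp, BLOOD) in topology.edges

    def test_invalid_topologies_rejected(self):
        with pytest.raises(ValueError):  # unreachable compartment
            CompartmentTopology("bad", (BLOOD, DEEP), (), (BLOOD,))
        with pytest.raises(ValueError):  # self-loop
            CompartmentTopology("bad", (BLOOD,), ((BLOOD, BLOOD),), (BLOOD,))
        with pytest.raises(ValueError):  # no elimination
            CompartmentTopology("bad", (BLOOD, DEEP),
                                ((BLOOD, DEEP), (DEEP, BLOOD)), ())

    def test_json_round_trip(self, topology):
        again = CompartmentTopology.from_json_dict(topology.to_json_dict())
        assert again == topology


class TestRateMatrix:
    def test_one_compartment_elimination_only(self):
        top = CompartmentTopology("mono", (BLOOD,), (), (BLOOD,))
        p = ParameterVector(Vd_mL=1000.0, k_el={BLOOD: 0.01})
        A = rate_matrix(top, p)
        assert A.shape == (1, 1) and A[0, 0] == pytest.approx(-0.01)

    def test_all_zero_rates_give_zero_matrix(self, topology):
        p = ParameterVector(
            Vd_mL=1.0, k={e: 0.0 for e in topology.edges}, k_el={BLOOD: 0.0}
        )
        assert np.all(rate_matrix(topology, p) == 0.0)

    def test_column_sums_equal_minus_elimination(self, topology, f1_params):
        A = rate_matrix(topology, f1_params)
        sums = A.sum(axis=0)
        expected = np.zeros(5)
        expected[0] = -f1_params.k_el[BLOOD]
        assert np.allclose(sums, expected, atol=1e-18)

    def test_missing_rate_rejected(self, topology):
        p = ParameterVector(Vd_mL=1.0, k={}, k_el={BLOOD: 0.01})
        with pytest.raises(KeyError):
            rate_matrix(topology, p)


class TestSimulate:
    def test_one_compartment_closed_form(self):
        top = CompartmentTopology("mono", (BLOOD,), (), (BLOOD,))
        kel, vd, dose = 0.005, 4000.0, 1000.0
        p = ParameterVector(Vd_mL=vd, k_el={BLOOD: kel})
        t = np.linspace(0, 1000, 11)
        course = simulate(top, p, DoseEvent(dose), t)
        expected = (dose / vd) * np.exp(-kel * t)
        assert np.allclose(course.blood_concentration(vd), expected, rtol=1e-12)
        # at one half-life the concentration is half the initial one
        t_half = np.log(2) / kel
        c = simulate(top, p, DoseEvent(dose), [0.0, t_half])
        assert c.blood_concentration(vd)[1] == pytest.approx(dose / (2 * vd))

    def test_zero_rates_keep_dose_in_blood(self, topology):
        p = ParameterVector(
            Vd_mL=1.0, k={e: 0.0 for e in topology.edges}, k_el={BLOOD: 0.0}
        )
        course = simulate(topology, p, DoseEvent(500.0), [0.0, 1e4, 1e6])
        assert np.allclose(course.amount(BLOOD), 500.0)

    def test_matrix_exponential_matches_ode(self, topology, f1_params):
        """Two independent solvers agree to near machine precision."""
        times = np.geomspace(1.0, 168 * 60.0, 50)
        dose = DoseEvent(1000.0)
        a = simulate(topology, f1_params, dose, times).amounts_ug
        b = simulate_ode(topology, f1_params, dose, times).amounts_ug
        assert np.max(np.abs(a - b)) / np.max(a) < 1e-8

    def test_mass_balance_and_non_negativity(self, topology, f1_params):
        times = np.linspace(0.0, 10080.0, 30)
        course = simulate(topology, f1_params, DoseEvent(1000.0), times)
        total = course.amounts_ug.sum(axis=0) + course.eliminated_ug
        assert np.allclose(total, 1000.0, rtol=1e-8)
        assert np.all(course.amounts_ug >= 0.0)
        assert np.all(np.diff(course.eliminated_ug) >= -1e-9)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_mass_balance_random_parameters(self, seed):
        rng = np.random.default_rng(seed)
        top = five_compartment_model()
        flat = {k: 10 ** rng.uniform(-5, -3) for k in top.parameter_names}
        flat["Vd"] = 10 ** rng.uniform(3, 4)
        p = ParameterVector.from_flat_dict(flat, top)
        times = np.geomspace(1.0, 1e4, 12)
        course = simulate(top, p, DoseEvent(1000.0), times)
        total = course.amounts_ug.sum(axis=0) + course.eliminated_ug
        assert np.allclose(total, 1000.0, rtol=1e-8)
        assert np.all(course.amounts_ug >= 0.0)

    def test_infusion_converges_to_bolus_for_short_duration(self, topology, f1_params):
        times = np.array([240.0, 1440.0, 10080.0])
        bolus = simulate(topology, f1_params, DoseEvent(1000.0), times)
        inf = simulate(topology, f1_params, DoseEvent(1000.0, duration_min=1.0), times)
        assert np.allclose(bolus.amounts_ug, inf.amounts_ug, rtol=1e-2)

    def test_infusion_mass_balance_mid_infusion(self, topology, f1_params):
        times = np.array([0.0, 15.0, 30.0, 60.0])
        course = simulate(topology, f1_params, DoseEvent(1000.0, duration_min=30.0), times)
        delivered = np.clip(times / 30.0, 0, 1) * 1000.0
        total = course.amounts_ug.sum(axis=0) + course.eliminated_ug
        assert np.allclose(total, delivered, rtol=1e-8, atol=1e-8)

    def test_terminal_decay_matches_slowest_eigenvalue(self, topology, f1_params):
        A = rate_matrix(topology, f1_params)
        lam = min(abs(w.real) for w in np.linalg.eigvals(A))
        t = np.array([40000.0, 60000.0, 80000.0])
        course = simulate(topology, f1_params, DoseEvent(1000.0), t)
        c = course.blood_concentration(f1_params.Vd_mL)
        slopes = -np.diff(np.log(c)) / np.diff(t)
        assert slopes[-1] == pytest.approx(lam, rel=1e-3)

    def test_unsorted_times_rejected(self, topology, f1_params):
        with pytest.raises(ValueError):
            simulate(topology, f1_params, DoseEvent(1.0), [10.0, 5.0])


def test_two_compartment_model_is_valid():
    top = two_compartment_model()
    assert set(top.compartments) == {BLOOD, DEEP}
    assert top.elimination == (BLOOD,)
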