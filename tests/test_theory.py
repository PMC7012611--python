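import dataclasses
import math

import numpy as np
import pytest

import optobalance as ob
from optobalance.circuits import CircuitSpec, NeuronParams, PopulationLabel
from optobalance.theory import DegenerateCircuitError

from conftest import brute_force_states


def jittered(spec, rng, amount=0.10):
    """Spec with every nonzero interaction redrawn uniformly within +-amount."""
    mask = spec.J > 0
    factors = np.where(mask, rng.uniform(1 - amount, 1 + amount, spec.J.shape), 1.0)
    return spec.with_J(spec.J * factors)


class TestSolveBalance:
    def test_two_pop_baseline(self, architectures):
        spec, _, _ = architectures["two_pop"]
        st = ob.solve_balance(ob.balance_problem(spec), range(2))
        # independent 2x2 solve of 170 + 29 rE - 30 rI = 0, 170 + 36 rE - 36 rI = 0
        assert st.rates == pytest.approx([28.3333, 33.0556], abs=5e-4)
        assert st.consistent

    def test_model2_baseline_vector(self, architectures):
        spec, _, _ = architectures["model2"]
        st = ob.solve_balance(ob.balance_problem(spec), range(4))
        assert st.rates == pytest.approx([3.0362, 6.5783, 6.2653, 3.9690], abs=5e-4)
        assert round(st.rates[spec.index("E")], 1) == 3.0

    def test_single_inhibitory_toy(self):
        # one self-inhibiting population: r = 2 J0 r0 / J_II
        spec = CircuitSpec(
            populations=(PopulationLabel("I", -1),),
            J=np.array([[10.0]]), J0=np.array([1.0]), tau=np.array([[2.0]]),
            neuron=(NeuronParams(g_leak=0.1),),
        )
        st = ob.solve_balance(ob.balance_problem(spec, 0.0), [0])
        assert st.rates[0] == pytest.approx(1.0)

    def test_residual_bound_on_fixtures(self, architectures):
        for _, (spec, _, _) in architectures.items():
            problem = ob.balance_problem(spec, 5.0)
            st = ob.solve_balance(problem, range(spec.n_pop))
            act = sorted(st.active)
            res = np.abs(problem.c[act] + problem.A[np.ix_(act, act)] @ st.rates[act])
            assert res.max() <= 1e-9

    def test_silent_population_inputs(self, architectures):
        spec, _, _ = architectures["two_pop"]
        st = ob.solve_balance(ob.balance_problem(spec, 50.0), [1])
        assert st.rates[0] == 0.0
        assert st.rates[1] == pytest.approx((170 + 50) / 36)
        assert st.silent_inputs[0] < 0 and st.consistent

    def test_degenerate_block_signalled(self):
        spec = CircuitSpec(
            populations=(PopulationLabel("E", 1), PopulationLabel("I", -1)),
            J=np.array([[30.0, 30.0], [30.0, 30.0]]),  # zero determinant
            J0=np.array([10.0, 10.0]),
            tau=np.full((2, 2), 2.0),
            neuron=(NeuronParams(), NeuronParams()),
        )
        with pytest.raises(DegenerateCircuitError):
            ob.solve_balance(ob.balance_problem(spec), range(2))


class TestConsistentStates:
    def test_two_pop_unique_baseline(self, architectures):
        spec, _, _ = architectures["two_pop"]
        states = ob.consistent_states(ob.balance_problem(spec, 0.0))
        assert len(states) == 1 and states[0].active == frozenset({0, 1})

    def test_two_pop_strong_drive_silences_E(self, architectures):
        spec, _, _ = architectures["two_pop"]
        states = ob.consistent_states(ob.balance_problem(spec, 50.0))
        assert len(states) == 1
        assert states[0].active == frozenset({1})
        assert states[0].rates[1] == pytest.approx(220 / 36)

    @pytest.mark.parametrize("I_opto", [0.0, 10.0, 34.0 - 1e-6, 40.0, 120.0])
    def test_agrees_with_brute_force_on_fixtures(self, architectures, I_opto):
        for _, (spec, _, _) in architectures.items():
            problem = ob.balance_problem(spec, I_opto)
            got = {st.active for st in ob.consistent_states(problem)}
            expect = {a for a, _ in brute_force_states(problem.A, problem.c)}
            assert got == expect


class TestSweep:
    def test_two_pop_breakpoint_closed_form(self, architectures):
        # eliminating r_I gives r_E = (34 - I)/1.2: E silences exactly at I = 34
        spec, _, _ = architectures["two_pop"]
        grid = np.linspace(0.0, 60.0, 61)
        sweep = ob.sweep_opto(spec, I_grid=grid)
        assert len(sweep.breakpoints) == 1
        assert sweep.breakpoints[0] == pytest.approx(34.0, abs=1e-6)

    def test_two_pop_pv_minimum_at_breakpoint(self, architectures):
        # dr_I/dI = -29/36 before the breakpoint and +1/36 after
        spec, _, _ = architectures["two_pop"]
        grid = np.linspace(0.0, 60.0, 241)
        sweep = ob.sweep_opto(spec, I_grid=grid)
        i_I = spec.index("I")
        k_min = int(np.argmin(sweep.rates[:, i_I]))
        assert abs(grid[k_min] - 34.0) <= (grid[1] - grid[0])
        below = grid < 34
        slopes = np.diff(sweep.rates[below, i_I]) / np.diff(grid[below])
        assert slopes == pytest.approx(-29 / 36, abs=1e-9)
        above = grid > 34
        slopes_up = np.diff(sweep.rates[above, i_I]) / np.diff(grid[above])
        assert slopes_up == pytest.approx(1 / 36, abs=1e-9)

    def test_piecewise_linearity(self, architectures):
        for name in ("two_pop", "model1_paradox", "model2"):
            spec, _, _ = architectures[name]
            grid = np.linspace(0.0, 80.0, 161)
            sweep = ob.sweep_opto(spec, I_grid=grid)
            cuts = [grid[0], *sweep.breakpoints, grid[-1]]
            for lo, hi in zip(cuts[:-1], cuts[1:]):
                seg = (grid > lo + 1e-9) & (grid < hi - 1e-9)
                if seg.sum() < 3:
                    continue
                x = grid[seg]
                for p in range(spec.n_pop):
                    y = sweep.rates[seg, p]
                    fit = np.polyval(np.polyfit(x, y, 1), x)
                    assert np.abs(fit - y).max() <= 1e-9

    def test_model1_normalized_E_V_identical(self, architectures):
        # balance of PC and VIP inputs onto SOM forces r_V proportional to r_E
        for name in ("model1_nonparadox", "model1_paradox"):
            spec, _, _ = architectures[name]
            grid = np.linspace(0.0, 30.0, 31)
            sweep = ob.sweep_opto(spec, I_grid=grid)
            all_active = [s == frozenset(range(4)) for s in sweep.active_sets]
            nE, nV = sweep.normalized[:, spec.index("E")], sweep.normalized[:, spec.index("V")]
            assert np.abs(nE[all_active] - nV[all_active]).max() <= 1e-9

    def test_model2_rI_over_rE_constant(self, architectures):
        spec, _, _ = architectures["model2"]
        grid = np.linspace(0.0, 60.0, 61)
        sweep = ob.sweep_opto(spec, I_grid=grid)
        s_active = [spec.index("S") in s for s in sweep.active_sets]
        ratio = sweep.rates[s_active, spec.index("I")] / sweep.rates[s_active, spec.index("E")]
        assert ratio == pytest.approx(26 / 12, abs=1e-9)

    def test_model1_nonparadox_pv_rises_others_fall(self, architectures):
        spec, _, _ = architectures["model1_nonparadox"]
        sweep = ob.sweep_opto(spec, I_grid=np.array([0.0, 5.0]))
        d = sweep.rates[1] - sweep.rates[0]
        assert d[spec.index("I")] > 0
        assert all(d[spec.index(n)] < 0 for n in ("E", "S", "V"))

    def test_model1_paradox_pv_falls(self, architectures):
        spec, _, _ = architectures["model1_paradox"]
        sweep = ob.sweep_opto(spec, I_grid=np.array([0.0, 5.0]))
        assert sweep.rates[1, spec.index("I")] < sweep.rates[0, spec.index("I")]

    def test_gamma_grid_maps_through_photocurrent(self, architectures):
        spec, _, opto = architectures["two_pop"]
        sweep = ob.sweep_opto(spec, Gamma_grid=np.array([0.0, 0.5]), opto=opto)
        assert sweep.I_opto[1] == pytest.approx(8 * math.log(2))
        assert sweep.normalized[0] == pytest.approx([1.0, 1.0])


class TestSusceptibility:
    def test_no_recurrent_excitation_pins_pv(self, architectures):
        spec, _, _ = architectures["two_pop_noEE"]
        chi = ob.susceptibility(spec)
        assert chi[1, 1] == pytest.approx(0.0, abs=1e-15)

    def test_chi_II_signs_for_model1(self, architectures):
        non, _, _ = architectures["model1_nonparadox"]
        par, _, _ = architectures["model1_paradox"]
        i = non.index("I")
        assert ob.susceptibility(non)[i, i] > 0
        assert ob.susceptibility(par)[i, i] < 0

    def test_chiEI_chiIE_product_positive_when_nonparadoxical(self, architectures):
        spec, _, _ = architectures["model1_nonparadox"]
        chi = ob.susceptibility(spec)
        e, i = spec.index("E"), spec.index("I")
        assert chi[e, i] * chi[i, e] > 0

    def test_matches_finite_difference(self, architectures):
        rng = np.random.default_rng(42)
        specs = [architectures[n][0] for n in ob.FIXTURE_NAMES]
        cases = [jittered(specs[k % len(specs)], rng) for k in range(100)]
        h = 1e-6
        for spec in cases:
            chi = ob.susceptibility(spec)
            for b in range(spec.n_pop):
                I = np.zeros(spec.n_pop)
                I[b] = h
                r_plus = ob.solve_balance(ob.balance_problem(spec, I), range(spec.n_pop)).rates
                I[b] = -h
                r_minus = ob.solve_balance(ob.balance_problem(spec, I), range(spec.n_pop)).rates
                fd = (r_plus - r_minus) / (2 * h)
                denom = max(1.0, np.abs(chi[:, b]).max())
                assert np.abs(fd - chi[:, b]).max() / denom <= 1e-6

    def test_silent_rows_and_columns_zero(self, architectures):
        spec, _, _ = architectures["model2"]
        chi = ob.susceptibility(spec, active=[0, 1, 3])
        s = spec.index("S")
        assert np.all(chi[s, :] == 0) and np.all(chi[:, s] == 0)


class TestParadoxAudit:
    def test_model1_jee_star_values(self, architectures):
        non = ob.paradox_audit(architectures["model1_nonparadox"][0])
        assert non["jee_star"] == pytest.approx(12 * 41 / 35, abs=1e-9)  # ~14.06
        assert non["model1_paradox"] is False
        par = ob.paradox_audit(architectures["model1_paradox"][0])
        assert par["jee_star"] == pytest.approx(31.2 * 32.8 / 14.6, abs=1e-9)  # ~70.09
        assert par["model1_paradox"] is True

    def test_model2_loop_inequalities(self, architectures):
        audit = ob.paradox_audit(architectures["model2"][0])
        assert audit["model2_loop_criteria"] == {"paradox": True, "ff_monotonic": True}
        assert audit["margins"]["loop_minus_direct"] == pytest.approx(36 * 36 - 22 * 32)
        assert audit["margins"]["ff_loop_minus_direct"] == pytest.approx(32 * 36 - 22 * 16)

    def test_two_pop_criterion(self, architectures):
        assert ob.paradox_audit(architectures["two_pop"][0])["two_pop_criterion"] is True
        assert ob.paradox_audit(architectures["two_pop_noEE"][0])["two_pop_criterion"] is False

    def test_boolean_matches_chi_sign_on_fixtures_and_jitters(self, architectures):
        for name, (spec, _, _) in architectures.items():
            audit = ob.paradox_audit(spec)
            assert audit["warnings"] == [], name
            if name == "two_pop_noEE":
                # chi_II is exactly zero here; the criterion reads "not paradoxical"
                assert audit["paradoxical"] is False
            else:
                assert audit["paradoxical"] == (audit["chi_II"] < 0)
        # +-10% interaction jitters of the three four-population tables
        rng = np.random.default_rng(7)
        for name in ("model1_nonparadox", "model1_paradox", "model2"):
            spec, _, _ = architectures[name]
            for k in range(100):
                audit = ob.paradox_audit(jittered(spec, rng))
                assert audit["warnings"] == [], (name, k)
                assert audit["paradoxical"] == (audit["chi_II"] < 0)

    def test_generic_topology_falls_back_to_chi(self, architectures):
        spec, _, _ = architectures["model2"]
        generic = dataclasses.replace(spec, topology="custom")
        audit = ob.paradox_audit(generic)
        assert audit["warnings"] and audit["paradoxical"] is True


class TestStability:
    def test_two_pop_determinant(self, architectures):
        out = ob.stability_check(architectures["two_pop"][0])
        assert out["det"] == pytest.approx(36.0)
        assert out["necessary_ok"]

    def test_model1_nonparadox_determinant(self, architectures):
        out = ob.stability_check(architectures["model1_nonparadox"][0])
        assert out["det"] == pytest.approx(2.08e5, rel=2e-3)

    def test_missing_inhibition_flagged(self, architectures):
        spec, _, _ = architectures["two_pop"]
        mod = spec.with_J(np.array([[29.0, 0.0], [36.0, 36.0]]))
        out = ob.stability_check(mod)
        assert out["det"] == pytest.approx(-1044.0)
        assert not out["necessary_ok"]


class TestProportionality:
    def test_model1_ratio(self, architectures):
        out = ob.proportionality_ratio(architectures["model1_nonparadox"][0])
        assert out["pair"] == ("E", "V")
        assert out["ratio"] == pytest.approx(24 / 14)

    def test_model2_ratio(self, architectures):
        out = ob.proportionality_ratio(architectures["model2"][0])
        assert out["pair"] == ("E", "I")
        assert out["ratio"] == pytest.approx(26 / 12)

    def test_ratio_not_applicable_when_som_silent(self, architectures):
        spec, _, _ = architectures["model2"]
        st = ob.solve_balance(ob.balance_problem(spec), [0, 1, 3])
        out = ob.proportionality_ratio(spec, state=st)
        assert out["applicable"] is False

    def test_three_population_circuit_never_paradoxical(self):
        """With SOM fed only by PC and PV, chi_II = -J_ES J_SE / det(A), and
        every rate-stable draw (det(-A) > 0, positive all-active rates) has
        chi_II >= 0: the disinhibitory loop needed for the paradoxical effect
        is missing."""
        rng = np.random.default_rng(2024)
        pops = (PopulationLabel("E", 1), PopulationLabel("I", -1), PopulationLabel("S", -1))
        checked = 0
        while checked < 1000:
            J = rng.uniform(5.0, 45.0, (3, 3))
            J[2, 2] = 0.0  # no SOM-SOM coupling
            J0 = np.array([rng.uniform(5, 45), rng.uniform(5, 45), 0.0])
            spec = CircuitSpec(populations=pops, J=J, J0=J0,
                               tau=np.where(J > 0, 2.0, np.nan),
                               neuron=tuple(NeuronParams() for _ in range(3)))
            A = ob.effective_matrix(spec)
            if np.linalg.det(-A) <= 0:
                continue
            st = ob.solve_balance(ob.balance_problem(spec, 0.0), range(3))
            if not (st.consistent and np.all(st.rates > 0)):
                continue
            chi = ob.susceptibility(spec)
            assert chi[1, 1] >= 0
            checked += 1
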