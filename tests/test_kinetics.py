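"""RRE construction, integration formalisms, pruning, and chunking."""

from collections import Counter

import numpy as np
import pytest
from scipy.integrate import quad

from crnkit.chemgraph import Species
from crnkit.conditions import (
    ConditionSet,
    DoubleRampGradientProfile,
    FixedProfile,
    LinearDirectProfile,
    solve_profiles,
)
from crnkit.fixtures import (
    arrhenius_ab_toy,
    make_ab_toy,
    make_toy_reversible_5species,
)
from crnkit.kinetics import (
    FLOAT64_TIME_EPS,
    RREError,
    SimulationParams,
    build_rre,
    global_to_local_stops,
    prune_slow,
    solve_chunked,
    solve_continuous,
    solve_discrete,
)
from crnkit.network import ReactionNetwork
from crnkit.rates import ArrheniusParams, StaticCalculator, arrhenius_k
from crnkit.sampler import Reaction


def _abstract(name, comp):
    return Species(canonical_id=name, element_counts=comp)


def _linear_net():
    """A -> B (unimolecular) with same composition."""
    A = _abstract("A", {"X": 1})
    B = _abstract("B", {"X": 1})
    net = ReactionNetwork()
    net.add_reaction(Reaction(Counter([A]), Counter([B])))
    return net


FIXED_T = ConditionSet({"T": FixedProfile(300.0)}, t_end=10.0, tau_r=1.0)


class TestBuildRRE:
    def test_single_reaction_rhs_and_jacobian(self):
        rre = build_rre(_linear_net())
        c = np.array([2.0, 0.5])
        k = np.array([3.0])
        np.testing.assert_allclose(rre.rhs(c, k), [-6.0, 6.0])
        np.testing.assert_allclose(rre.jacobian(c, k), [[-3.0, 0.0], [3.0, 0.0]])

    def test_dimerization_stoichiometric_factor(self):
        # A + A -> B: dA/dt = -2 k A^2
        A = _abstract("A", {"X": 1})
        B = _abstract("B", {"X": 2})
        net = ReactionNetwork()
        net.add_reaction(Reaction(Counter({A: 2}), Counter([B])))
        rre = build_rre(net)
        c = np.array([3.0, 0.0])
        k = np.array([0.7])
        dc = rre.rhs(c, k)
        assert dc[0] == pytest.approx(-2 * 0.7 * 9.0)
        assert dc[1] == pytest.approx(+0.7 * 9.0)

    def test_jacobian_matches_finite_differences(self):
        net, calc = make_toy_reversible_5species()
        rre = build_rre(net)
        rng = np.random.default_rng(4)
        c = rng.uniform(0.1, 1.0, size=rre.n_species)
        k = calc.k
        jac = rre.jacobian(c, k)
        h = 1e-6
        fd = np.zeros_like(jac)
        for m in range(rre.n_species):
            cp, cm_ = c.copy(), c.copy()
            cp[m] += h
            cm_[m] -= h
            fd[:, m] = (rre.rhs(cp, k) - rre.rhs(cm_, k)) / (2 * h)
        assert np.max(np.abs(jac - fd)) < 1e-6

    def test_unknown_species_rejected(self):
        net = _linear_net()
        net.reactions.append(
            Reaction(
                Counter([_abstract("Z", {"X": 1})]),
                Counter([_abstract("A", {"X": 1})]),
            )
        )
        with pytest.raises(RREError):
            build_rre(net)


class TestContinuous:
    def test_reversible_equilibrium_closed_form(self):
        net, calc = make_ab_toy(2.0, 1.0)
        sim = SimulationParams(t_end=20.0, c0={"A": 1.0}, formalism="continuous")
        sol = solve_continuous(build_rre(net), FIXED_T, calc, sim)
        f = sol.final()
        assert f["A"] == pytest.approx(1.0 / 3.0, abs=1e-6)
        assert f["B"] == pytest.approx(2.0 / 3.0, abs=1e-6)

    def test_fixed_conditions_match_closed_form_relaxation(self):
        k1, km1 = 2.0, 1.0
        net, calc = make_ab_toy(k1, km1)
        sim = SimulationParams(t_end=2.0, c0={"A": 1.0}, rtol=1e-10, atol=1e-13)
        sol = solve_continuous(build_rre(net), FIXED_T, calc, sim)
        c_eq = km1 / (k1 + km1)
        exact = c_eq + (1 - c_eq) * np.exp(-(k1 + km1) * sol.times)
        np.testing.assert_allclose(sol.trajectory("A"), exact, atol=1e-8)

    def test_linear_ramp_matches_quadrature_oracle(self):
        # irreversible A -> B with Arrhenius k under a linear T ramp:
        # c_A(t) = exp(-int_0^t k(T(t')) dt')
        net = _linear_net()
        params = ArrheniusParams(Ea=np.array([40e3]), A=np.array([1e4]))
        from crnkit.rates import ArrheniusCalculator

        calc = ArrheniusCalculator(params)
        prof = LinearDirectProfile(x_start=300.0, x_end=800.0, rate=50.0)
        cs = ConditionSet({"T": prof}, t_end=10.0)
        sim = SimulationParams(
            t_end=10.0, c0={"A": 1.0}, rtol=1e-11, atol=1e-14,
            formalism="continuous",
        )
        sol = solve_continuous(build_rre(net), cs, calc, sim)

        def k_of_t(t):
            return arrhenius_k(params, prof.function(t))[0]

        integral, _ = quad(k_of_t, 0.0, 10.0, limit=200)
        exact = np.exp(-integral)
        assert sol.final()["A"] == pytest.approx(exact, rel=1e-6)

    def test_steady_state_reached_under_fixed_conditions(self):
        net, calc = make_toy_reversible_5species()
        cs = ConditionSet({"T": FixedProfile(300.0)}, t_end=500.0)
        sim = SimulationParams(t_end=500.0, c0={"A": 1.0, "B": 0.8},
                               rtol=1e-10, atol=1e-14, formalism="continuous")
        rre = build_rre(net)
        sol = solve_continuous(rre, cs, calc, sim)
        c_final = sol.concentrations[-1]
        residual = np.max(np.abs(rre.rhs(c_final, calc.k)))
        assert residual < 1e-8 * c_final.max()


class TestDiscrete:
    def test_constant_conditions_match_continuous(self):
        net, calc = make_ab_toy(2.0, 1.0)
        rre = build_rre(net)
        sim = SimulationParams(t_end=10.0, c0={"A": 1.0}, rtol=1e-10, atol=1e-13)
        sol_c = solve_continuous(rre, FIXED_T, calc, sim)
        sol_d = solve_discrete(rre, FIXED_T, calc, sim)
        for s in ("A", "B"):
            assert sol_d.final()[s] == pytest.approx(sol_c.final()[s], abs=1e-8)

    def test_coarse_updates_relax_to_static_steady_states(self):
        # with very coarse tau_r, inter-stop dynamics are static kinetics:
        # each segment relaxes toward the equilibrium of its frozen k
        net, calc = arrhenius_ab_toy()
        prof = DoubleRampGradientProfile.from_plateaus(
            300.0, 70.0, 10.0, 5.0, -70.0, 10.0
        )
        cs = ConditionSet({"T": prof}, t_end=25.0, tau_r=12.5)
        sim = SimulationParams(t_end=25.0, c0={"A": 1.0})
        sol = solve_discrete(build_rre(net), cs, calc, sim)
        # late in the final segment, dc/dt under the frozen k must be tiny
        t_last = sol.times[-1]
        k_frozen = calc.rates({"T": float(sol.condition_traces["T"][-1])})
        seg_mask = sol.times > t_last - 1.0
        c_late = sol.concentrations[seg_mask][-1]
        rre = build_rre(net)
        assert np.max(np.abs(rre.rhs(c_late, k_frozen))) < 1e-3


class TestChunked:
    def test_single_chunk_equals_unchunked(self):
        net, calc = make_ab_toy()
        sim_a = SimulationParams(t_end=10.0, c0={"A": 1.0}, tau_c=10.0)
        sim_b = SimulationParams(t_end=10.0, c0={"A": 1.0}, tau_c=None)
        rre = build_rre(net)
        sol_a = solve_chunked(rre, FIXED_T, calc, sim_a)
        sol_b = solve_chunked(rre, FIXED_T, calc, sim_b)
        np.testing.assert_array_equal(sol_a.concentrations, sol_b.concentrations)

    def test_ten_chunks_match_unchunked(self):
        net, calc = arrhenius_ab_toy()
        prof = DoubleRampGradientProfile.from_plateaus(
            300.0, 70.0, 10.0, 5.0, -70.0, 10.0
        )
        rtol = 1e-8
        cs = ConditionSet({"T": prof}, t_end=25.0, tau_r=0.5)
        rre = build_rre(net)
        sol_1 = solve_chunked(rre, cs, calc,
                              SimulationParams(t_end=25.0, c0={"A": 1.0},
                                               rtol=rtol, tau_c=None))
        sol_10 = solve_chunked(rre, cs, calc,
                               SimulationParams(t_end=25.0, c0={"A": 1.0},
                                                rtol=rtol, tau_c=2.5))
        for s in ("A", "B"):
            a, b = sol_1.final()[s], sol_10.final()[s]
            assert abs(a - b) / max(abs(a), 1e-30) < 10 * rtol

    def test_global_to_local_stop_mapping(self):
        tau_c = 2.0
        stops = np.array([0.5, 2.0, 5.0, 5.5, 6.0])
        # chunk 2 spans (4, 6]: global 5.0 -> local 1.0, 5.5 -> 1.5, 6.0 -> 2.0
        np.testing.assert_allclose(
            global_to_local_stops(stops, 2, tau_c), [1.0, 1.5, 2.0]
        )
        # a stop at 2.5*tau_c lands in chunk 2 at local 0.5*tau_c
        np.testing.assert_allclose(
            global_to_local_stops(np.array([2.5 * tau_c]), 2, tau_c),
            [0.5 * tau_c],
        )

    def test_bookkeeping_identity(self):
        from crnkit.kinetics import ChunkState

        st = ChunkState(n_c=7, t_local=0.3, tau_c=1.5)
        assert st.t_global == pytest.approx(7 * 1.5 + 0.3, abs=0.0)


class TestPruning:
    def _net_with_slow_leak(self, k_slow):
        A = _abstract("A", {"X": 1})
        B = _abstract("B", {"X": 1})
        C = _abstract("C", {"X": 1})
        net = ReactionNetwork()
        net.add_reaction(Reaction(Counter([A]), Counter([B])))
        net.add_reaction(Reaction(Counter([B]), Counter([A])))
        net.add_reaction(Reaction(Counter([B]), Counter([C])))
        calc = StaticCalculator(np.array([2.0, 1.0, k_slow]))
        return net, calc

    def test_zero_rate_always_pruned(self):
        net, calc = self._net_with_slow_leak(0.0)
        sim = SimulationParams(t_end=10.0, c0={"A": 1.0}, c_max_prune=2.0)
        pruned = prune_slow(net, calc, solve_profiles(FIXED_T), sim)
        assert pruned.n_reactions == 2

    def test_threshold_boundary(self):
        rtol, t_end, c_max = 1e-8, 10.0, 2.0
        # k * c_max * t_end = 0.1 * rtol -> pruned
        net, calc = self._net_with_slow_leak(0.1 * rtol / (c_max * t_end))
        sim = SimulationParams(t_end=t_end, c0={"A": 1.0}, rtol=rtol,
                               c_max_prune=c_max)
        assert prune_slow(net, calc, solve_profiles(FIXED_T), sim).n_reactions == 2
        # at 10 * rtol -> retained
        net, calc = self._net_with_slow_leak(10 * rtol / (c_max * t_end))
        assert prune_slow(net, calc, solve_profiles(FIXED_T), sim).n_reactions == 3

    def test_pruned_solution_matches_full(self):
        rtol = 1e-8
        k_slow = 0.05 * rtol / (2.0 * 10.0)
        net, calc = self._net_with_slow_leak(k_slow)
        sim = SimulationParams(t_end=10.0, c0={"A": 1.0}, rtol=rtol,
                               atol=1e-14, c_max_prune=2.0)
        rre_full = build_rre(net)
        sol_full = solve_chunked(rre_full, FIXED_T, calc, sim)
        pruned = prune_slow(net, calc, solve_profiles(FIXED_T), sim)
        from crnkit.kinetics import slow_reaction_mask, subset_calculator

        keep = slow_reaction_mask(net, calc, solve_profiles(FIXED_T), sim)
        calc_p = subset_calculator(calc, keep)
        sol_p = solve_chunked(build_rre(pruned), FIXED_T, calc_p, sim)
        for s in ("A", "B"):
            a = sol_full.final()[s]
            b = sol_p.final()[s]
            assert abs(a - b) / max(abs(a), 1e-30) < 10 * rtol


class TestSolutionInvariants:
    def test_element_conservation_and_nonnegativity(self):
        net, calc = make_toy_reversible_5species()
        cs = ConditionSet({"T": FixedProfile(300.0)}, t_end=50.0, tau_r=5.0)
        sim = SimulationParams(t_end=50.0, c0={"A": 1.0, "B": 0.8})
        rre = build_rre(net)
        sol = solve_chunked(rre, cs, calc, sim)
        totals = np.array([rre.element_totals(c) for c in sol.concentrations])
        drift = np.abs(totals - totals[0]).max() / totals[0].max()
        assert drift < 1e-6
        assert sol.concentrations.min() >= -sim.atol

    def test_c_max_equals_grid_maximum(self):
        net, calc = make_ab_toy()
        sim = SimulationParams(t_end=10.0, c0={"A": 1.0})
        sol = solve_chunked(build_rre(net), FIXED_T, calc, sim)
        assert sol.c_max["A"] == sol.trajectory("A").max()
        assert sol.c_max["B"] == sol.trajectory("B").max()

    def test_float64_time_epsilon_constant(self):
        assert FLOAT64_TIME_EPS == 2.0 ** -53
        assert FLOAT64_TIME_EPS == np.finfo(np.float64).epsneg
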