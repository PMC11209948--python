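"""Direct and iterative CRN exploration: convergence, seeds, filtering."""

from collections import Counter

import numpy as np
import pytest

from crnkit.chemgraph import ChemSystem, Species, species_from_smiles, split_molecules
from crnkit.conditions import ConditionSet, FixedProfile
from crnkit.explore import (
    DirectExploreParams,
    ExploreDeps,
    IterativeExploreParams,
    RxFilter,
    SimulationDeps,
    apply_rxfilter,
    explore_direct,
    explore_iterative,
    select_seeds,
)
from crnkit.fixtures import h2_species, h_library
from crnkit.kinetics import KineticSolution, SimulationParams
from crnkit.moves import enumerate_applications, apply_move
from crnkit.network import ReactionNetwork
from crnkit.rates import ArrheniusCalculator, ArrheniusParams
from crnkit.sampler import Reaction, assemble_system, reaction_from_diff


def brute_force_network(init_species, lib, max_rounds=6):
    """Exhaustive enumeration oracle over the move space.

    Closes the reaction set over all unimolecular and bimolecular systems
    built from discovered species, applying every move at every valid slot
    assignment deterministically — no stochastic sampling involved.
    """
    from itertools import combinations_with_replacement

    from crnkit.chemgraph import connectivity_from_geometry

    net = ReactionNetwork()
    for sp in init_species:
        net.add_species(sp)
    for _ in range(max_rounds):
        added = False
        species_now = list(net.species)
        systems = [[s] for s in species_now] + [
            list(pair) for pair in combinations_with_replacement(species_now, 2)
        ]
        for mols in systems:
            system = ChemSystem(Counter(mols))
            geom = assemble_system(system, seed=0)
            cm = connectivity_from_geometry(geom)
            before = Counter(sp for sp, _ in split_molecules(cm, geom))
            for move in lib.moves:
                for app in enumerate_applications(
                    cm, geom.element_symbols, move
                ):
                    new_cm = apply_move(cm, geom.element_symbols, move, app)
                    after = Counter(sp for sp, _ in split_molecules(new_cm, geom))
                    try:
                        rxn = reaction_from_diff(before, after)
                    except Exception:
                        continue
                    if rxn is None:
                        continue
                    if net.add_reaction(rxn):
                        added = True
        if not added:
            break
    return net


def _flat_calc(net):
    Ea = np.zeros(net.n_reactions)
    A = np.ones(net.n_reactions)
    mol = np.array([sum(r.reactants.values()) for r in net.reactions])
    return ArrheniusCalculator(ArrheniusParams(Ea, A), molecularity=mol)


H2_DEPS_KWARGS = dict(skip_geometry=True)


class TestExploreDirect:
    def test_h2_converges_to_two_reactions(self, h2_system, hh_library):
        params = DirectExploreParams(radius=4, maxiters=50,
                                     rxn_convergence_threshold=3, rng_seed=0)
        res = explore_direct(h2_system, params,
                             ExploreDeps(library=hh_library, **H2_DEPS_KWARGS))
        assert res.converged
        assert res.network.n_reactions == 2
        assert res.network.n_species == 2
        smis = sorted(r.smiles() for r in res.network.reactions)
        assert smis == ["[H].[H]>>[H][H]", "[H][H]>>[H].[H]"]

    def test_convergence_sample_budget_arithmetic(self):
        params = DirectExploreParams(radius=100, parallel_runs=6,
                                     rxn_convergence_threshold=5)
        assert params.convergence_sample_budget == 3000

    def test_maxiters_one_flags_unconverged(self, h2_system, hh_library):
        params = DirectExploreParams(radius=2, maxiters=1,
                                     rxn_convergence_threshold=5, rng_seed=0)
        res = explore_direct(h2_system, params,
                             ExploreDeps(library=hh_library, **H2_DEPS_KWARGS))
        assert not res.converged
        assert res.iterations == 1

    def test_reproducible_under_seed(self, h2_system, hh_library):
        params = DirectExploreParams(radius=3, maxiters=20,
                                     rxn_convergence_threshold=2, rng_seed=7)
        deps = ExploreDeps(library=hh_library, **H2_DEPS_KWARGS)
        a = explore_direct(h2_system, params, deps)
        b = explore_direct(h2_system, params, deps)
        assert a.network.signature() == b.network.signature()
        assert a.new_reactions_per_iteration == b.new_reactions_per_iteration

    def test_matches_enumeration_oracle(self, h2_system, hh_library):
        params = DirectExploreParams(radius=4, maxiters=50,
                                     rxn_convergence_threshold=3, rng_seed=1)
        res = explore_direct(h2_system, params,
                             ExploreDeps(library=hh_library, **H2_DEPS_KWARGS))
        oracle = brute_force_network([h2_species()], hh_library)
        assert res.network.signature() == oracle.signature()


class TestSelectSeeds:
    def _solution(self, cmax):
        ids = list(cmax)
        times = np.array([0.0, 1.0])
        conc = np.vstack([np.zeros(len(ids)), [cmax[s] for s in ids]])
        return KineticSolution(times, conc, ids)

    def test_strict_threshold(self):
        sol = self._solution({"A": 0.05, "B": 0.01})
        assert select_seeds(sol, 0.02).ids == {"A"}

    def test_zero_cutoff_selects_all_nonzero(self):
        sol = self._solution({"A": 0.05, "B": 0.01, "C": 0.0})
        assert select_seeds(sol, 0.0).ids == {"A", "B"}

    def test_tie_at_cutoff_excluded(self):
        sol = self._solution({"A": 0.02, "B": 0.03})
        assert select_seeds(sol, 0.02).ids == {"B"}


class TestRxFilter:
    def _c5_reaction(self):
        pentane = species_from_smiles("CCCCC")
        radical = species_from_smiles("[CH2]CCCC")
        h = species_from_smiles("[H]")
        return Reaction(Counter([pentane]), Counter([radical, h]))

    def test_c5_product_removed_under_c4_cap(self):
        net = ReactionNetwork()
        net.add_reaction(self._c5_reaction())
        out = apply_rxfilter(net, RxFilter(max_carbon=4))
        assert out.n_reactions == 0

    def test_c5_consumer_also_removed(self):
        # closure: the filtered model must not reference a filtered species
        net = ReactionNetwork()
        rxn = self._c5_reaction()
        net.add_reaction(rxn)
        net.add_reaction(rxn.reverse())  # consumes the C5 species
        out = apply_rxfilter(net, RxFilter(max_carbon=4))
        assert out.n_reactions == 0
        assert out.n_species == 0

    def test_small_network_unchanged(self):
        ethane = species_from_smiles("CC")
        methyl = species_from_smiles("[CH3]")
        net = ReactionNetwork()
        net.add_reaction(Reaction(Counter([ethane]), Counter({methyl: 2})))
        out = apply_rxfilter(net, RxFilter(max_carbon=4))
        assert out.signature() == net.signature()

    def test_unfiltered_network_retains_provenance(self):
        net = ReactionNetwork()
        rxn = self._c5_reaction()
        net.add_reaction(rxn, level=3)
        apply_rxfilter(net, RxFilter(max_carbon=4))
        assert net.provenance[rxn.key] == {"level": 3}


class TestExploreIterative:
    def _sim_deps(self, t_end=5.0):
        cs = ConditionSet({"T": FixedProfile(1000.0)}, t_end=t_end, tau_r=1.0)
        sim = SimulationParams(t_end=t_end, c0={"[H][H]": 1.0})
        return SimulationDeps(conditions=cs, calculator_factory=_flat_calc,
                              sim=sim)

    def test_permissive_cutoff_matches_direct_and_oracle(self, h2_system,
                                                         hh_library):
        deps = ExploreDeps(library=hh_library, **H2_DEPS_KWARGS)
        iparams = IterativeExploreParams(
            c_select=1e-9, max_levels=8, rng_seed=3,
            rxn_convergence_threshold=3, filter=RxFilter(max_carbon=None),
        )
        ires = explore_iterative([h2_species()], iparams, deps,
                                 self._sim_deps())
        dparams = DirectExploreParams(radius=4, maxiters=50,
                                      rxn_convergence_threshold=3, rng_seed=3)
        dres = explore_direct(h2_system, dparams, deps)
        oracle = brute_force_network([h2_species()], hh_library)
        assert ires.converged
        assert ires.network.signature() == dres.network.signature()
        assert ires.network.signature() == oracle.signature()

    def test_unreachable_cutoff_terminates_with_warning(self, hh_library):
        deps = ExploreDeps(library=hh_library, **H2_DEPS_KWARGS)
        iparams = IterativeExploreParams(
            c_select=100.0, max_levels=5, rng_seed=0,
            rxn_convergence_threshold=2, filter=RxFilter(max_carbon=None),
        )
        res = explore_iterative([h2_species()], iparams, deps, self._sim_deps())
        assert not res.converged
        assert res.warning is not None
        assert len(res.levels) == 1

    def test_level_records_are_auditable(self, hh_library):
        deps = ExploreDeps(library=hh_library, **H2_DEPS_KWARGS)
        iparams = IterativeExploreParams(
            c_select=1e-9, max_levels=8, rng_seed=5,
            rxn_convergence_threshold=2, filter=RxFilter(max_carbon=None),
        )
        res = explore_iterative([h2_species()], iparams, deps, self._sim_deps())
        assert res.levels[0].seeds_in == frozenset({"[H][H]"})
        for rec in res.levels:
            assert rec.seeds_out <= {"[H][H]", "[H]"}
            assert set(rec.c_max) <= {"[H][H]", "[H]"}

    def test_monotone_growth_across_levels(self, hh_library):
        deps = ExploreDeps(library=hh_library, **H2_DEPS_KWARGS)
        iparams = IterativeExploreParams(
            c_select=1e-9, max_levels=6, rng_seed=2,
            rxn_convergence_threshold=2, filter=RxFilter(max_carbon=None),
        )
        res = explore_iterative([h2_species()], iparams, deps, self._sim_deps())
        # cumulative reaction count per level never decreases
        counts = []
        running = 0
        for rec in res.levels:
            running += rec.new_reactions
            counts.append(running)
        assert counts == sorted(counts)


class TestNetworkContainer:
    def test_deduplication_is_idempotent(self):
        ethane = species_from_smiles("CC")
        methyl = species_from_smiles("[CH3]")
        rxn = Reaction(Counter([ethane]), Counter({methyl: 2}))
        net = ReactionNetwork()
        assert net.add_reaction(rxn)
        sig = net.signature()
        assert not net.add_reaction(rxn)
        assert net.signature() == sig

    def test_serialization_round_trip(self, tmp_path):
        ethane = species_from_smiles("CC")
        methyl = species_from_smiles("[CH3]")
        net = ReactionNetwork()
        net.add_reaction(Reaction(Counter([ethane]), Counter({methyl: 2})),
                         level=1)
        p = tmp_path / "net.crn"
        net.dump(p)
        back = ReactionNetwork.load(p)
        assert back.signature() == net.signature()
        key = net.reactions[0].key
        assert back.provenance[key]["level"] == "1"
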