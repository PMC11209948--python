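"""CRN assembly: direct (brute-force) and iterative (kinetics-guided)
exploration, convergence accounting, seed selection and reaction filtering.

Direct exploration repeatedly runs the SE-GDS sampler from the initial
system and accumulates every discovered reaction (and its reverse, stored
as an independent directional reaction) until ``rxn_convergence_threshold``
consecutive iterations add nothing new.  Each iteration performs
``parallel_runs`` sampler executions of radius ``n_r``, so convergence
requires ``threshold * parallel_runs * n_r`` reactions to have been sampled
without any change to the network.

Iterative exploration grows the network level by level.  Each level samples
only reactions adjacent (radius 1) to the current seed system — the species
whose maximum simulated concentration exceeded ``c_select`` in the previous
level's kinetic simulation — then filters the cumulative network, simulates
it (discrete formalism), and selects the next seed system.  Exploration
converges when the seed system is unchanged for
``seed_convergence_threshold`` consecutive levels.  This keeps the network
compact by never expanding species that are not kinetically viable under
the experimental conditions of interest.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from itertools import combinations_with_replacement
from typing import Callable

import numpy as np

from .chemgraph import ChemSystem, Species
from .conditions import ConditionSet
from .grp import GRPParams, RefinerHook, identity_refiner
from .kinetics import KineticSolution, SimulationParams, build_rre, solve_chunked
from .moves import ForbiddenPatterns, MoveLibrary, ValenceConstraints
from .network import ReactionNetwork
from .rates import Calculator
from .sampler import Reaction, SamplerParams, extract_reactions, run_segds

logger = logging.getLogger(__name__)

__all__ = [
    "ReactionNetwork",
    "ExploreDeps",
    "DirectExploreParams",
    "IterativeExploreParams",
    "SimulationDeps",
    "RxFilter",
    "SeedSystem",
    "explore_direct",
    "explore_iterative",
    "select_seeds",
    "apply_rxfilter",
]


@dataclass
class ExploreDeps:
    """Sampler dependencies shared by both exploration algorithms."""

    library: MoveLibrary
    valence: ValenceConstraints = field(default_factory=ValenceConstraints)
    forbidden: ForbiddenPatterns | None = None
    refiner: RefinerHook = identity_refiner
    grp_params: GRPParams | None = None
    skip_geometry: bool = False


@dataclass
class DirectExploreParams:
    radius: int = 100                    # n_r per sampler run
    maxiters: int = 1000
    rxn_convergence_threshold: int = 5
    parallel_runs: int = 1
    rng_seed: int = 0
    max_attempts: int = 100

    def __post_init__(self) -> None:
        if min(self.radius, self.maxiters, self.rxn_convergence_threshold,
               self.parallel_runs) < 1:
            raise ValueError("all direct-exploration parameters must be >= 1")

    @property
    def convergence_sample_budget(self) -> int:
        """Reactions that must be sampled without change to declare convergence."""
        return self.rxn_convergence_threshold * self.parallel_runs * self.radius


@dataclass
class DirectExploreResult:
    network: ReactionNetwork
    converged: bool
    iterations: int
    samples_without_change: int
    new_reactions_per_iteration: list[int]


def explore_direct(
    init: ChemSystem,
    params: DirectExploreParams,
    deps: ExploreDeps,
) -> DirectExploreResult:
    """Brute-force CRN assembly from repeated SE-GDS runs.

    Terminates when ``maxiters`` is reached or when
    ``rxn_convergence_threshold`` consecutive iterations (each of
    ``parallel_runs`` sampler executions at radius ``radius``) add zero new
    reactions.  Every discovered reaction's reverse is registered as its own
    directional reaction.
    """
    if not init.species_multiset:
        raise ValueError("initial system is empty")
    net = ReactionNetwork()
    for sp in init.species_multiset:
        net.add_species(sp)

    no_change = 0
    samples_without_change = 0
    history: list[int] = []
    iteration = 0
    while iteration < params.maxiters and no_change < params.rxn_convergence_threshold:
        iteration += 1
        new_count = 0
        sampled = 0
        for run in range(params.parallel_runs):
            run_seed = int(
                np.random.SeedSequence(
                    [params.rng_seed, iteration, run]
                ).generate_state(1)[0] % (2**31)
            )
            sp = SamplerParams(
                n_r=params.radius,
                n_m=1,
                max_attempts=params.max_attempts,
                rng_seed=run_seed,
            )
            mechs = run_segds(
                init,
                deps.library,
                deps.valence,
                deps.forbidden,
                sp,
                deps.refiner,
                grp_params=deps.grp_params,
                skip_geometry=deps.skip_geometry,
            )
            for mech in mechs:
                for rxn in extract_reactions(mech):
                    sampled += 1
                    if net.add_reaction(rxn, iteration=iteration):
                        new_count += 1
                    if net.add_reaction(rxn.reverse(), iteration=iteration,
                                        reverse_of=rxn.smiles()):
                        new_count += 1
        history.append(new_count)
        if new_count == 0:
            no_change += 1
            samples_without_change += params.parallel_runs * params.radius
        else:
            no_change = 0
            samples_without_change = 0
        logger.info(
            "direct iteration %d: %d sampled, %d new (streak %d)",
            iteration, sampled, new_count, no_change,
        )
    converged = no_change >= params.rxn_convergence_threshold
    if not converged:
        logger.warning("direct exploration stopped unconverged at maxiters=%d",
                       params.maxiters)
    return DirectExploreResult(net, converged, iteration,
                               samples_without_change, history)


@dataclass(frozen=True)
class RxFilter:
    """Deterministic species predicate; default caps carbon count per species."""

    max_carbon: int | None = 4
    predicate: Callable[[Species], bool] | None = None

    def allows(self, sp: Species) -> bool:
        if self.predicate is not None and not self.predicate(sp):
            return False
        if self.max_carbon is not None and sp.count("C") > self.max_carbon:
            return False
        return True


@dataclass(frozen=True)
class SeedSystem:
    """Species selected as seeds for the next exploration level."""

    ids: frozenset[str]

    def __len__(self) -> int:
        return len(self.ids)


def select_seeds(solution: KineticSolution, c_select: float) -> SeedSystem:
    """Seed species: maximum concentration strictly greater than c_select."""
    cmax = solution.c_max
    return SeedSystem(frozenset(sid for sid, v in cmax.items() if v > c_select))


def apply_rxfilter(net: ReactionNetwork, filt: RxFilter) -> ReactionNetwork:
    """Simulated copy of a network with filtered reactions removed.

    A reaction is removed when any participant (product or reactant) fails
    the predicate — the filtered model must reference no filtered-out
    species.  Species left in no remaining reaction are dropped from the
    simulated network; the unfiltered network keeps them in provenance.
    """
    out = ReactionNetwork()
    kept: list[Reaction] = []
    for rxn in net.reactions:
        participants = list(rxn.reactants) + list(rxn.products)
        if all(filt.allows(sp) for sp in participants):
            kept.append(rxn)
    referenced = {sp for r in kept for sp in list(r.reactants) + list(r.products)}
    for sp in net.species:
        if sp in referenced:
            out.add_species(sp)
    for rxn in kept:
        out.add_reaction(rxn, **net.provenance.get(rxn.key, {}))
    return out


@dataclass
class IterativeExploreParams:
    c_select: float = 0.01               # mol dm^-3 seed cutoff
    seed_convergence_threshold: int = 2
    max_levels: int = 20
    level_maxiters: int = 200
    rxn_convergence_threshold: int = 5
    parallel_runs: int = 1
    rng_seed: int = 0
    max_attempts: int = 100
    filter: RxFilter = field(default_factory=RxFilter)

    def __post_init__(self) -> None:
        if self.c_select <= 0:
            raise ValueError("c_select must be positive")
        if min(self.seed_convergence_threshold, self.max_levels) < 1:
            raise ValueError("thresholds must be >= 1")


@dataclass
class SimulationDeps:
    """Kinetic-simulation dependencies for iterative exploration."""

    conditions: ConditionSet
    calculator_factory: Callable[[ReactionNetwork], Calculator]
    sim: SimulationParams


@dataclass
class LevelRecord:
    level: int
    seeds_in: frozenset[str]
    new_reactions: int
    seeds_out: frozenset[str]
    c_max: dict[str, float]


@dataclass
class IterativeExploreResult:
    network: ReactionNetwork
    simulated_network: ReactionNetwork
    converged: bool
    levels: list[LevelRecord]
    warning: str | None = None


def _sample_level(
    seed_species: list[Species],
    net: ReactionNetwork,
    params: IterativeExploreParams,
    deps: ExploreDeps,
    level: int,
) -> int:
    """Sample radius-1 reactions adjacent to the seed system to convergence.

    Adjacency covers unimolecular applications on each seed and bimolecular
    applications on each unordered seed pair, including self-pairs.
    """
    systems = [ChemSystem(Counter([s])) for s in seed_species]
    systems += [
        ChemSystem(Counter([a, b]))
        for a, b in combinations_with_replacement(seed_species, 2)
    ]
    new_total = 0
    no_change = 0
    iteration = 0
    while iteration < params.level_maxiters and no_change < params.rxn_convergence_threshold:
        iteration += 1
        new_count = 0
        for si, system in enumerate(systems):
            for run in range(params.parallel_runs):
                run_seed = int(
                    np.random.SeedSequence(
                        [params.rng_seed, level, iteration, si, run]
                    ).generate_state(1)[0] % (2**31)
                )
                sp = SamplerParams(n_r=1, n_m=1, max_attempts=params.max_attempts,
                                   rng_seed=run_seed)
                mechs = run_segds(
                    system, deps.library, deps.valence, deps.forbidden, sp,
                    deps.refiner, grp_params=deps.grp_params,
                    skip_geometry=deps.skip_geometry,
                )
                for mech in mechs:
                    for rxn in extract_reactions(mech):
                        if net.add_reaction(rxn, level=level, iteration=iteration):
                            new_count += 1
                        if net.add_reaction(rxn.reverse(), level=level,
                                            iteration=iteration,
                                            reverse_of=rxn.smiles()):
                            new_count += 1
        no_change = no_change + 1 if new_count == 0 else 0
        new_total += new_count
    return new_total


def explore_iterative(
    init_species: list[Species],
    params: IterativeExploreParams,
    deps: ExploreDeps,
    sim_deps: SimulationDeps,
) -> IterativeExploreResult:
    """Kinetics-guided iterative CRN growth.

    Per level: sample radius-1 reactions from the seed system until level
    convergence; filter the cumulative network; simulate it under the
    supplied conditions (discrete formalism); select the next seed system
    as the species with ``c_max > c_select``.  Terminates on seed-system
    stability, ``max_levels``, or an empty seed set (with a warning — an
    empty seed system means every species fell below the cutoff and
    further exploration would be blind).
    """
    if not init_species:
        raise ValueError("initial species list is empty")
    net = ReactionNetwork()
    for sp in init_species:
        net.add_species(sp)
    species_by_id = {sp.canonical_id: sp for sp in init_species}

    seeds = frozenset(sp.canonical_id for sp in init_species)
    records: list[LevelRecord] = []
    unchanged = 0
    converged = False
    warning: str | None = None
    simnet = net

    for level in range(1, params.max_levels + 1):
        seed_species = [species_by_id[sid] for sid in sorted(seeds)]
        new_reactions = _sample_level(seed_species, net, params, deps, level)
        species_by_id.update({sp.canonical_id: sp for sp in net.species})

        simnet = apply_rxfilter(net, params.filter)
        if simnet.n_reactions == 0:
            warning = "no simulatable reactions at level %d" % level
            logger.warning(warning)
            records.append(LevelRecord(level, seeds, new_reactions, frozenset(), {}))
            break
        calc = sim_deps.calculator_factory(simnet)
        sim = SimulationParams(
            t_end=sim_deps.sim.t_end,
            c0={k: v for k, v in sim_deps.sim.c0.items()
                if k in {s.canonical_id for s in simnet.species}},
            rtol=sim_deps.sim.rtol,
            atol=sim_deps.sim.atol,
            formalism="discrete",
            tau_c=sim_deps.sim.tau_c,
            solver=sim_deps.sim.solver,
            n_out=sim_deps.sim.n_out,
        )
        rre = build_rre(simnet)
        sol = solve_chunked(rre, sim_deps.conditions, calc, sim)
        new_seed_system = select_seeds(sol, params.c_select)
        new_seeds = new_seed_system.ids
        records.append(LevelRecord(level, seeds, new_reactions, new_seeds, sol.c_max))
        logger.info("level %d: %d new reactions, %d seeds", level,
                    new_reactions, len(new_seeds))

        if not new_seeds:
            warning = (
                "empty seed system: every species' c_max fell below c_select; "
                "network is likely under-explored"
            )
            logger.warning(warning)
            break
        if new_seeds == seeds:
            unchanged += 1
            if unchanged >= params.seed_convergence_threshold:
                converged = True
                break
        else:
            unchanged = 0
        seeds = new_seeds

    return IterativeExploreResult(net, simnet, converged, records, warning)
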