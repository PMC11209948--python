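"""Mass-action reaction-rate equations and their integration under
variable conditions.

A reaction network is compiled into a sparse-stoichiometry RRE system

    dc_s/dt = sum_i (nu+_is - nu-_is) * k_i * prod_j c_j^(nu-_ij)

with an analytic Jacobian whose sparsity follows the stoichiometric
couplings.  Two rate-update formalisms are provided:

* continuous — the rate vector ``k(conditions(t))`` is re-evaluated inside
  the right-hand side at every integrator step;
* discrete — rate constants are precalculated on the stop grid ``t_stops``
  (spacing ``tau_r`` over intervals where conditions vary) and swapped in
  at each stop, with the solver forced to land exactly on every stop so
  that no step straddles a parameter discontinuity.

Long runs can additionally be split into chunks of length ``tau_c``:
within each chunk the solver works in local time ``t_local in [0, tau_c]``
and global time is reconstructed as ``t_global = n_c * tau_c + t_local``.
Accumulating small steps against the small local time instead of the large
global time avoids the floating-point underflow floor ``t_global * eps``
(eps = 2^-53 for IEEE doubles) that otherwise stalls fast-reaction
integration at long time scales.

Slow reactions whose maximum possible concentration increment over the
whole run falls below solver precision can be pruned before compilation:
reaction i is removed iff ``k_i^max * c_max^order * t_end < rtol``,
where ``k_i^max`` is evaluated at the most favorable condition values
attained over the profiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.integrate import solve_ivp

from .conditions import ConditionSet, ConditionSolution, make_tstops, solve_profiles
from .network import ReactionNetwork
from .rates import Calculator, RateMatrix, check_conditions, precalculate_rates

#: Unit roundoff of IEEE 64-bit floats: the smallest relative time increment
#: representable when accumulating steps against a global simulation time.
FLOAT64_TIME_EPS = 2.0 ** -53


class RREError(ValueError):
    pass


class IntegrationError(RuntimeError):
    pass


@dataclass
class RRESystem:
    """Stoichiometric mass-action ODE system with parametric rate slots."""

    species_ids: list[str]
    nu_minus: np.ndarray      # (n_reactions, n_species) reactant stoichiometry
    nu_plus: np.ndarray       # product stoichiometry
    element_matrix: np.ndarray  # (n_elements, n_species) for conservation checks
    elements: list[str]

    def __post_init__(self) -> None:
        self.nu_minus = np.asarray(self.nu_minus, dtype=int)
        self.nu_plus = np.asarray(self.nu_plus, dtype=int)
        if np.any(self.nu_minus < 0) or np.any(self.nu_plus < 0):
            raise RREError("stoichiometries must be non-negative")
        if np.any(self.nu_minus.sum(axis=1) > 2):
            raise RREError("reactant molecularity above 2")
        self.net_stoich = (self.nu_plus - self.nu_minus).astype(float)

    @property
    def n_species(self) -> int:
        return len(self.species_ids)

    @property
    def n_reactions(self) -> int:
        return self.nu_minus.shape[0]

    @property
    def reaction_order(self) -> np.ndarray:
        return self.nu_minus.sum(axis=1)

    def rate_vector(self, c: np.ndarray, k: np.ndarray) -> np.ndarray:
        """Per-reaction mass-action rates k_i * prod_j c_j^nu-_ij."""
        cpos = np.maximum(c, 0.0)
        # prod over species with nonzero nu_minus; nu entries are 0,1,2
        prod = np.ones(self.n_reactions)
        rows, cols = np.nonzero(self.nu_minus)
        for i, j in zip(rows, cols):
            prod[i] *= cpos[j] ** self.nu_minus[i, j]
        return k * prod

    def rhs(self, c: np.ndarray, k: np.ndarray) -> np.ndarray:
        return self.net_stoich.T @ self.rate_vector(c, k)

    def jacobian(self, c: np.ndarray, k: np.ndarray) -> np.ndarray:
        """Analytic d(dc/dt)/dc with the exact stoichiometric sparsity."""
        cpos = np.maximum(c, 0.0)
        n_r, n_s = self.nu_minus.shape
        drate = np.zeros((n_r, n_s))
        rows, cols = np.nonzero(self.nu_minus)
        rate_base = self.rate_vector(cpos, k)
        for i, m in zip(rows, cols):
            order = self.nu_minus[i, m]
            # d/dc_m of k * prod c^nu: handle c_m = 0 without 0/0
            prod = k[i]
            for j in np.nonzero(self.nu_minus[i])[0]:
                nu = self.nu_minus[i, j]
                if j == m:
                    prod *= order * cpos[j] ** (nu - 1)
                else:
                    prod *= cpos[j] ** nu
            drate[i, m] = prod
        return self.net_stoich.T @ drate

    def element_totals(self, c: np.ndarray) -> np.ndarray:
        return self.element_matrix @ np.maximum(c, 0.0)


def build_rre(net: ReactionNetwork) -> RRESystem:
    """Compile a deduplicated network into a mass-action RRE system."""
    index = net.species_index()
    n_s = net.n_species
    n_r = net.n_reactions
    nu_minus = np.zeros((n_r, n_s), dtype=int)
    nu_plus = np.zeros((n_r, n_s), dtype=int)
    for i, rxn in enumerate(net.reactions):
        for sp, n in rxn.reactants.items():
            if sp.canonical_id not in index:
                raise RREError(f"reaction references unknown species {sp.canonical_id}")
            nu_minus[i, index[sp.canonical_id]] = n
        for sp, n in rxn.products.items():
            if sp.canonical_id not in index:
                raise RREError(f"reaction references unknown species {sp.canonical_id}")
            nu_plus[i, index[sp.canonical_id]] = n
    elements = sorted({el for s in net.species for el in s.element_counts})
    emat = np.zeros((len(elements), n_s))
    for j, s in enumerate(net.species):
        for ei, el in enumerate(elements):
            emat[ei, j] = s.count(el)
    return RRESystem(
        species_ids=[s.canonical_id for s in net.species],
        nu_minus=nu_minus,
        nu_plus=nu_plus,
        element_matrix=emat,
        elements=elements,
    )


@dataclass
class SimulationParams:
    t_end: float
    c0: dict[str, float]
    rtol: float = 1e-8
    atol: float = 1e-12
    formalism: Literal["continuous", "discrete"] = "discrete"
    tau_c: float | None = None          # chunk length; None = unchunked
    c_max_prune: float | None = None    # pruning concentration bound
    solver: str = "BDF"
    n_out: int = 401                    # output grid points per solve

    def __post_init__(self) -> None:
        if self.t_end <= 0:
            raise ValueError("t_end must be positive")
        if any(v < 0 for v in self.c0.values()):
            raise ValueError("initial concentrations must be non-negative")
        if self.rtol <= 0:
            raise ValueError("rtol must be positive")
        if self.tau_c is not None and self.tau_c <= 0:
            raise ValueError("tau_c must be positive when chunking is enabled")


@dataclass
class ChunkState:
    """Bookkeeping for chunked time accumulation: t_global = n_c*tau_c + t_local."""

    n_c: int = 0
    t_local: float = 0.0
    tau_c: float = 0.0

    @property
    def t_global(self) -> float:
        return self.n_c * self.tau_c + self.t_local


def global_to_local_stops(
    t_stops: np.ndarray, n_c: int, tau_c: float
) -> np.ndarray:
    """Map global stop times falling inside chunk ``n_c`` onto local time.

    A global stop t maps to ``t - n_c * tau_c`` when it lies within
    ``(n_c * tau_c, (n_c + 1) * tau_c]``.
    """
    t_stops = np.asarray(t_stops, dtype=float)
    lo = n_c * tau_c
    hi = (n_c + 1) * tau_c
    sel = (t_stops > lo) & (t_stops <= hi)
    return t_stops[sel] - lo


@dataclass
class KineticSolution:
    """Time grid, concentration trajectories, condition traces, c_max."""

    times: np.ndarray
    concentrations: np.ndarray           # (n_times, n_species)
    species_ids: list[str]
    condition_traces: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        if self.concentrations.shape[0] != self.times.shape[0]:
            raise ValueError("trajectory length mismatch")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("time grid must be strictly increasing")

    @property
    def c_max(self) -> dict[str, float]:
        """Per-species maximum concentration over the output grid."""
        return {
            sid: float(self.concentrations[:, j].max())
            for j, sid in enumerate(self.species_ids)
        }

    def final(self) -> dict[str, float]:
        return {
            sid: float(self.concentrations[-1, j])
            for j, sid in enumerate(self.species_ids)
        }

    def trajectory(self, species_id: str) -> np.ndarray:
        j = self.species_ids.index(species_id)
        return self.concentrations[:, j]


def _c0_vector(rre: RRESystem, sim: SimulationParams) -> np.ndarray:
    c0 = np.zeros(rre.n_species)
    for sid, v in sim.c0.items():
        if sid not in rre.species_ids:
            raise RREError(f"initial concentration for unknown species {sid!r}")
        c0[rre.species_ids.index(sid)] = v
    return c0


def _integrate_segment(
    rre: RRESystem,
    c_start: np.ndarray,
    t0: float,
    t1: float,
    k_of_t,
    jac_of_t,
    sim: SimulationParams,
    t_eval: np.ndarray | None = None,
):
    sol = solve_ivp(
        lambda t, c: rre.rhs(c, k_of_t(t)),
        (t0, t1),
        c_start,
        method=sim.solver,
        jac=lambda t, c: rre.jacobian(c, k_of_t(t)),
        rtol=sim.rtol,
        atol=sim.atol,
        t_eval=t_eval,
        dense_output=t_eval is None,
    )
    if not sol.success:
        raise IntegrationError(
            f"integration failed on [{t0}, {t1}] with {sim.solver}: {sol.message} "
            f"(stiffness or step-size failure; consider a smaller rtol or BDF)"
        )
    return sol


def solve_continuous(
    rre: RRESystem,
    cs: ConditionSet,
    calc: Calculator,
    sim: SimulationParams,
    csol: ConditionSolution | None = None,
) -> KineticSolution:
    """Continuous formalism: k(conditions(t)) evaluated at every RHS call."""
    check_conditions(calc, cs.names())
    csol = csol or solve_profiles(cs)
    c0 = _c0_vector(rre, sim)
    t_eval = np.linspace(0.0, sim.t_end, sim.n_out)

    def k_of_t(t: float) -> np.ndarray:
        return calc.rates(csol.at(t))

    sol = _integrate_segment(rre, c0, 0.0, sim.t_end, k_of_t, None, sim, t_eval)
    traces = {
        name: np.array([csol(name, t) for t in sol.t]) for name in cs.names()
    }
    return KineticSolution(sol.t, sol.y.T, list(rre.species_ids), traces)


def solve_discrete(
    rre: RRESystem,
    cs: ConditionSet,
    calc: Calculator,
    sim: SimulationParams,
    csol: ConditionSolution | None = None,
    rate_matrix: RateMatrix | None = None,
) -> KineticSolution:
    """Discrete formalism: piecewise-static kinetics between rate-update stops.

    Rate constants are precalculated at every global stop; integration
    proceeds segment by segment, swapping in the stop's column of
    ``K_precalc`` and reinitializing the solver at each discontinuity.
    """
    check_conditions(calc, cs.names())
    csol = csol or solve_profiles(cs)
    if rate_matrix is None:
        t_stops = make_tstops(cs)
        rate_matrix = precalculate_rates(calc, csol, t_stops)
    t_stops = rate_matrix.t_stops

    c0 = _c0_vector(rre, sim)
    # segment boundaries: 0, all interior stops, t_end
    bounds = np.concatenate(([0.0], t_stops[(t_stops > 0) & (t_stops < sim.t_end)], [sim.t_end]))
    bounds = np.unique(bounds)

    # rate vector on each segment: the column of the most recent stop at or
    # before the segment start (conditions at t=0 if no stop has passed yet)
    k0 = calc.rates(csol.at(0.0))

    def k_for_segment(t_seg_start: float) -> np.ndarray:
        idx = np.searchsorted(t_stops, t_seg_start + 1e-15 * max(1.0, sim.t_end)) - 1
        if idx < 0:
            return k0
        return rate_matrix.column(idx)

    times = [np.array([0.0])]
    concs = [c0[None, :]]
    c = c0
    n_out_per = max(2, int(np.ceil(sim.n_out * 1.0 / max(1, len(bounds) - 1))) + 1)
    for a, b in zip(bounds[:-1], bounds[1:]):
        k_seg = k_for_segment(a)
        t_eval = np.linspace(a, b, n_out_per)
        sol = _integrate_segment(
            rre, c, a, b, lambda t, kk=k_seg: kk, None, sim, t_eval
        )
        c = sol.y[:, -1]
        times.append(sol.t[1:])
        concs.append(sol.y.T[1:])
    t_all = np.concatenate(times)
    c_all = np.vstack(concs)
    keep = np.concatenate(([True], np.diff(t_all) > 0))
    t_all, c_all = t_all[keep], c_all[keep]
    traces = {name: np.array([csol(name, t) for t in t_all]) for name in cs.names()}
    return KineticSolution(t_all, c_all, list(rre.species_ids), traces)


def solve_chunked(
    rre: RRESystem,
    cs: ConditionSet,
    calc: Calculator,
    sim: SimulationParams,
) -> KineticSolution:
    """Chunked time accumulation wrapped around the selected inner formalism.

    Each chunk restarts the inner solver at local time zero from the
    previous chunk's final concentrations; global stop times are converted
    into local ones before each inner solve.  With ``tau_c`` unset or equal
    to ``t_end`` this reduces to a single inner call.
    """
    if sim.tau_c is None or sim.tau_c >= sim.t_end:
        return _solve_inner(rre, cs, calc, sim)

    csol = solve_profiles(cs)
    tau_c = sim.tau_c
    n_chunks = int(np.ceil(sim.t_end / tau_c - 1e-12))
    use_discrete = sim.formalism == "discrete"
    if use_discrete:
        t_stops_global = make_tstops(cs)
        rm_global = precalculate_rates(calc, csol, t_stops_global)

    state = ChunkState(n_c=0, t_local=0.0, tau_c=tau_c)
    c = _c0_vector(rre, sim)
    all_t = [np.array([0.0])]
    all_c = [c[None, :]]
    for n_c in range(n_chunks):
        state.n_c = n_c
        t_offset = n_c * tau_c
        chunk_end = min(tau_c, sim.t_end - t_offset)
        n_out = max(2, sim.n_out // n_chunks + 1)
        try:
            if use_discrete:
                local_stops = global_to_local_stops(rm_global.t_stops, n_c, tau_c)
                local_stops = local_stops[local_stops <= chunk_end]
                # columns for the local stops
                sel = np.isin(rm_global.t_stops, local_stops + t_offset)
                local_rm = RateMatrix(rm_global.K_precalc[:, sel], local_stops)
                bounds = np.unique(
                    np.concatenate(
                        ([0.0], local_stops[(local_stops > 0) & (local_stops < chunk_end)], [chunk_end])
                    )
                )
                k_prev = calc.rates(csol.at(t_offset))
                t_seg = [np.array([0.0])]
                c_seg = [c[None, :]]
                for a, b in zip(bounds[:-1], bounds[1:]):
                    idx = np.searchsorted(local_stops, a + 1e-15 * max(1.0, tau_c)) - 1
                    k_cur = local_rm.column(idx) if idx >= 0 else k_prev
                    t_eval = np.linspace(a, b, max(2, n_out // max(1, len(bounds) - 1) + 1))
                    sol = _integrate_segment(
                        rre, c, a, b, lambda t, kk=k_cur: kk, None, sim, t_eval
                    )
                    c = sol.y[:, -1]
                    t_seg.append(sol.t[1:])
                    c_seg.append(sol.y.T[1:])
                chunk_t = np.concatenate(t_seg)
                chunk_c = np.vstack(c_seg)
            else:
                def k_of_t(t_local: float) -> np.ndarray:
                    return calc.rates(csol.at(t_offset + t_local))

                t_eval = np.linspace(0.0, chunk_end, n_out)
                sol = _integrate_segment(rre, c, 0.0, chunk_end, k_of_t, None, sim, t_eval)
                c = sol.y[:, -1]
                chunk_t = sol.t
                chunk_c = sol.y.T
        except IntegrationError as exc:
            raise IntegrationError(f"chunk {n_c}: {exc}") from exc
        state.t_local = chunk_end
        assert abs(state.t_global - (t_offset + chunk_end)) < 1e-9 * max(1.0, sim.t_end)
        mask = chunk_t > 0
        all_t.append(chunk_t[mask] + t_offset)
        all_c.append(chunk_c[mask])

    t_all = np.concatenate(all_t)
    c_all = np.vstack(all_c)
    keep = np.concatenate(([True], np.diff(t_all) > 0))
    t_all, c_all = t_all[keep], c_all[keep]
    traces = {name: np.array([csol(name, t) for t in t_all]) for name in cs.names()}
    return KineticSolution(t_all, c_all, list(rre.species_ids), traces)


def _solve_inner(
    rre: RRESystem, cs: ConditionSet, calc: Calculator, sim: SimulationParams
) -> KineticSolution:
    if sim.formalism == "continuous":
        return solve_continuous(rre, cs, calc, sim)
    return solve_discrete(rre, cs, calc, sim)


def simulate(
    net: ReactionNetwork,
    cs: ConditionSet,
    calc: Calculator,
    sim: SimulationParams,
) -> KineticSolution:
    """Convenience front end: compile, optionally prune/chunk, and solve."""
    if sim.c_max_prune is not None:
        keep = slow_reaction_mask(net, calc, solve_profiles(cs), sim)
        net = _mask_network(net, keep)
        calc = subset_calculator(calc, keep)
    rre = build_rre(net)
    return solve_chunked(rre, cs, calc, sim)


def slow_reaction_mask(
    net: ReactionNetwork,
    calc: Calculator,
    csol: ConditionSolution,
    sim: SimulationParams,
) -> np.ndarray:
    """Boolean keep-mask over reactions: True = retained.

    Reaction i is pruned (False) iff ``k_i^max * c_max_prune^order * t_end
    < rtol`` with ``k_i^max`` the rate constant at the most favorable
    condition values attained anywhere over the profiles — its maximum
    possible concentration increment stays below solver precision.
    """
    if sim.c_max_prune is None:
        raise ValueError("c_max_prune must be set for pruning")
    tt = np.linspace(0.0, csol.t_end, 201)
    k_max = np.zeros(len(net.reactions))
    for t in tt:
        k_max = np.maximum(k_max, calc.rates(csol.at(t)))
    rre = build_rre(net)
    order = rre.reaction_order
    r_max = k_max * sim.c_max_prune ** order * sim.t_end
    return r_max >= sim.rtol


def _mask_network(net: ReactionNetwork, keep: np.ndarray) -> ReactionNetwork:
    pruned = ReactionNetwork()
    for sp in net.species:
        pruned.add_species(sp)
    for i, rxn in enumerate(net.reactions):
        if keep[i]:
            pruned.add_reaction(rxn, **net.provenance.get(rxn.key, {}))
    return pruned


def prune_slow(
    net: ReactionNetwork,
    calc: Calculator,
    csol: ConditionSolution,
    sim: SimulationParams,
) -> ReactionNetwork:
    """Remove reactions whose maximum possible extent is below solver noise."""
    return _mask_network(net, slow_reaction_mask(net, calc, csol, sim))


def subset_calculator(calc: Calculator, keep: np.ndarray) -> Calculator:
    """Restrict a per-reaction calculator payload to a keep-mask."""
    from dataclasses import replace

    from .rates import ArrheniusCalculator, ArrheniusParams, StaticCalculator

    keep = np.asarray(keep, dtype=bool)
    if keep.all():
        return calc
    if isinstance(calc, StaticCalculator):
        return StaticCalculator(calc.k[keep])
    if isinstance(calc, ArrheniusCalculator):
        mol = calc.molecularity[keep] if calc.molecularity is not None else None
        return ArrheniusCalculator(
            ArrheniusParams(calc.params.Ea[keep], calc.params.A[keep]),
            molecularity=mol,
            diffusion=calc.diffusion,
        )
    raise RREError(
        f"cannot subset calculator of type {type(calc).__name__}; "
        "rebuild it for the pruned network"
    )
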