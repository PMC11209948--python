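"""Deterministic toy inputs: preset CRNs, surrogate kinetics, stiff networks.

Everything here is synthetic and generated in memory, so the full workflow
is testable with no external data:

* a five-species reversible toy network (three forward/backward reaction
  pairs) for equilibrium and detailed-balance checks;
* a two-species A<->B toy for closed-form kinetics;
* the exhaustively enumerable H2/H chemistry for exploration oracles;
* a surrogate bond-energy Arrhenius parameterization for C/H networks
  (homolysis barriers from a mean bond-enthalpy table, barrierless radical
  recombination, an Evans-Polanyi-style linear rule for transfers) — a
  deliberately simple stand-in kinetic model for demonstration runs, not a
  predictive one;
* random connected stiff networks with log-uniform rate constants.
"""

from __future__ import annotations

import logging
from collections import Counter

import numpy as np

from .chemgraph import Species, species_from_smiles
from .constants import MAX_VALENCE
from .moves import GraphMove, MoveLibrary
from .network import ReactionNetwork
from .rates import ArrheniusCalculator, ArrheniusParams, StaticCalculator
from .sampler import Reaction

logger = logging.getLogger(__name__)


def _abstract(name: str, composition: dict[str, int]) -> Species:
    return Species(canonical_id=name, element_counts=composition)


def make_toy_reversible_5species(
    k_forward: tuple[float, float, float] = (2.0, 1.0, 1.5),
    k_backward: tuple[float, float, float] = (1.0, 0.5, 1.0),
) -> tuple[ReactionNetwork, StaticCalculator]:
    """Five species A-E linked by three reversible reactions.

    A + B <-> C,  C <-> D,  D + A <-> E.  Compositions are chosen over two
    abstract elements so every reaction is exactly element-balanced.
    Returns the network and a static calculator ordered
    (k1, k-1, k2, k-2, k3, k-3).
    """
    A = _abstract("A", {"X": 1})
    B = _abstract("B", {"Y": 1})
    C = _abstract("C", {"X": 1, "Y": 1})
    D = _abstract("D", {"X": 1, "Y": 1})
    E = _abstract("E", {"X": 2, "Y": 1})

    pairs = [
        (Counter([A, B]), Counter([C])),
        (Counter([C]), Counter([D])),
        (Counter([D, A]), Counter([E])),
    ]
    net = ReactionNetwork()
    ks: list[float] = []
    for (lhs, rhs), kf, kb in zip(pairs, k_forward, k_backward):
        fwd = Reaction(Counter(lhs), Counter(rhs))
        net.add_reaction(fwd, preset="toy5")
        ks.append(kf)
        net.add_reaction(fwd.reverse(), preset="toy5")
        ks.append(kb)
    if any(k <= 0 for k in ks):
        raise ValueError("toy rate constants must be positive")
    return net, StaticCalculator(np.array(ks))


def make_ab_toy(
    k1: float = 2.0, km1: float = 1.0
) -> tuple[ReactionNetwork, ArrheniusCalculator]:
    """Reversible isomerization A <-> B with Ea = 0 (temperature-flat rates).

    Useful as the base system for variable-condition solver checks; with
    ``arrhenius_ab_toy`` the same topology gets temperature-dependent rates.
    """
    net, _ = _ab_network()
    calc = ArrheniusCalculator(
        ArrheniusParams(Ea=np.zeros(2), A=np.array([k1, km1])),
        molecularity=np.array([1, 1]),
    )
    return net, calc


def arrhenius_ab_toy(
    A1: float = 1e3,
    Ea1: float = 40e3,
    A2: float = 5e2,
    Ea2: float = 35e3,
) -> tuple[ReactionNetwork, ArrheniusCalculator]:
    """A <-> B with genuinely temperature-dependent Arrhenius rates."""
    net, _ = _ab_network()
    calc = ArrheniusCalculator(
        ArrheniusParams(Ea=np.array([Ea1, Ea2]), A=np.array([A1, A2])),
        molecularity=np.array([1, 1]),
    )
    return net, calc


def _ab_network() -> tuple[ReactionNetwork, None]:
    A = _abstract("A", {"X": 1})
    B = _abstract("B", {"X": 1})
    fwd = Reaction(Counter([A]), Counter([B]))
    net = ReactionNetwork()
    net.add_reaction(fwd, preset="ab")
    net.add_reaction(fwd.reverse(), preset="ab")
    return net, None


# ---------------------------------------------------------------------------
# Enumerable H2/H chemistry

def h2_species() -> Species:
    return species_from_smiles("[H][H]")


def h_library() -> MoveLibrary:
    """Break/make bond moves restricted to hydrogen."""
    hset = (frozenset({"H"}), frozenset({"H"}))
    return MoveLibrary(
        moves=[
            GraphMove("break_HH", ((0, 1, -1),), allowed_elements=hset, weight=1.0),
            GraphMove("form_HH", ((0, 1, +1),), allowed_elements=hset, weight=1.0),
        ]
    )


# ---------------------------------------------------------------------------
# Surrogate hydrocarbon kinetics

#: Mean single-bond enthalpies, J/mol (surrogate barrier heights).
BOND_ENERGY = {
    frozenset(["H"]): 436e3,
    frozenset(["C", "H"]): 413e3,
    frozenset(["C"]): 347e3,
}

#: Surrogate prefactor conventions.
A_UNIMOLECULAR = 1e15   # s^-1
A_BIMOLECULAR = 1e10    # dm^3 mol^-1 s^-1
EA_FALLBACK = 150e3     # J/mol for unclassifiable reactions
EP_OFFSET = 40e3        # Evans-Polanyi intercept, J/mol
EP_SLOPE = 0.5          # Evans-Polanyi slope


def _total_radicals(sp: Species) -> int:
    if sp.graph is None:
        return 0
    return sum(
        max(0, MAX_VALENCE.get(sp.graph.nodes[n]["element"], 4) - sp.graph.degree[n])
        for n in sp.graph.nodes
    )


def _radical_element(sp: Species) -> str | None:
    """Element of the highest-deficit atom (the presumed radical site)."""
    if sp.graph is None:
        return None
    best, best_def = None, 0
    for n in sp.graph.nodes:
        el = sp.graph.nodes[n]["element"]
        deficit = MAX_VALENCE.get(el, 4) - sp.graph.degree[n]
        if deficit > best_def:
            best, best_def = el, deficit
    return best


def _side_radicals(side: Counter) -> int:
    return sum(_total_radicals(sp) * n for sp, n in side.items())


def surrogate_ea(rxn: Reaction) -> tuple[float, str]:
    """Surrogate activation energy (J/mol) and the class label used."""
    n_react = sum(rxn.reactants.values())
    n_prod = sum(rxn.products.values())
    rad_in = _side_radicals(rxn.reactants)
    rad_out = _side_radicals(rxn.products)

    if n_react == 1 and n_prod == 2 and rad_out == rad_in + 2:
        # homolysis: barrier = energy of the broken bond, identified by the
        # elements of the two newly created radical sites
        els = []
        for sp, n in rxn.products.items():
            el = _radical_element(sp)
            if el is not None:
                els.extend([el] * n)
        key = frozenset(els[:2]) if len(els) >= 2 else None
        if key in BOND_ENERGY:
            return BOND_ENERGY[key], "homolysis"
        return EA_FALLBACK, "homolysis-unknown-bond"
    if n_react == 2 and n_prod == 1 and rad_in == rad_out + 2:
        return 0.0, "recombination"
    if n_react == 2 and n_prod == 2 and rad_in == rad_out and rad_in > 0:
        # transfer: Evans-Polanyi on (broken - formed) bond energies, bonds
        # keyed by the radical site elements on each side plus hydrogen
        el_new = None
        for sp in rxn.products:
            if sp not in rxn.reactants:
                el_new = _radical_element(sp)
                if el_new:
                    break
        el_old = None
        for sp in rxn.reactants:
            if sp not in rxn.products:
                el_old = _radical_element(sp)
                if el_old:
                    break
        broken = BOND_ENERGY.get(frozenset({el_new, "H"} - {None}))
        formed = BOND_ENERGY.get(frozenset({el_old, "H"} - {None}))
        if broken is not None and formed is not None:
            return max(0.0, EP_OFFSET + EP_SLOPE * (broken - formed)), "transfer"
        return EA_FALLBACK, "transfer-unknown-bond"
    return EA_FALLBACK, "fallback"


def make_hydrocarbon_surrogate_rates(net: ReactionNetwork) -> ArrheniusCalculator:
    """Assign surrogate Arrhenius parameters to every reaction of a C/H network.

    Total by construction: unclassifiable reactions receive the fallback
    barrier with a logged warning rather than failing.
    """
    Ea = np.zeros(net.n_reactions)
    A = np.zeros(net.n_reactions)
    mol = np.zeros(net.n_reactions, dtype=int)
    for i, rxn in enumerate(net.reactions):
        ea, label = surrogate_ea(rxn)
        if "unknown" in label or label == "fallback":
            logger.warning("surrogate fallback Ea for %s (%s)", rxn.smiles(), label)
        Ea[i] = ea
        mol[i] = sum(rxn.reactants.values())
        A[i] = A_BIMOLECULAR if mol[i] == 2 else A_UNIMOLECULAR
    return ArrheniusCalculator(ArrheniusParams(Ea, A), molecularity=mol)


# ---------------------------------------------------------------------------
# Random stiff networks

def make_random_stiff_crn(
    n_species: int,
    n_reactions: int,
    k_span_decades: float,
    seed: int = 0,
) -> tuple[ReactionNetwork, StaticCalculator]:
    """Connected, element-consistent abstract network with log-uniform rates.

    Species come in two mass tiers (one or two abstract "X" units), so
    unimolecular conversions within a tier and association/dissociation
    between tiers are all exactly balanced.  Rate constants span
    ``k_span_decades`` decades, log-uniformly, centred on 1 s^-1.
    """
    if n_species < 2:
        raise ValueError("need at least two species")
    if k_span_decades < 0:
        raise ValueError("span must be non-negative")
    rng = np.random.default_rng(seed)
    n_light = max(2, (n_species + 1) // 2 + 1)
    n_light = min(n_light, n_species)
    n_heavy = n_species - n_light
    light = [_abstract(f"L{i}", {"X": 1}) for i in range(n_light)]
    heavy = [_abstract(f"H{i}", {"X": 2}) for i in range(n_heavy)]

    net = ReactionNetwork()
    proposals: list[Reaction] = []
    # spanning proposals guarantee connectivity
    for i in range(n_light - 1):
        proposals.append(Reaction(Counter([light[i]]), Counter([light[i + 1]])))
    for j in range(n_heavy):
        a = light[j % n_light]
        b = light[(j + 1) % n_light]
        proposals.append(Reaction(Counter([a, b]), Counter([heavy[j]])))
    # random extras
    attempts = 0
    while len(proposals) < n_reactions and attempts < 50 * n_reactions:
        attempts += 1
        kind = rng.integers(4)
        try:
            if kind == 0 and n_light >= 2:
                i, j = rng.choice(n_light, size=2, replace=False)
                r = Reaction(Counter([light[i]]), Counter([light[j]]))
            elif kind == 1 and n_heavy >= 2:
                i, j = rng.choice(n_heavy, size=2, replace=False)
                r = Reaction(Counter([heavy[i]]), Counter([heavy[j]]))
            elif kind == 2 and n_heavy >= 1:
                i, j = rng.integers(n_light), rng.integers(n_light)
                h = rng.integers(n_heavy)
                r = Reaction(Counter([light[i], light[j]]), Counter([heavy[h]]))
            elif n_heavy >= 1:
                i, j = rng.integers(n_light), rng.integers(n_light)
                h = rng.integers(n_heavy)
                r = Reaction(Counter([heavy[h]]), Counter([light[i], light[j]]))
            else:
                continue
        except Exception:
            continue
        if r not in proposals:
            proposals.append(r)

    ks = []
    for r in proposals[:n_reactions] if len(proposals) > n_reactions else proposals:
        if net.add_reaction(r, preset="stiff"):
            log_k = rng.uniform(-k_span_decades / 2, k_span_decades / 2)
            ks.append(10.0 ** log_k)
    for sp in light + heavy:
        net.add_species(sp)
    return net, StaticCalculator(np.array(ks))
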