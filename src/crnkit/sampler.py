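"""Single-ended graph-driven sampling (SE-GDS) of reaction mechanisms.

Starting from a molecular system, one sampling step (i) draws a graph move
from the weighted library, (ii) picks a valid slot assignment on the
system's combined connectivity matrix, (iii) validates valences, forbidden
patterns and molecularity, and (iv) regenerates a 3D geometry for the new
CM through the graph restraining potential plus the optional refiner hook.
If any stage fails the CM is restored and a new move is drawn, up to
``max_attempts`` times; exhausting the budget truncates the mechanism.
Repeating the step ``n_r`` times builds one randomly sampled mechanism;
``n_m`` mechanisms are generated per run.

Moves act on the combined system CM, so inter-molecular bond formation
(bimolecular chemistry) arises naturally.  Reactions of molecularity above
two on either side are rejected: their occurrence probability in reaction
mixtures is negligible.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem

from .chemgraph import (
    CanonicalizationError,
    ChemSystem,
    ConnectivityMatrix,
    CovalentRadiiTable,
    Geometry,
    Species,
    connectivity_from_geometry,
    split_molecules,
)
from .grp import GraphMismatch, GRPParams, RefinerHook, identity_refiner, optimize_to_graph
from .moves import (
    ForbiddenPatterns,
    MoveLibrary,
    MoveRejected,
    ValenceConstraints,
    apply_move,
    enumerate_applications,
    sample_move,
)


@dataclass(frozen=True)
class SamplerParams:
    n_r: int = 1            # reactions per mechanism ("radius")
    n_m: int = 1            # mechanisms per run
    max_attempts: int = 100
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_r, self.n_m, self.max_attempts) < 1:
            raise ValueError("n_r, n_m and max_attempts must all be >= 1")


class ReactionError(ValueError):
    """Internal consistency failure while forming a Reaction."""


@dataclass(frozen=True)
class Reaction:
    """A directional, element-balanced species-multiset transformation."""

    reactants: Counter
    products: Counter

    def __post_init__(self) -> None:
        if not self.reactants or not self.products:
            raise ReactionError("reaction sides must be nonempty")
        if self.reactants == self.products:
            raise ReactionError("reactants equal products")
        if sum(self.reactants.values()) > 2 or sum(self.products.values()) > 2:
            raise ReactionError("molecularity above bimolecular")
        lhs: Counter = Counter()
        for sp, n in self.reactants.items():
            for el, c in sp.element_counts.items():
                lhs[el] += n * c
        rhs: Counter = Counter()
        for sp, n in self.products.items():
            for el, c in sp.element_counts.items():
                rhs[el] += n * c
        if lhs != rhs:
            raise ReactionError(f"element imbalance: {dict(lhs)} vs {dict(rhs)}")

    @property
    def key(self) -> tuple:
        """Direction-specific identity under canonical species ids."""
        return (
            tuple(sorted((sp.canonical_id, n) for sp, n in self.reactants.items())),
            tuple(sorted((sp.canonical_id, n) for sp, n in self.products.items())),
        )

    def reverse(self) -> "Reaction":
        return Reaction(Counter(self.products), Counter(self.reactants))

    def smiles(self) -> str:
        def side(ms: Counter) -> str:
            parts: list[str] = []
            for sp, n in sorted(ms.items(), key=lambda kv: kv[0].canonical_id):
                parts.extend([sp.canonical_id] * n)
            return ".".join(parts)

        return f"{side(self.reactants)}>>{side(self.products)}"

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Reaction) and self.key == other.key

    def __hash__(self) -> int:
        return hash(self.key)

    def __repr__(self) -> str:
        return f"Reaction({self.smiles()!r})"


@dataclass
class MechanismStep:
    species_before: Counter
    reaction: Reaction | None   # None when the move changed no multiplicity
    species_after: Counter
    geometry_after: Geometry | None = None
    attempts: int = 1


@dataclass
class Mechanism:
    steps: list[MechanismStep] = field(default_factory=list)
    truncated: bool = False

    def __len__(self) -> int:
        return len(self.steps)


def reaction_from_diff(before: Counter, after: Counter) -> Reaction | None:
    """Diff two species multisets into a reaction, dropping spectators.

    Returns None when the multisets are identical (no net transformation).
    """
    consumed = before - after
    formed = after - before
    if not consumed and not formed:
        return None
    if not consumed or not formed:
        raise ReactionError("one-sided multiset change cannot be balanced")
    return Reaction(consumed, formed)


def extract_reactions(mech: Mechanism) -> list[Reaction]:
    """Stoichiometric reactions of a mechanism, discarding no-change steps."""
    return [s.reaction for s in mech.steps if s.reaction is not None]


# ---------------------------------------------------------------------------
# Geometry bootstrap for species without coordinates

def geometry_for_species(sp: Species, seed: int = 0) -> Geometry:
    """Generate approximate 3D coordinates for a species fragment graph.

    Tries RDKit distance-geometry embedding first; falls back to GRP
    minimization from seeded random coordinates.
    """
    if sp.graph is None:
        raise ValueError(f"species {sp.canonical_id} carries no fragment graph")
    g = sp.graph
    nodes = list(g.nodes)
    elements = [g.nodes[n]["element"] for n in nodes]
    n = len(nodes)
    if n == 1:
        return Geometry(elements, np.zeros((1, 3)))

    index = {node: i for i, node in enumerate(nodes)}
    mol = Chem.RWMol()
    for el in elements:
        a = Chem.Atom(el)
        a.SetNoImplicit(True)
        mol.AddAtom(a)
    for u, v in g.edges:
        mol.AddBond(index[u], index[v], Chem.BondType.SINGLE)
    from .constants import MAX_VALENCE

    for node in nodes:
        deficit = MAX_VALENCE.get(elements[index[node]], 4) - g.degree[node]
        if deficit > 0:
            mol.GetAtomWithIdx(index[node]).SetNumRadicalElectrons(deficit)
    try:
        m = mol.GetMol()
        Chem.SanitizeMol(m)
        params = AllChem.ETKDGv3()
        params.randomSeed = seed + 1
        if AllChem.EmbedMolecule(m, params) == 0:
            conf = m.GetConformer()
            coords = np.array(
                [list(conf.GetAtomPosition(i)) for i in range(m.GetNumAtoms())]
            )
            geom = Geometry(elements, coords)
            target = ConnectivityMatrix(
                np.array(Chem.GetAdjacencyMatrix(m), dtype=np.int8)
            )
            if np.array_equal(
                connectivity_from_geometry(geom).entries, target.entries
            ):
                return geom
    except Exception:
        pass

    # Fallback: GRP from seeded random coordinates (retry a few seeds)
    adj = np.zeros((n, n), dtype=np.int8)
    for u, v in g.edges:
        adj[index[u], index[v]] = adj[index[v], index[u]] = 1
    target = ConnectivityMatrix(adj)
    for trial in range(10):
        rng = np.random.default_rng(seed * 1000 + trial)
        coords = rng.normal(scale=1.5, size=(n, 3))
        try:
            return optimize_to_graph(Geometry(elements, coords), target)
        except GraphMismatch:
            continue
    raise GraphMismatch(f"could not embed species {sp.canonical_id}")


def assemble_system(
    system: ChemSystem, seed: int = 0, spacing: float = 6.0
) -> Geometry:
    """Lay out all molecules of a system along a line, well separated."""
    geoms: list[Geometry] = []
    if system.geometries is not None:
        geoms = [g.copy() for g in system.geometries]
    else:
        for i, sp in enumerate(system.molecules()):
            geoms.append(geometry_for_species(sp, seed=seed + i))
    symbols: list[str] = []
    coords: list[np.ndarray] = []
    offset = 0.0
    for g in geoms:
        c = g.coordinates - g.coordinates.mean(axis=0)
        extent = float(np.ptp(c[:, 0])) if g.n_atoms > 1 else 0.0
        offset += extent / 2
        c = c + np.array([offset, 0.0, 0.0])
        offset += extent / 2 + spacing
        symbols.extend(g.element_symbols)
        coords.append(c)
    return Geometry(symbols, np.vstack(coords))


# ---------------------------------------------------------------------------
# Main SE-GDS loop

def run_segds(
    system: ChemSystem,
    lib: MoveLibrary,
    valence: ValenceConstraints | None = None,
    forbidden: ForbiddenPatterns | None = None,
    params: SamplerParams | None = None,
    refiner: RefinerHook = identity_refiner,
    radii: CovalentRadiiTable | None = None,
    grp_params: GRPParams | None = None,
    skip_geometry: bool = False,
) -> list[Mechanism]:
    """Run the SE-GDS sampler: ``n_m`` mechanisms of up to ``n_r`` steps each.

    Fully reproducible for fixed inputs and ``params.rng_seed``.  With
    ``skip_geometry`` the GRP/refiner round-trip is bypassed (graph-level
    sampling only), which is useful for enumeration oracles and large sweeps.
    """
    valence = valence or ValenceConstraints()
    params = params or SamplerParams()
    radii = radii or CovalentRadiiTable()
    rng = np.random.default_rng(params.rng_seed)

    mechanisms: list[Mechanism] = []
    for i_mech in range(params.n_m):
        geom = assemble_system(system, seed=params.rng_seed + 7919 * i_mech)
        cm = connectivity_from_geometry(geom, radii)
        multiset = Counter(sp for sp, _ in split_molecules(cm, geom))
        mech = Mechanism()
        for _step in range(params.n_r):
            step = _attempt_step(
                geom, cm, multiset, lib, valence, forbidden, params, refiner,
                radii, grp_params, rng, skip_geometry,
            )
            if step is None:
                mech.truncated = True
                break
            mech.steps.append(step)
            multiset = step.species_after
            if not skip_geometry:
                geom = step.geometry_after
                cm = connectivity_from_geometry(geom, radii)
            else:
                cm = step._cm_after  # type: ignore[attr-defined]
                geom = Geometry(list(geom.element_symbols), geom.coordinates)
        mechanisms.append(mech)
    return mechanisms


def _attempt_step(
    geom: Geometry,
    cm: ConnectivityMatrix,
    multiset: Counter,
    lib: MoveLibrary,
    valence: ValenceConstraints,
    forbidden: ForbiddenPatterns | None,
    params: SamplerParams,
    refiner: RefinerHook,
    radii: CovalentRadiiTable,
    grp_params: GRPParams | None,
    rng: np.random.Generator,
    skip_geometry: bool,
) -> MechanismStep | None:
    elements = geom.element_symbols
    for attempt in range(1, params.max_attempts + 1):
        move = sample_move(lib, rng)
        apps = enumerate_applications(cm, elements, move, valence, forbidden)
        if not apps:
            continue
        assignment = apps[int(rng.integers(len(apps)))]
        try:
            new_cm = apply_move(cm, elements, move, assignment, valence, forbidden)
        except MoveRejected:
            continue
        try:
            parts = split_molecules(new_cm, geom)
        except CanonicalizationError:
            continue
        new_multiset = Counter(sp for sp, _ in parts)
        try:
            reaction = reaction_from_diff(multiset, new_multiset)
        except ReactionError:
            continue  # molecularity or balance rejection

        if skip_geometry:
            step = MechanismStep(
                species_before=Counter(multiset),
                reaction=reaction,
                species_after=new_multiset,
                geometry_after=None,
                attempts=attempt,
            )
            step._cm_after = new_cm  # type: ignore[attr-defined]
            return step

        try:
            new_geom = optimize_to_graph(geom, new_cm, radii, grp_params, refiner)
        except GraphMismatch:
            continue
        return MechanismStep(
            species_before=Counter(multiset),
            reaction=reaction,
            species_after=new_multiset,
            geometry_after=new_geom,
            attempts=attempt,
        )
    return None


def dump_mechanism(mech: Mechanism) -> str:
    """One reaction-SMILES line per step (no-change steps annotated)."""
    lines = []
    for s in mech.steps:
        lines.append(s.reaction.smiles() if s.reaction else "# no net change")
    return "\n".join(lines)
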