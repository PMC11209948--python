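"""Graph-move library: definition, weighted sampling, application, validity.

A graph move is a templated edit of the connectivity matrix over ``k``
abstract atom slots: an ordered list of bond deltas ``(slot_i, slot_j, +/-1)``
optionally restricted to element whitelists per slot.  Moves carry relative
selection weights so that sampling can be biased toward reaction classes
expected to dominate a given chemistry; uniform weights recover unbiased
exploration.

Validity of an edited CM is enforced by (a) per-element maximum valences
(graph degree limits) and (b) an optional list of forbidden subgraph
patterns, matched exactly on element-labelled graphs (VF2).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import yaml

from .chemgraph import ConnectivityMatrix
from .constants import MAX_VALENCE


class MoveRejected(Exception):
    """A move application violated a precondition, valence, or forbidden pattern."""


class MoveLibraryError(ValueError):
    """Invalid move-library configuration."""


@dataclass(frozen=True)
class GraphMove:
    name: str
    bond_deltas: tuple[tuple[int, int, int], ...]
    allowed_elements: tuple[frozenset[str], ...] = ()
    weight: float = 1.0

    def __post_init__(self) -> None:
        deltas = tuple((int(i), int(j), int(d)) for i, j, d in self.bond_deltas)
        object.__setattr__(self, "bond_deltas", deltas)
        if not deltas:
            raise MoveLibraryError(f"move {self.name!r} has no bond deltas")
        pairs = [frozenset((i, j)) for i, j, _ in deltas]
        if len(set(pairs)) != len(pairs):
            raise MoveLibraryError(f"move {self.name!r} repeats a slot pair")
        for i, j, d in deltas:
            if i == j:
                raise MoveLibraryError("slot pair must be distinct")
            if d not in (-1, 1):
                raise MoveLibraryError("delta must be +1 or -1")
        k = self.n_slots
        if k < 2:
            raise MoveLibraryError("a move needs at least 2 slots")
        allowed = self.allowed_elements or tuple(frozenset() for _ in range(k))
        allowed = tuple(frozenset(a) for a in allowed)
        if len(allowed) != k:
            raise MoveLibraryError("allowed_elements length must equal slot count")
        object.__setattr__(self, "allowed_elements", allowed)
        if not np.isfinite(self.weight) or self.weight < 0:
            raise MoveLibraryError("weight must be finite and >= 0")

    @property
    def n_slots(self) -> int:
        return max(max(i, j) for i, j, _ in self.bond_deltas) + 1

    def slot_allows(self, slot: int, element: str) -> bool:
        allowed = self.allowed_elements[slot]
        return not allowed or element in allowed

    def slot_symmetries(self) -> list[tuple[int, ...]]:
        """Permutations of slots that leave the move template invariant."""
        k = self.n_slots
        delta_set = {(frozenset((i, j)), d) for i, j, d in self.bond_deltas}
        syms = []
        for perm in permutations(range(k)):
            mapped = {(frozenset((perm[i], perm[j])), d) for i, j, d in self.bond_deltas}
            if mapped == delta_set and all(
                self.allowed_elements[i] == self.allowed_elements[perm[i]]
                for i in range(k)
            ):
                syms.append(perm)
        return syms


@dataclass
class MoveLibrary:
    moves: list[GraphMove]

    def __post_init__(self) -> None:
        if not self.moves:
            raise MoveLibraryError("move library is empty")
        if sum(m.weight for m in self.moves) <= 0:
            raise MoveLibraryError("sum of move weights must be positive")


@dataclass(frozen=True)
class ValenceConstraints:
    max_valence_by_element: Mapping[str, int] = field(
        default_factory=lambda: dict(MAX_VALENCE)
    )

    def __post_init__(self) -> None:
        if any(v < 1 for v in self.max_valence_by_element.values()):
            raise ValueError("max valences must be >= 1")

    def limit(self, element: str) -> int:
        return self.max_valence_by_element.get(element, 4)


@dataclass
class ForbiddenPatterns:
    """Element-labelled subgraphs whose occurrence invalidates a CM."""

    patterns: list[nx.Graph] = field(default_factory=list)

    def __post_init__(self) -> None:
        if any(p.number_of_nodes() == 0 for p in self.patterns):
            raise ValueError("forbidden patterns must be nonempty graphs")

    def occurs_in(self, graph: nx.Graph) -> bool:
        for pat in self.patterns:
            gm = nx.algorithms.isomorphism.GraphMatcher(
                graph,
                pat,
                node_match=lambda a, b: a["element"] == b["element"],
            )
            if gm.subgraph_is_monomorphic():
                return True
        return False


def sample_move(lib: MoveLibrary, rng: np.random.Generator) -> GraphMove:
    """Draw a move with probability proportional to its weight."""
    weights = np.array([m.weight for m in lib.moves], dtype=float)
    p = weights / weights.sum()
    idx = rng.choice(len(lib.moves), p=p)
    return lib.moves[int(idx)]


def _check_assignment(
    cm: ConnectivityMatrix,
    elements: Sequence[str],
    move: GraphMove,
    assignment: Sequence[int],
) -> bool:
    """Preconditions only: distinct atoms, whitelists, delta applicability."""
    if len(set(assignment)) != len(assignment):
        return False
    if len(assignment) != move.n_slots:
        return False
    for slot, atom in enumerate(assignment):
        if not move.slot_allows(slot, elements[atom]):
            return False
    for i, j, d in move.bond_deltas:
        a, b = assignment[i], assignment[j]
        bonded = cm.entries[a, b] == 1
        if d == 1 and bonded:
            return False
        if d == -1 and not bonded:
            return False
    return True


def apply_move(
    cm: ConnectivityMatrix,
    elements: Sequence[str],
    move: GraphMove,
    slot_assignment: Sequence[int],
    valence: ValenceConstraints | None = None,
    forbidden: ForbiddenPatterns | None = None,
) -> ConnectivityMatrix:
    """Apply a move's bond deltas at a slot assignment, validating the result.

    Raises :class:`MoveRejected` on any precondition, valence, or
    forbidden-pattern failure; the input CM is never modified.
    """
    valence = valence or ValenceConstraints()
    if not _check_assignment(cm, elements, move, slot_assignment):
        raise MoveRejected(f"invalid slot assignment {list(slot_assignment)} for {move.name}")
    m = cm.entries.copy()
    for i, j, d in move.bond_deltas:
        a, b = slot_assignment[i], slot_assignment[j]
        m[a, b] = m[b, a] = 1 if d == 1 else 0
    new_cm = ConnectivityMatrix(m)
    degrees = m.sum(axis=1)
    for atom in slot_assignment:
        if degrees[atom] > valence.limit(elements[atom]):
            raise MoveRejected(
                f"valence of {elements[atom]}{atom} exceeds "
                f"{valence.limit(elements[atom])}"
            )
    if forbidden is not None and forbidden.patterns:
        if forbidden.occurs_in(new_cm.to_graph(elements)):
            raise MoveRejected("forbidden pattern present after move")
    return new_cm


def enumerate_applications(
    cm: ConnectivityMatrix,
    elements: Sequence[str],
    move: GraphMove,
    valence: ValenceConstraints | None = None,
    forbidden: ForbiddenPatterns | None = None,
) -> list[tuple[int, ...]]:
    """Exhaustively list valid slot assignments, deduplicated by slot symmetry."""
    valence = valence or ValenceConstraints()
    n = cm.n_atoms
    syms = move.slot_symmetries()
    seen: set[tuple[int, ...]] = set()
    out: list[tuple[int, ...]] = []
    for assignment in permutations(range(n), move.n_slots):
        canon = min(tuple(assignment[s] for s in perm) for perm in syms)
        if canon in seen:
            continue
        if not _check_assignment(cm, elements, move, assignment):
            continue
        try:
            apply_move(cm, elements, move, assignment, valence, forbidden)
        except MoveRejected:
            continue
        seen.add(canon)
        out.append(tuple(assignment))
    return out


def default_library() -> MoveLibrary:
    """The shipped 2-/3-atom move set.

    Covers bond formation, homolytic cleavage, atom transfer and concerted
    exchange — the elementary CM edits spanning unimolecular and bimolecular
    radical chemistry.
    """
    return MoveLibrary(
        moves=[
            GraphMove("form_bond", ((0, 1, +1),), weight=1.0),
            GraphMove("break_bond", ((0, 1, -1),), weight=1.0),
            GraphMove("atom_transfer", ((0, 1, -1), (1, 2, +1)), weight=1.0),
            GraphMove("exchange", ((0, 1, -1), (0, 2, +1)), weight=1.0),
        ]
    )


# ---------------------------------------------------------------------------
# Library file format (YAML): a list of move records.

def load_library(path: str | Path) -> MoveLibrary:
    """Read a move library from its YAML schema.

    Each record: ``name`` (str), ``deltas`` (list of [slot_i, slot_j, delta]),
    optional ``elements`` (list of per-slot element lists, [] = any), optional
    ``weight`` (float, default 1).
    """
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, list):
        raise MoveLibraryError("library file must contain a list of moves")
    moves = []
    for rec in data:
        deltas = tuple((int(i), int(j), int(d)) for i, j, d in rec["deltas"])
        elements = tuple(frozenset(e) for e in rec.get("elements", []))
        moves.append(
            GraphMove(
                name=str(rec["name"]),
                bond_deltas=deltas,
                allowed_elements=elements,
                weight=float(rec.get("weight", 1.0)),
            )
        )
    return MoveLibrary(moves)


def dump_library(lib: MoveLibrary, path: str | Path) -> None:
    data = []
    for m in lib.moves:
        rec: dict = {
            "name": m.name,
            "deltas": [[i, j, d] for i, j, d in m.bond_deltas],
            "weight": m.weight,
        }
        if any(m.allowed_elements):
            rec["elements"] = [sorted(a) for a in m.allowed_elements]
        data.append(rec)
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
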