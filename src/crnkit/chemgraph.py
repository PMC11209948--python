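"""Molecular graphs from geometry: bond perception, splitting, canonical identity.

A molecular system is represented at the graph level by a binary, symmetric
connectivity matrix (CM) over its atoms.  Two atoms ``i`` and ``j`` are
considered bonded when their Euclidean distance falls below a cutoff

    r_cut(i, j) = alpha * (R_i + R_j)

built from tabulated covalent radii ``R`` and a dimensionless scaling
``alpha`` (default 1.1) that absorbs bond-length variation across molecular
environments.  Bond order is deliberately not modelled: the CM answers only
"bonded or not", which is the resolution at which graph moves operate.

Species identity is a canonical, hydrogen-explicit SMILES string in which
radical centres are implied by the valence deficit of each atom (e.g. a
carbon of degree 3 carries one unpaired electron and canonicalizes to
``[CH3]``).  Canonicalization is delegated to RDKit so that isomorphic
fragments always collapse to the same identifier.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
from rdkit import Chem
from rdkit import RDLogger

from .constants import COVALENT_RADII, MAX_VALENCE

RDLogger.DisableLog("rdApp.*")


class UnsupportedElementError(KeyError):
    """Raised when a geometry contains an element absent from the radii table."""


class CanonicalizationError(ValueError):
    """Raised when a fragment cannot be rationalized into a SMILES string."""


@dataclass(frozen=True)
class CovalentRadiiTable:
    """Covalent radii (Angstrom) plus the cutoff scaling factor alpha."""

    radius_by_element: Mapping[str, float] = field(
        default_factory=lambda: dict(COVALENT_RADII)
    )
    alpha: float = 1.1

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        for el, r in self.radius_by_element.items():
            if r <= 0:
                raise ValueError(f"radius for {el} must be positive")

    def radius(self, element: str) -> float:
        try:
            return self.radius_by_element[element]
        except KeyError as exc:
            raise UnsupportedElementError(
                f"element {element!r} not in covalent radii table"
            ) from exc

    def cutoff(self, element_i: str, element_j: str) -> float:
        """Bonding cutoff distance alpha*(R_i + R_j) in Angstrom."""
        return self.alpha * (self.radius(element_i) + self.radius(element_j))


@dataclass
class Geometry:
    """Atomic Cartesian coordinates (Angstrom) with element labels."""

    element_symbols: list[str]
    coordinates: np.ndarray

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float).reshape(-1, 3)
        if len(self.element_symbols) == 0:
            raise ValueError("geometry must contain at least one atom")
        if self.coordinates.shape[0] != len(self.element_symbols):
            raise ValueError("coordinate count does not match element count")
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("coordinates must be finite")

    @property
    def n_atoms(self) -> int:
        return len(self.element_symbols)

    def copy(self) -> "Geometry":
        return Geometry(list(self.element_symbols), self.coordinates.copy())


@dataclass(frozen=True)
class ConnectivityMatrix:
    """Symmetric binary adjacency matrix with zero diagonal."""

    entries: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.entries, dtype=np.int8)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("connectivity matrix must be square")
        if not np.array_equal(m, m.T):
            raise ValueError("connectivity matrix must be symmetric")
        if np.any(np.diag(m) != 0):
            raise ValueError("connectivity matrix must have zero diagonal")
        if not np.isin(m, (0, 1)).all():
            raise ValueError("entries must be 0 or 1")
        object.__setattr__(self, "entries", m)

    @property
    def n_atoms(self) -> int:
        return self.entries.shape[0]

    def degree(self, i: int) -> int:
        return int(self.entries[i].sum())

    def bonds(self) -> list[tuple[int, int]]:
        ii, jj = np.nonzero(np.triu(self.entries))
        return list(zip(ii.tolist(), jj.tolist()))

    def with_bond(self, i: int, j: int, value: int) -> "ConnectivityMatrix":
        m = self.entries.copy()
        m[i, j] = m[j, i] = value
        return ConnectivityMatrix(m)

    def to_graph(self, elements: Sequence[str]) -> nx.Graph:
        g = nx.Graph()
        for i, el in enumerate(elements):
            g.add_node(i, element=el)
        g.add_edges_from(self.bonds())
        return g

    def components(self) -> list[list[int]]:
        g = nx.from_numpy_array(self.entries)
        return [sorted(c) for c in nx.connected_components(g)]


@dataclass(frozen=True)
class Species:
    """A connected molecular fragment identified by canonical SMILES.

    ``graph`` and per-atom data are optional so that abstract species (as in
    toy kinetic networks, where "A" or "B" stand for whole molecules) can
    share the same network machinery.
    """

    canonical_id: str
    element_counts: Mapping[str, int]
    graph: nx.Graph | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "element_counts", dict(self.element_counts))

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Species) and self.canonical_id == other.canonical_id

    def __hash__(self) -> int:
        return hash(self.canonical_id)

    def __repr__(self) -> str:
        return f"Species({self.canonical_id!r})"

    def count(self, element: str) -> int:
        return self.element_counts.get(element, 0)


@dataclass
class ChemSystem:
    """A multiset of species, optionally with one geometry per molecule."""

    species_multiset: Counter
    geometries: list[Geometry] | None = None

    def __post_init__(self) -> None:
        if any(n < 1 for n in self.species_multiset.values()):
            raise ValueError("multiplicities must be >= 1")

    @classmethod
    def from_species(cls, species: Iterable[Species]) -> "ChemSystem":
        return cls(Counter(species))

    def molecules(self) -> list[Species]:
        out: list[Species] = []
        for sp, n in self.species_multiset.items():
            out.extend([sp] * n)
        return out


def connectivity_from_geometry(
    geom: Geometry, radii: CovalentRadiiTable | None = None
) -> ConnectivityMatrix:
    """Perceive bonds from interatomic distances against covalent-radius cutoffs.

    Entry (i, j) is 1 iff ``r_ij < alpha * (R_i + R_j)`` for i != j.
    """
    radii = radii or CovalentRadiiTable()
    n = geom.n_atoms
    r = np.array([radii.radius(el) for el in geom.element_symbols])
    cut = radii.alpha * (r[:, None] + r[None, :])
    d = np.linalg.norm(geom.coordinates[:, None, :] - geom.coordinates[None, :, :], axis=-1)
    m = (d < cut).astype(np.int8)
    np.fill_diagonal(m, 0)
    return ConnectivityMatrix(m)


def canonical_species(
    graph: nx.Graph,
    max_valence: Mapping[str, int] | None = None,
) -> Species:
    """Canonicalize a connected, element-labelled fragment graph to a Species.

    Radical electrons on each atom equal (max valence - degree).  A degree
    exceeding the element's maximum valence cannot be rationalized and
    raises :class:`CanonicalizationError`, which samplers treat as a signal
    to reject the originating graph move.
    """
    if graph.number_of_nodes() == 0:
        raise CanonicalizationError("empty fragment")
    if not nx.is_connected(graph):
        raise CanonicalizationError("fragment graph is not connected")
    max_valence = max_valence or MAX_VALENCE

    nodes = list(graph.nodes)
    index = {n: i for i, n in enumerate(nodes)}
    mol = Chem.RWMol()
    for n in nodes:
        el = graph.nodes[n]["element"]
        if el not in max_valence:
            raise CanonicalizationError(f"no valence entry for element {el!r}")
        atom = Chem.Atom(el)
        atom.SetNoImplicit(True)
        mol.AddAtom(atom)
    for u, v in graph.edges:
        mol.AddBond(index[u], index[v], Chem.BondType.SINGLE)
    for n in nodes:
        el = graph.nodes[n]["element"]
        deg = graph.degree[n]
        deficit = max_valence[el] - deg
        if deficit < 0:
            raise CanonicalizationError(
                f"{el} with degree {deg} exceeds max valence {max_valence[el]}"
            )
        mol.GetAtomWithIdx(index[n]).SetNumRadicalElectrons(deficit)
    try:
        m = mol.GetMol()
        Chem.SanitizeMol(m)
        smiles = Chem.MolToSmiles(Chem.RemoveHs(m))
    except Exception as exc:  # RDKit raises various sanitization errors
        raise CanonicalizationError(str(exc)) from exc

    counts = Counter(graph.nodes[n]["element"] for n in nodes)
    return Species(canonical_id=smiles, element_counts=dict(counts), graph=graph)


def split_molecules(
    cm: ConnectivityMatrix,
    geom: Geometry,
    max_valence: Mapping[str, int] | None = None,
) -> list[tuple[Species, Geometry]]:
    """Split a system CM into connected components, one (Species, Geometry) each."""
    if cm.n_atoms != geom.n_atoms:
        raise ValueError("connectivity matrix inconsistent with geometry size")
    out: list[tuple[Species, Geometry]] = []
    full = cm.to_graph(geom.element_symbols)
    for comp in cm.components():
        sub = full.subgraph(comp).copy()
        sp = canonical_species(sub, max_valence=max_valence)
        sub_geom = Geometry(
            [geom.element_symbols[i] for i in comp], geom.coordinates[comp]
        )
        out.append((sp, sub_geom))
    return out


def species_from_smiles(smiles: str) -> Species:
    """Build a Species (with explicit-H fragment graph) from a SMILES string."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise CanonicalizationError(f"unparseable SMILES {smiles!r}")
    mol = Chem.AddHs(mol)
    g = nx.Graph()
    for atom in mol.GetAtoms():
        g.add_node(atom.GetIdx(), element=atom.GetSymbol())
    for bond in mol.GetBonds():
        g.add_edge(bond.GetBeginAtomIdx(), bond.GetEndAtomIdx())
    return canonical_species(g)


# ---------------------------------------------------------------------------
# XYZ I/O

def read_xyz(path: str | Path) -> Geometry:
    """Read a single-frame XYZ file (count line, comment line, atom lines)."""
    lines = Path(path).read_text().splitlines()
    n = int(lines[0].split()[0])
    symbols: list[str] = []
    coords: list[list[float]] = []
    for line in lines[2 : 2 + n]:
        parts = line.split()
        symbols.append(parts[0])
        coords.append([float(x) for x in parts[1:4]])
    return Geometry(symbols, np.array(coords))


def write_xyz(geom: Geometry, path: str | Path, comment: str = "") -> None:
    lines = [str(geom.n_atoms), comment]
    for el, (x, y, z) in zip(geom.element_symbols, geom.coordinates):
        lines.append(f"{el} {x:.8f} {y:.8f} {z:.8f}")
    Path(path).write_text("\n".join(lines) + "\n")
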