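"""Graph restraining potential (GRP): embed a target connectivity in 3D.

The GRP is an empirical potential over Cartesian coordinates that is zero
exactly when the coordinates realize a target connectivity matrix with some
slack, and positive otherwise.  It decomposes into an atomic term ``W`` and
a molecular term ``V_mol``:

* ``W``: flat-bottom harmonic wells on every atom pair, keyed to the bond
  perception cutoff ``c = alpha (R_i + R_j)``.  A target-bonded pair is
  penalized when its distance exceeds ``(1 - delta) c``; a target-nonbonded
  pair when it falls below ``(1 + delta) c``.  The margin ``delta`` keeps
  minimized structures safely inside / outside the perception cutoff.
* ``V_mol``: a harmonic penalty on pairs of molecule centroids (molecules =
  connected components of the target CM) closer than a separation threshold,
  keeping distinct molecules far enough apart that no spurious bonds form.

Minimizing the GRP from a reasonable start therefore produces an approximate
geometry whose perceived CM matches the target.  The resulting structures
are crude; a :class:`RefinerHook` lets callers attach an external geometry
optimizer (e.g. a semiempirical electronic-structure method) as a second
sanitization stage.  If either stage changes the CM, the caller receives a
mismatch signal rather than a silently wrong geometry.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.optimize import minimize

from .chemgraph import (
    ConnectivityMatrix,
    CovalentRadiiTable,
    Geometry,
    connectivity_from_geometry,
)

RefinerHook = Callable[[Geometry], Geometry]


def identity_refiner(geom: Geometry) -> Geometry:
    return geom


@dataclass(frozen=True)
class GRPParams:
    k_bond: float = 10.0      # energy / A^2, bonded-pair well walls
    k_rep: float = 10.0       # nonbonded repulsion
    k_mol: float = 5.0        # inter-molecular centroid separation
    # fractional well offset delta; must satisfy (1 - delta) * alpha > 1 so
    # that ideal bond lengths (~ R_i + R_j) rest inside the bonded well
    margin: float = 0.08
    mol_separation: float = 4.0  # A, centroid distance threshold
    max_iter: int = 500
    grad_tol: float = 1e-6

    def __post_init__(self) -> None:
        if min(self.k_bond, self.k_rep, self.k_mol) <= 0:
            raise ValueError("force constants must be positive")
        if not 0 < self.margin < 1:
            raise ValueError("margin must be in (0, 1)")


class GraphMismatch(Exception):
    """GRP minimization or refinement produced a CM differing from the target."""


def grp_energy(
    coords: np.ndarray,
    target: ConnectivityMatrix,
    elements: list[str],
    radii: CovalentRadiiTable | None = None,
    params: GRPParams | None = None,
) -> tuple[float, np.ndarray]:
    """Energy and exact analytic gradient of the GRP at given coordinates."""
    radii = radii or CovalentRadiiTable()
    params = params or GRPParams()
    x = np.asarray(coords, dtype=float).reshape(-1, 3)
    n = x.shape[0]
    grad = np.zeros_like(x)
    energy = 0.0

    rvec = np.array([radii.radius(el) for el in elements])
    cut = radii.alpha * (rvec[:, None] + rvec[None, :])
    lo = (1.0 - params.margin) * cut   # bonded pairs must sit below this
    hi = (1.0 + params.margin) * cut   # nonbonded pairs must sit above this

    diff = x[:, None, :] - x[None, :, :]
    dist = np.linalg.norm(diff, axis=-1)
    np.fill_diagonal(dist, np.inf)

    bonded = target.entries == 1
    iu = np.triu_indices(n, k=1)
    for i, j in zip(*iu):
        d = dist[i, j]
        u = diff[i, j] / d
        if bonded[i, j]:
            if d > lo[i, j]:
                dev = d - lo[i, j]
                energy += 0.5 * params.k_bond * dev * dev
                f = params.k_bond * dev
                grad[i] += f * u
                grad[j] -= f * u
        else:
            if d < hi[i, j]:
                dev = hi[i, j] - d
                energy += 0.5 * params.k_rep * dev * dev
                f = -params.k_rep * dev
                grad[i] += f * u
                grad[j] -= f * u

    # V_mol: keep centroids of distinct target molecules apart
    comps = target.components()
    if len(comps) > 1:
        for a in range(len(comps)):
            for b in range(a + 1, len(comps)):
                ca, cb = comps[a], comps[b]
                ga = x[ca].mean(axis=0)
                gb = x[cb].mean(axis=0)
                dv = ga - gb
                d = float(np.linalg.norm(dv))
                if d < params.mol_separation and d > 0:
                    dev = params.mol_separation - d
                    energy += 0.5 * params.k_mol * dev * dev
                    f = -params.k_mol * dev * (dv / d)
                    grad[ca] += f / len(ca)
                    grad[cb] -= f / len(cb)
    return energy, grad


def _prepare_start(
    geom: Geometry,
    target: ConnectivityMatrix,
    radii: CovalentRadiiTable,
    params: GRPParams,
) -> np.ndarray:
    """Displace newly separated fragments along former bond axes.

    Pairs bonded in the perceived CM of the start geometry but target-
    nonbonded and in different target components get their components pushed
    apart by 1.5x the perception cutoff, giving the optimizer a downhill
    start out of the old well.
    """
    x = geom.coordinates.copy()
    current = connectivity_from_geometry(geom, radii)
    comps = target.components()
    comp_of = {}
    for ci, comp in enumerate(comps):
        for a in comp:
            comp_of[a] = ci
    rvec = np.array([radii.radius(el) for el in geom.element_symbols])
    for i in range(geom.n_atoms):
        for j in range(i + 1, geom.n_atoms):
            if (
                current.entries[i, j] == 1
                and target.entries[i, j] == 0
                and comp_of[i] != comp_of[j]
            ):
                axis = x[j] - x[i]
                norm = np.linalg.norm(axis)
                if norm == 0:
                    axis = np.array([1.0, 0.0, 0.0])
                    norm = 1.0
                shift = 1.5 * radii.alpha * (rvec[i] + rvec[j]) * axis / norm
                x[comps[comp_of[j]]] += shift
    return x


def optimize_to_graph(
    start: Geometry,
    target: ConnectivityMatrix,
    radii: CovalentRadiiTable | None = None,
    params: GRPParams | None = None,
    refiner: RefinerHook = identity_refiner,
) -> Geometry:
    """Minimize the GRP to realize ``target``, then apply the refiner hook.

    Returns the final geometry; raises :class:`GraphMismatch` if the
    minimized or refined geometry does not perceive back to ``target``.
    Deterministic for fixed start coordinates (gradient descent via L-BFGS
    with analytic gradients; no stochastic elements).
    """
    radii = radii or CovalentRadiiTable()
    params = params or GRPParams()
    if start.n_atoms != target.n_atoms:
        raise ValueError("start geometry size does not match target CM")

    x0 = _prepare_start(start, target, radii, params)

    def fun(flat: np.ndarray) -> tuple[float, np.ndarray]:
        e, g = grp_energy(flat.reshape(-1, 3), target, start.element_symbols, radii, params)
        return e, g.ravel()

    res = minimize(
        fun,
        x0.ravel(),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": params.max_iter, "gtol": params.grad_tol},
    )
    out = Geometry(list(start.element_symbols), res.x.reshape(-1, 3))
    perceived = connectivity_from_geometry(out, radii)
    if not np.array_equal(perceived.entries, target.entries):
        raise GraphMismatch("GRP minimization did not realize the target CM")

    refined = refiner(out)
    if refined.n_atoms != out.n_atoms:
        raise GraphMismatch("refiner changed the atom count")
    perceived = connectivity_from_geometry(refined, radii)
    if not np.array_equal(perceived.entries, target.entries):
        raise GraphMismatch("refiner changed the connectivity")
    return refined
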