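"""Kinetic calculators: Arrhenius, collision theory, diffusion capping,
and the precomputed rate matrix for the discrete formalism.

A calculator declares the experimental conditions it accepts (e.g. ``{"T"}``)
and maps condition values to a vector of per-reaction rate constants.  The
declaration is checked against the supplied ConditionSet before any
integration starts, so a missing condition fails fast with an actionable
message.

Units convention: unimolecular rate constants are s^-1; bimolecular are
dm^3 mol^-1 s^-1 (matching concentrations in mol dm^-3).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Protocol, Sequence

import numpy as np

from .constants import K_BOLTZMANN, N_AVOGADRO, R_GAS


class ConditionMismatchError(ValueError):
    """A calculator's declared condition is missing from the ConditionSet."""


class Calculator(Protocol):
    """Contract: declared condition names + condition values -> rate vector."""

    conditions: frozenset[str]

    @property
    def n_reactions(self) -> int: ...

    def rates(self, conditions: Mapping[str, float]) -> np.ndarray: ...


def check_conditions(calc: "Calculator", available: set[str]) -> None:
    missing = set(calc.conditions) - available
    if missing:
        raise ConditionMismatchError(
            f"calculator requires condition(s) {sorted(missing)} absent from "
            f"the ConditionSet (available: {sorted(available)})"
        )


@dataclass(frozen=True)
class DiffusionModel:
    """Diffusion-limited rate capping in a fluid of viscosity eta(T).

    The diffusion-controlled limit is taken in the Smoluchowski form
    ``k_D = 8RT / (3 eta)`` and combined with the calculated constant by
    partial diffusion control, ``1/k_r = 1/k_calc + 1/k_D`` — a smooth
    crossover that never exceeds either limit.  Unimolecular reactions have
    no encounter step and are never capped.
    """

    viscosity: Callable[[float], float] = lambda T: 1.0e-3  # Pa s (water-like)
    enabled: bool = True

    def k_d(self, T: float) -> float:
        eta = self.viscosity(T)
        if eta <= 0:
            raise ValueError("viscosity must be positive")
        return 8.0 * R_GAS * T / (3.0 * eta)


def diffusion_limit(k_calc, T: float, dm: DiffusionModel | None):
    """Cap a calculated rate constant by partial diffusion control.

    Applied exactly once per rate evaluation.  Disabled or absent model
    returns ``k_calc`` unchanged.
    """
    if dm is None or not dm.enabled:
        return k_calc
    k_calc = np.asarray(k_calc, dtype=float)
    k_d = dm.k_d(T)
    with np.errstate(divide="ignore"):
        out = np.where(k_calc > 0, 1.0 / (1.0 / np.maximum(k_calc, 1e-300) + 1.0 / k_d), 0.0)
    return out if out.ndim else float(out)


@dataclass
class ArrheniusParams:
    """Per-reaction activation energies (J/mol) and prefactors."""

    Ea: np.ndarray
    A: np.ndarray

    def __post_init__(self) -> None:
        self.Ea = np.asarray(self.Ea, dtype=float)
        self.A = np.asarray(self.A, dtype=float)
        if self.Ea.shape != self.A.shape:
            raise ValueError("Ea and A must have equal length")
        if not np.all(np.isfinite(self.Ea)):
            raise ValueError("Ea must be finite")
        if not np.all(self.A > 0):
            raise ValueError("prefactors must be positive")


def arrhenius_k(params: ArrheniusParams, T: float) -> np.ndarray:
    """k_i = A_i * exp(-Ea_i / (R T)); domain error for T <= 0."""
    if T <= 0:
        raise ValueError(f"temperature must be positive, got {T}")
    return params.A * np.exp(-params.Ea / (R_GAS * T))


@dataclass
class ArrheniusCalculator:
    """Temperature-dependent Arrhenius rates with optional diffusion capping.

    ``molecularity`` flags bimolecular reactions (the only ones capped).
    """

    params: ArrheniusParams
    molecularity: np.ndarray | None = None
    diffusion: DiffusionModel | None = None
    conditions: frozenset[str] = frozenset({"T"})

    def __post_init__(self) -> None:
        if self.molecularity is not None:
            self.molecularity = np.asarray(self.molecularity, dtype=int)
            if self.molecularity.shape != self.params.Ea.shape:
                raise ValueError("molecularity length mismatch")

    @property
    def n_reactions(self) -> int:
        return self.params.Ea.shape[0]

    def rates(self, conditions: Mapping[str, float]) -> np.ndarray:
        T = conditions["T"]
        k = arrhenius_k(self.params, T)
        if self.diffusion is not None and self.diffusion.enabled:
            capped = diffusion_limit(k, T, self.diffusion)
            if self.molecularity is not None:
                k = np.where(self.molecularity >= 2, capped, k)
            else:
                k = capped
        return k


@dataclass
class StaticCalculator:
    """Condition-independent rate constants (fixed-kinetics baseline)."""

    k: np.ndarray
    conditions: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        self.k = np.asarray(self.k, dtype=float)

    @property
    def n_reactions(self) -> int:
        return self.k.shape[0]

    def rates(self, conditions: Mapping[str, float]) -> np.ndarray:
        return self.k.copy()


@dataclass
class CollisionParams:
    """Hard-sphere species data + per-reaction activation energies."""

    radius_by_species: Mapping[str, float]      # m
    molar_mass_by_species: Mapping[str, float]  # g/mol
    Ea: Mapping[tuple, float] | None = None     # J/mol keyed by reaction key

    def __post_init__(self) -> None:
        if any(r <= 0 for r in self.radius_by_species.values()):
            raise ValueError("hard-sphere radii must be positive")
        if any(m <= 0 for m in self.molar_mass_by_species.values()):
            raise ValueError("molar masses must be positive")


def collision_k(
    cp: CollisionParams,
    species_a: str,
    species_b: str,
    Ea: float,
    T: float,
) -> float:
    """Simple collision theory rate for a bimolecular reaction A + B.

    ``k = N_A sigma sqrt(8 k_B T / (pi mu)) exp(-Ea / (R T))`` with
    ``sigma = pi (r_A + r_B)^2``; returned in dm^3 mol^-1 s^-1.
    """
    if T <= 0:
        raise ValueError("temperature must be positive")
    r_a = cp.radius_by_species[species_a]
    r_b = cp.radius_by_species[species_b]
    m_a = cp.molar_mass_by_species[species_a] * 1e-3 / N_AVOGADRO  # kg
    m_b = cp.molar_mass_by_species[species_b] * 1e-3 / N_AVOGADRO
    mu = m_a * m_b / (m_a + m_b)
    sigma = np.pi * (r_a + r_b) ** 2
    mean_speed = np.sqrt(8.0 * K_BOLTZMANN * T / (np.pi * mu))
    k_m3 = N_AVOGADRO * sigma * mean_speed * np.exp(-Ea / (R_GAS * T))
    return float(k_m3 * 1e3)  # m^3 -> dm^3


@dataclass
class RateMatrix:
    """Precalculated rate constants: one column per global stop time."""

    K_precalc: np.ndarray  # (n_reactions, n_stops)
    t_stops: np.ndarray

    def __post_init__(self) -> None:
        self.K_precalc = np.asarray(self.K_precalc, dtype=float)
        self.t_stops = np.asarray(self.t_stops, dtype=float)
        if self.K_precalc.shape[1] != self.t_stops.shape[0]:
            raise ValueError("column count must equal number of stops")
        if not np.all(np.isfinite(self.K_precalc)) or np.any(self.K_precalc < 0):
            raise ValueError("rate constants must be finite and non-negative")

    def column(self, j: int) -> np.ndarray:
        return self.K_precalc[:, j]


def precalculate_rates(
    calc: Calculator,
    csol,
    t_stops: Sequence[float],
) -> RateMatrix:
    """Evaluate the calculator at interpolated condition values of each stop."""
    check_conditions(calc, csol.names())
    t_stops = np.asarray(t_stops, dtype=float)
    cols = []
    for t in t_stops:
        cols.append(calc.rates(csol.at(t)))
    K = np.column_stack(cols) if cols else np.zeros((calc.n_reactions, 0))
    return RateMatrix(K, t_stops)
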