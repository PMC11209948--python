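"""Variable experimental-condition profiles and the discrete rate-update grid.

Three profile variants are supported:

* fixed — a constant value for the whole simulation;
* direct — the value is an explicit function of time;
* gradient — the value's time derivative is given and the profile is
  obtained by numerical integration from an initial value.

Profiles are agnostic to the quantity they represent (temperature, pressure,
volume, ...); units are annotations only.  Named profiles are bound together
in a :class:`ConditionSet` with a global end time and the rate-update
timestep ``tau_r`` that spaces the discrete-formalism stop grid.

Constancy, used to avoid unnecessary rate-update stops, is declared
structurally: each profile reports the closed intervals on which it varies
(a gradient profile varies where its gradient is nonzero; a black-box direct
function is treated as variable everywhere).  No numerical sniffing of
user functions is performed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
from scipy.integrate import solve_ivp


class ProfileError(ValueError):
    pass


class ConditionProfile:
    """Base class; subclasses implement value/gradient semantics."""

    units: str = ""

    def variable_intervals(self, t_end: float) -> list[tuple[float, float]]:
        """Closed intervals within [0, t_end] on which the value varies."""
        raise NotImplementedError


@dataclass
class FixedProfile(ConditionProfile):
    value: float
    units: str = ""

    def __post_init__(self) -> None:
        if not np.isfinite(self.value):
            raise ProfileError("fixed value must be finite")

    def variable_intervals(self, t_end: float) -> list[tuple[float, float]]:
        return []


@dataclass
class DirectProfile(ConditionProfile):
    """Value given as an explicit function of time (treated variable everywhere)."""

    function: Callable[[float], float]
    units: str = ""

    def variable_intervals(self, t_end: float) -> list[tuple[float, float]]:
        return [(0.0, t_end)]


@dataclass
class LinearDirectProfile(ConditionProfile):
    """Linear ramp X_start -> X_end at a fixed rate, then held at X_end."""

    x_start: float
    x_end: float
    rate: float
    units: str = ""

    def __post_init__(self) -> None:
        if self.rate == 0:
            raise ProfileError("rate must be nonzero")
        if (self.x_end - self.x_start) / self.rate < 0:
            raise ProfileError("rate sign inconsistent with X_start -> X_end")

    @property
    def t_end_profile(self) -> float:
        return (self.x_end - self.x_start) / self.rate

    def function(self, t: float) -> float:
        t = np.minimum(t, self.t_end_profile)
        return self.x_start + self.rate * t

    def variable_intervals(self, t_end: float) -> list[tuple[float, float]]:
        hi = min(self.t_end_profile, t_end)
        return [(0.0, hi)] if hi > 0 else []


@dataclass
class GradientProfile(ConditionProfile):
    """Value integrated from a gradient function g(t) and an initial value."""

    gradient: Callable[[float], float]
    x_start: float
    units: str = ""
    breakpoints: tuple[float, ...] = ()

    def variable_intervals(self, t_end: float) -> list[tuple[float, float]]:
        return [(0.0, t_end)]


@dataclass
class DoubleRampGradientProfile(ConditionProfile):
    """Two linear ramps separated by plateaus: gradient is r_1 on
    [t_r1_start, t_r1_end], r_2 on [t_r2_start, t_r2_end], zero elsewhere.
    """

    x_start: float
    r_1: float
    r_2: float
    t_r1_start: float
    t_r1_end: float
    t_r2_start: float
    t_r2_end: float
    units: str = ""

    def __post_init__(self) -> None:
        ts = (self.t_r1_start, self.t_r1_end, self.t_r2_start, self.t_r2_end)
        if not (0 <= ts[0] <= ts[1] <= ts[2] <= ts[3]):
            raise ProfileError("ramp times must be ordered")

    @classmethod
    def from_plateaus(
        cls,
        x_start: float,
        r_1: float,
        ramp1_length: float,
        plateau_length: float,
        r_2: float,
        ramp2_length: float,
        start_plateau: float = 0.0,
        units: str = "",
    ) -> "DoubleRampGradientProfile":
        t0 = start_plateau
        t1 = t0 + ramp1_length
        t2 = t1 + plateau_length
        t3 = t2 + ramp2_length
        return cls(x_start, r_1, r_2, t0, t1, t2, t3, units=units)

    def gradient(self, t: float) -> float:
        if self.t_r1_start <= t <= self.t_r1_end:
            return self.r_1
        if self.t_r2_start <= t <= self.t_r2_end:
            return self.r_2
        return 0.0

    def value(self, t: float) -> float:
        """Closed-form (trapezoid) antiderivative of the piecewise gradient."""
        v = self.x_start
        v += self.r_1 * (np.clip(t, self.t_r1_start, self.t_r1_end) - self.t_r1_start)
        v += self.r_2 * (np.clip(t, self.t_r2_start, self.t_r2_end) - self.t_r2_start)
        return v

    def variable_intervals(self, t_end: float) -> list[tuple[float, float]]:
        out = []
        if self.r_1 != 0 and self.t_r1_end > self.t_r1_start:
            out.append((max(0.0, self.t_r1_start), min(self.t_r1_end, t_end)))
        if self.r_2 != 0 and self.t_r2_end > self.t_r2_start:
            out.append((max(0.0, self.t_r2_start), min(self.t_r2_end, t_end)))
        return [(a, b) for a, b in out if b > a]


@dataclass
class ConditionSet:
    """Named condition profiles bound to a global timespan and update grid."""

    profiles: Mapping[str, ConditionProfile]
    t_end: float
    tau_r: float = field(default=0.0)

    def __post_init__(self) -> None:
        self.profiles = dict(self.profiles)
        if self.t_end <= 0:
            raise ProfileError("t_end must be positive")
        if self.tau_r < 0:
            raise ProfileError("tau_r must be positive when set")

    def names(self) -> set[str]:
        return set(self.profiles)


class ConditionSolution:
    """Interpolable per-condition value-of-time over [0, t_end]."""

    def __init__(self, values: Mapping[str, Callable[[float], float]], t_end: float):
        self._values = dict(values)
        self.t_end = t_end

    def __call__(self, name: str, t) -> float:
        return self._values[name](t)

    def at(self, t) -> dict[str, float]:
        return {name: float(np.asarray(f(t))) for name, f in self._values.items()}

    def names(self) -> set[str]:
        return set(self._values)

    def max_values(self, n_grid: int = 2001) -> dict[str, float]:
        """Per-condition maximum over a fine grid (for pruning bounds)."""
        tt = np.linspace(0.0, self.t_end, n_grid)
        return {
            name: float(max(float(np.asarray(f(t))) for t in tt))
            for name, f in self._values.items()
        }


def _integrate_gradient(
    gradient: Callable[[float], float],
    x0: float,
    t_end: float,
    breakpoints: tuple[float, ...],
    rtol: float,
    atol: float,
) -> Callable[[float], float]:
    """Integrate dx/dt = g(t) with dense output, restarting at breakpoints
    so that gradient discontinuities never straddle an integrator step."""
    knots = sorted({0.0, t_end, *[b for b in breakpoints if 0.0 < b < t_end]})
    segments = []
    x = x0
    for a, b in zip(knots[:-1], knots[1:]):
        # clamp gradient sampling strictly inside the segment so that the
        # value at a breakpoint (ambiguous for piecewise gradients) never
        # leaks into the neighbouring segment's quadrature
        delta = 1e-9 * (b - a)

        def g_seg(t, _a=a + delta, _b=b - delta):
            return gradient(min(max(t, _a), _b))

        sol = solve_ivp(
            lambda t, y: [g_seg(t)],
            (a, b),
            [x],
            rtol=rtol,
            atol=atol,
            dense_output=True,
            max_step=(b - a) / 4 if b > a else np.inf,
        )
        if not sol.success:
            raise ProfileError(f"gradient integration failed on [{a}, {b}]: {sol.message}")
        segments.append((a, b, sol.sol))
        x = float(sol.y[0, -1])

    def value(t: float) -> float:
        t = float(t)
        t = min(max(t, 0.0), t_end)
        for a, b, dense in segments:
            if a <= t <= b:
                return float(dense(t)[0])
        return float(segments[-1][2](segments[-1][1])[0])

    return value


def solve_profiles(
    cs: ConditionSet, rtol: float = 1e-10, atol: float = 1e-12
) -> ConditionSolution:
    """Solve every profile in a ConditionSet over [0, t_end].

    Fixed profiles become constants, direct profiles are wrapped as-is, and
    gradient profiles are numerically integrated with dense interpolable
    output (piecewise-constant gradients restart at their breakpoints, so
    the result matches the analytic antiderivative to integration tolerance).
    """
    values: dict[str, Callable[[float], float]] = {}
    for name, prof in cs.profiles.items():
        if isinstance(prof, FixedProfile):
            values[name] = (lambda v: (lambda t: v))(prof.value)
        elif isinstance(prof, (LinearDirectProfile,)):
            values[name] = prof.function
        elif isinstance(prof, DirectProfile):
            values[name] = prof.function
        elif isinstance(prof, DoubleRampGradientProfile):
            bps = (prof.t_r1_start, prof.t_r1_end, prof.t_r2_start, prof.t_r2_end)
            values[name] = _integrate_gradient(
                prof.gradient, prof.x_start, cs.t_end, bps, rtol, atol
            )
        elif isinstance(prof, GradientProfile):
            values[name] = _integrate_gradient(
                prof.gradient, prof.x_start, cs.t_end, prof.breakpoints, rtol, atol
            )
        else:
            raise ProfileError(f"unknown profile type {type(prof).__name__}")
    return ConditionSolution(values, cs.t_end)


def make_tstops(cs: ConditionSet) -> np.ndarray:
    """Global rate-update stop times for the discrete formalism.

    For every variable condition, stops are laid down at spacing ``tau_r``
    across each interval on which that condition varies: the interval start,
    every ``tau_r`` thereafter, and always the interval end even if off-grid.
    Fixed conditions (and plateau interiors) contribute nothing.  The union
    over conditions is sorted, deduplicated, and clipped to [0, t_end].
    """
    if cs.tau_r <= 0:
        raise ProfileError("tau_r must be set and positive to build t_stops")
    stops: list[float] = []
    for prof in cs.profiles.values():
        for a, b in prof.variable_intervals(cs.t_end):
            n = int(np.floor((b - a) / cs.tau_r + 1e-9))
            grid = a + cs.tau_r * np.arange(n + 1)
            stops.extend(grid.tolist())
            stops.append(b)
    if not stops:
        return np.array([])
    arr = np.array(sorted(s for s in stops if 0.0 <= s <= cs.t_end))
    # deduplicate with a tolerance scaled to the span
    tol = 1e-12 * max(1.0, cs.t_end)
    keep = np.concatenate(([True], np.diff(arr) > tol))
    return arr[keep]
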