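"""Run configuration: YAML schema, validation, defaults.

A run config has up to five blocks.  Exactly one exploration mode must be
present:

```yaml
seed: 1
log_level: INFO
explore:
  mode: direct            # or iterative
  radius: 100
  maxiters: 1000
  rxn_convergence_threshold: 5
  parallel_runs: 6
  # iterative-only keys:
  seed_conc: 0.01         # c_select, mol dm^-3
  seed_convergence_threshold: 2
  max_levels: 20
  max_carbon: 4           # RxFilter cap
system:
  smiles: [CC, CC]        # initial molecules
  library: path/to/moves.yaml   # optional; default 2-/3-atom set
conditions:
  t_end: 20.0
  tau_r: 0.02
  profiles:
    T:
      type: double_ramp
      X_start: 300.0
      r_1: 70.0
      ramp1_length: 10.0
      plateau_length: 5.0
      r_2: -70.0
      ramp2_length: 10.0
simulation:
  t_end: 20.0
  reltol: 1.0e-8
  abstol: 1.0e-12
  formalism: discrete
  tau_c: null
  c0: {CC: 1.0}
```
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .conditions import (
    ConditionSet,
    DoubleRampGradientProfile,
    FixedProfile,
    LinearDirectProfile,
)
from .explore import DirectExploreParams, IterativeExploreParams, RxFilter
from .kinetics import SimulationParams


class ConfigError(ValueError):
    pass


_EXPLORE_KEYS = {
    "mode", "radius", "maxiters", "rxn_convergence_threshold", "parallel_runs",
    "seed_conc", "seed_convergence_threshold", "max_levels", "max_carbon",
    "max_attempts", "skip_geometry",
}
_SYSTEM_KEYS = {"smiles", "library", "xyz"}
_SIM_KEYS = {"t_end", "reltol", "abstol", "formalism", "tau_c", "c0",
             "c_max_prune", "solver", "save_points"}
_PROFILE_TYPES = {"fixed", "linear", "double_ramp"}


@dataclass
class RunConfig:
    seed: int
    log_level: str
    explore_mode: str
    direct_params: DirectExploreParams | None
    iterative_params: IterativeExploreParams | None
    system_smiles: list[str]
    library_path: str | None
    conditions: ConditionSet | None
    simulation: SimulationParams | None
    raw: dict = field(default_factory=dict)


def _reject_unknown(block: dict, allowed: set[str], where: str) -> None:
    unknown = set(block) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} in {where!r} block")


def _build_profile(name: str, spec: dict) -> Any:
    ptype = spec.get("type")
    if ptype not in _PROFILE_TYPES:
        raise ConfigError(
            f"profile {name!r}: type must be one of {sorted(_PROFILE_TYPES)}, "
            f"got {ptype!r}"
        )
    if ptype == "fixed":
        return FixedProfile(float(spec["value"]), units=spec.get("units", ""))
    if ptype == "linear":
        return LinearDirectProfile(
            float(spec["X_start"]), float(spec["X_end"]), float(spec["rate"]),
            units=spec.get("units", ""),
        )
    return DoubleRampGradientProfile.from_plateaus(
        x_start=float(spec["X_start"]),
        r_1=float(spec["r_1"]),
        ramp1_length=float(spec["ramp1_length"]),
        plateau_length=float(spec["plateau_length"]),
        r_2=float(spec["r_2"]),
        ramp2_length=float(spec["ramp2_length"]),
        start_plateau=float(spec.get("start_plateau", 0.0)),
        units=spec.get("units", ""),
    )


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run config, applying documented defaults."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    _reject_unknown(raw, {"seed", "log_level", "explore", "system",
                          "conditions", "simulation"}, "root")

    seed = int(raw.get("seed", 0))
    log_level = str(raw.get("log_level", "INFO"))

    exp = raw.get("explore", {})
    _reject_unknown(exp, _EXPLORE_KEYS, "explore")
    mode = exp.get("mode", "direct")
    if mode not in ("direct", "iterative"):
        raise ConfigError(f"explore.mode must be 'direct' or 'iterative', got {mode!r}")

    direct = iterative = None
    if mode == "direct":
        if any(k in exp for k in ("seed_conc", "seed_convergence_threshold", "max_levels")):
            raise ConfigError("iterative-only keys present in a direct explore block")
        direct = DirectExploreParams(
            radius=int(exp.get("radius", 100)),
            maxiters=int(exp.get("maxiters", 1000)),
            rxn_convergence_threshold=int(exp.get("rxn_convergence_threshold", 5)),
            parallel_runs=int(exp.get("parallel_runs", 1)),
            rng_seed=seed,
            max_attempts=int(exp.get("max_attempts", 100)),
        )
    else:
        iterative = IterativeExploreParams(
            c_select=float(exp.get("seed_conc", 0.01)),
            seed_convergence_threshold=int(exp.get("seed_convergence_threshold", 2)),
            max_levels=int(exp.get("max_levels", 20)),
            rxn_convergence_threshold=int(exp.get("rxn_convergence_threshold", 5)),
            parallel_runs=int(exp.get("parallel_runs", 1)),
            rng_seed=seed,
            max_attempts=int(exp.get("max_attempts", 100)),
            filter=RxFilter(max_carbon=exp.get("max_carbon", 4)),
        )

    sys_block = raw.get("system", {})
    _reject_unknown(sys_block, _SYSTEM_KEYS, "system")
    smiles = list(sys_block.get("smiles", []))
    library_path = sys_block.get("library")
    if library_path is not None and not Path(library_path).exists():
        raise ConfigError(f"move library file not found: {library_path}")

    conditions = None
    if "conditions" in raw:
        cond = raw["conditions"]
        _reject_unknown(cond, {"t_end", "tau_r", "profiles"}, "conditions")
        profiles = {
            name: _build_profile(name, spec)
            for name, spec in cond.get("profiles", {}).items()
        }
        conditions = ConditionSet(
            profiles=profiles,
            t_end=float(cond["t_end"]),
            tau_r=float(cond.get("tau_r", 0.0)),
        )

    simulation = None
    if "simulation" in raw:
        sim = raw["simulation"]
        _reject_unknown(sim, _SIM_KEYS, "simulation")
        simulation = SimulationParams(
            t_end=float(sim["t_end"]),
            c0={str(k): float(v) for k, v in sim.get("c0", {}).items()},
            rtol=float(sim.get("reltol", 1e-8)),
            atol=float(sim.get("abstol", 1e-12)),
            formalism=sim.get("formalism", "discrete"),
            tau_c=(float(sim["tau_c"]) if sim.get("tau_c") is not None else None),
            c_max_prune=(float(sim["c_max_prune"])
                         if sim.get("c_max_prune") is not None else None),
            solver=sim.get("solver", "BDF"),
            n_out=int(sim.get("save_points", 401)),
        )

    return RunConfig(
        seed=seed,
        log_level=log_level,
        explore_mode=mode,
        direct_params=direct,
        iterative_params=iterative,
        system_smiles=smiles,
        library_path=library_path,
        conditions=conditions,
        simulation=simulation,
        raw=raw,
    )


def dump_config(cfg: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.raw, sort_keys=False))
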