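# crnkit

Automated construction and long-time-scale kinetic simulation of chemical
reaction networks (CRNs) under variable experimental conditions.

`crnkit` targets the modelling of reactive mixtures — pyrolysis, radical
degradation, and similar chemistries — where the set of relevant elementary
reactions is not known in advance. It builds the network automatically by
stochastic sampling of *graph moves* on molecular connectivity matrices,
grows it selectively using the kinetics of the network itself, and then
integrates the resulting mass-action rate equations through arbitrary
temperature (or other condition) programs.

## What it does

**Reaction generation (SE-GDS).** A molecular system is reduced to a binary
connectivity matrix **G**: atoms *i*, *j* are bonded iff
*r<sub>ij</sub>* < α(*R<sub>i</sub>* + *R<sub>j</sub>*) with covalent radii
*R* and α = 1.1. A weighted library of 2- and 3-atom graph moves (bond
formation, homolysis, atom transfer, exchange) is sampled and applied to
**G**; moves violating valence limits or forbidden patterns are rejected.
Accepted graphs are re-embedded in 3D by minimizing a graph restraining
potential (flat-bottom pair wells keyed to the bonding cutoffs plus an
inter-molecular centroid term), optionally refined by a user-supplied
geometry optimizer, and accepted only if the optimized geometry perceives
back to the proposed graph. Chaining *n<sub>r</sub>* such steps yields a
random mechanism; species are identified by canonical radical-aware SMILES.

**Network assembly.** Two algorithms:

* *direct* — sample mechanisms until no new reaction appears for
  `rxn_convergence_threshold` consecutive iterations (each iteration =
  `parallel_runs` sampler executions of radius `radius`);
* *iterative* — level-by-level growth: sample only reactions adjacent
  (radius 1) to the current *seed* species, simulate the cumulative network,
  and re-seed with every species whose maximum concentration exceeded
  `c_select`. A reaction filter (e.g. a per-species carbon cap) keeps the
  simulated model bounded. This follows only kinetically viable pathways
  and keeps networks compact.

**Kinetics.** A network compiles to the mass-action system

dc<sub>s</sub>/dt = Σ<sub>i</sub> (ν⁺<sub>is</sub> − ν⁻<sub>is</sub>)
k<sub>i</sub> Π<sub>j</sub> c<sub>j</sub><sup>ν⁻<sub>ij</sub></sup>

with analytic Jacobian, integrated by a stiff BDF solver. Rate constants
come from pluggable calculators (Arrhenius, collision theory, static, or
user-defined) that declare the conditions they accept; condition profiles
(fixed, direct functions of time, or integrated gradients such as a
double temperature ramp) are solved independently of the RRE. Two update
formalisms are provided: *continuous* (k(T(t)) evaluated inside the RHS)
and *discrete* (rates precalculated on a stop grid of spacing τ<sub>r</sub>
and swapped in at each stop). Slow reactions can be pruned when
k<sup>max</sup>·c<sub>max</sub><sup>order</sup>·t<sub>end</sub> < rtol, fast
bimolecular rates capped by partial diffusion control
(1/k<sub>r</sub> = 1/k + 3η/8RT), and very long runs split into chunks of
length τ<sub>c</sub> so that time accumulation never hits the 2⁻⁵³
relative-increment floor of 64-bit floats.

## Worked example

Explore an ethane pyrolysis network (graph-level sampling) and push it
through a 300 K → 1000 K → 300 K double temperature ramp with the shipped
surrogate bond-energy kinetics:

```python
import numpy as np
from crnkit import *
from crnkit.chemgraph import ChemSystem, species_from_smiles
from crnkit.explore import DirectExploreParams, ExploreDeps, explore_direct
from crnkit.fixtures import make_hydrocarbon_surrogate_rates
from crnkit.moves import default_library

system = ChemSystem.from_species([species_from_smiles("CC"),
                                  species_from_smiles("CC")])
deps = ExploreDeps(library=default_library(), skip_geometry=True)
params = DirectExploreParams(radius=10, maxiters=8,
                             rxn_convergence_threshold=3, rng_seed=11)
res = explore_direct(system, params, deps)
print(f"converged={res.converged}  reactions={res.network.n_reactions}"
      f"  species={res.network.n_species}")

calc = make_hydrocarbon_surrogate_rates(res.network)
profile = DoubleRampGradientProfile.from_plateaus(300.0, 140.0, 5.0, 5.0,
                                                  -140.0, 5.0)
cs = ConditionSet({"T": profile}, t_end=15.0, tau_r=0.1)
sim = SimulationParams(t_end=15.0, c0={"CC": 1.0}, rtol=1e-8)
sol = solve_chunked(build_rre(res.network), cs, calc, sim)
i10 = np.searchsorted(sol.times, 10.0) - 1
print(f"[CC] at t=0: {sol.trajectory('CC')[0]:.3f} mol/dm3")
print(f"[CC] at end of 1000 K plateau: {sol.trajectory('CC')[i10]:.3e} mol/dm3")
for sid, c in sorted(sol.final().items(), key=lambda kv: -kv[1])[:4]:
    print(f"final [{sid}] = {c:.3e} mol/dm3")
```

Output (the `maxiters=8` cap deliberately stops sampling early, so the run
is flagged unconverged):

```
converged=False  reactions=80  species=24
[CC] at t=0: 1.000 mol/dm3
[CC] at end of 1000 K plateau (t=10 s): 9.999e-01 mol/dm3
final [CC] = 9.998e-01 mol/dm3
final [CCC] = 9.326e-05 mol/dm3
final [[H][H]] = 3.389e-05 mol/dm3
final [C] = 3.161e-05 mol/dm3
```

Ethane is (slightly) net-consumed across the temperature program, with
propane, molecular hydrogen and methane as the main products — the
surrogate barriers are deliberately simple, so conversion magnitudes are
illustrative, not predictive.

The same workflow is scriptable from the shell:

```bash
crnkit explore-direct config.yaml --out network.crn
crnkit simulate config.yaml network.crn --out conc.csv
crnkit profiles config.yaml --out profiles.csv
crnkit prune config.yaml network.crn --out pruned.crn
```

See `crnkit/config.py` for the YAML schema.

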