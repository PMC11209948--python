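# Methods

This note documents the models, numerical choices, and deliberate
simplifications behind `crnkit`, in the spirit of a package methods
appendix: what is computed, under which assumptions, and what the shipped
tests do and do not demonstrate.

## Bond perception and species identity

Bonding is purely geometric: atoms *i*, *j* are bonded iff their distance
is below α(R_i + R_j), with single-bond covalent radii R (Å) and α = 1.1.
Bond order is not modelled — the connectivity matrix (CM) is binary, which
is the resolution at which graph moves operate. The radii table is a
classic crystallographic set with R_H = 0.37 Å, chosen so H₂
(r = 0.74 Å) is perceived as bonded at α = 1.1; other published radius
sets would shift marginal cases and hence perceived networks, so the table
is shipped as data and overridable per call.

Species are connected CM components, identified by RDKit canonical SMILES
built from the explicit-H fragment graph with per-atom radical counts
(max valence − degree). This makes radical species first-class
(`[CH3]`, `[H]`, `[CH2]`) and gives isomorphism-invariant identifiers;
a degree above the element's maximum valence is unrationalizable and
surfaces as a canonicalization error, which samplers treat as a move
rejection. Aromaticity, stereochemistry, formal charges, and periodic
systems are out of scope.

## Graph moves

A move is an ordered set of ±1 bond deltas over k abstract atom slots
(k = 2, 3 in the shipped library: bond formation, homolytic cleavage,
atom transfer, concerted exchange), with optional per-slot element
whitelists and a relative selection weight. Moves act on the *combined*
system CM, so bimolecular chemistry needs no special casing. Validity of
an edited CM requires (i) preconditions (distinct slot atoms, whitelists,
delta applicability), (ii) per-element degree limits (C:4, H:1, O:2, N:3
by default), and (iii) absence of any forbidden subgraph, matched exactly
on element-labelled graphs via VF2. Enumeration of applications
deduplicates assignments equal under slot symmetries of the move template
(computed as the automorphisms of the delta set plus whitelists). The
library file format is YAML, one record per move, and round-trips.

## Graph restraining potential

The GRP realizes a target CM in 3D. Its atomic term W places a flat-bottom
harmonic well on every pair keyed to the perception cutoff c = α(R_i+R_j):
target-bonded pairs are penalized above (1−δ)c, target-nonbonded pairs
below (1+δ)c. The molecular term V_mol penalizes centroids of distinct
target molecules closer than 4 Å, so separate molecules cannot
accidentally re-bond. This is the minimal potential whose zero set is
exactly "coordinates that perceive to the target CM with slack δ".

The margin default is δ = 0.08. The constraint is (1−δ)·α > 1: ideal bond
lengths sit near R_i + R_j, so with α = 1.1 any δ below 1 − 1/1.1 ≈ 0.091
keeps chemically ideal geometries at zero energy; δ = 0.1 would not.

Minimization uses L-BFGS with the exact analytic gradient (verified
against central differences at 1e−5 step to <1e−6), deterministic for a
fixed start. Fragments newly separated by the target are first displaced
along the former bond axis by 1.5× the cutoff to give the optimizer a
downhill start. A `RefinerHook` (Geometry → Geometry, identity by default)
is applied after minimization as a second sanitization stage, standing in
for an electronic-structure re-optimization; if either stage changes the
perceived CM, the caller receives a mismatch signal, never a silently
wrong geometry. GRP energies are not comparable to quantum-chemical
energies and no transition-state search is attempted.

## SE-GDS sampling

One step: draw a move by weight, enumerate its valid applications on the
current CM, pick one uniformly, validate (valence, forbidden patterns,
molecularity ≤ 2 on both sides, species canonicalizability), then
regenerate geometry through the GRP + refiner. Any failure restores the
CM and redraws, up to `max_attempts` (default 100); exhaustion truncates
the mechanism rather than aborting the run, with attempt counts logged.
Rejections never consume radius: `n_r` counts accepted steps. Runs are
bit-reproducible given the seed (a single `numpy` Generator drives move,
assignment, and embedding choices). `skip_geometry=True` bypasses the
3D round-trip for graph-level sampling — used by enumeration oracles and
large sweeps where the geometric filter is not the question.

Reactions are multiset diffs between consecutive states (spectators
dropped); steps with no net change are discarded at extraction. Element
balance is asserted exactly — integer arithmetic, no tolerance. Each
discovered reaction is stored directionally, and exploration registers
the reverse as its own reaction, since forward and backward constants are
independent in the kinetic model.

## Exploration

*Direct*: iterations of `parallel_runs` sampler executions (independent
derived seeds, for reproducibility) at radius `radius`; convergence after
`rxn_convergence_threshold` consecutive iterations adding nothing, i.e.
threshold × parallel_runs × radius reactions sampled without change.

*Iterative*: per level, radius-1 sampling over all unimolecular seed
systems and unordered seed pairs (including self-pairs) until level
convergence (same counter logic); the cumulative network is then filtered
(`RxFilter`, default: drop reactions touching species with > 4 carbons —
removed reactions stay in provenance, so raising the cap needs no
resampling), simulated with the discrete formalism, and re-seeded with
species whose c_max strictly exceeds `c_select` (strict inequality is the
documented boundary convention; a tie is excluded). Termination: seed
system unchanged for `seed_convergence_threshold` consecutive levels
(default 2), `max_levels`, or an empty seed set — the last is an
under-exploration condition and is reported as a warning rather than
silently accepted. Seeds may re-enter at later levels whenever their
c_max rises above the cutoff again.

## Condition profiles

Profiles are value-typed (fixed), direct functions of time, or gradient
functions integrated from an initial value; units are annotations only
and no feedback from concentrations to conditions is supported.
Constancy is declared *structurally*: each profile reports the intervals
on which it varies (a double ramp varies only on its two ramps; a
black-box direct function is variable everywhere). No numerical sniffing
of user callables — this keeps the stop grid deterministic and testable.

Gradient profiles integrate with dense output, restarting at declared
breakpoints, and gradient evaluations are clamped 1e−9 of a segment
inside its ends so that the ambiguous value *at* a breakpoint of a
piecewise gradient never leaks into the neighbouring segment's
quadrature; double ramps then match their closed-form trapezoid
antiderivative to better than 1e−8 relative, and balanced ramps return
exactly to the start value within integration tolerance.

The discrete-formalism stop grid lays τ_r-spaced stops across each
variable interval of each condition: interval start, every τ_r after,
and always the interval end even if off-grid (boundary-inclusive
convention, documented here since several reasonable variants exist).
Fixed conditions and plateau interiors contribute nothing; the union is
sorted and deduplicated at 1e−12·t_end.

## Rate calculators

Calculators declare the condition names they accept and map condition
values to a per-reaction rate vector; the declaration is checked against
the ConditionSet before integration starts, failing with the missing
name. Shipped: Arrhenius (k = A·exp(−Ea/RT)), static, and simple
collision theory (k = N_A σ √(8k_BT/πμ)·exp(−Ea/RT), σ = π(r_A+r_B)²,
output dm³ mol⁻¹ s⁻¹ — bimolecular only; unimolecular steps need A-based
rates). Constants are CODATA 2018, pinned in one table. Units:
unimolecular s⁻¹, bimolecular dm³ mol⁻¹ s⁻¹ against concentrations in
mol dm⁻³.

Diffusion capping uses the Smoluchowski diffusion-controlled limit
k_D = 8RT/3η and the standard partial-diffusion-control harmonic
combination 1/k_r = 1/k + 1/k_D, applied exactly once per rate
evaluation and never to unimolecular reactions (no encounter step).
Both the k_D prefactor and the combination rule are standard choices and
overridable. Harmonic TST with partition functions, falloff kinetics,
and entropic corrections are out of scope.

The surrogate hydrocarbon parameterization (fixtures) exists so that
C/H demonstrations run end-to-end: homolysis barriers from a mean
bond-enthalpy table (H–H 436, C–H 413, C–C 347 kJ/mol), barrierless
recombination, an Evans–Polanyi-style linear rule for transfers
(Ea = max(0, 40 kJ/mol + 0.5·ΔBDE)), 150 kJ/mol fallback with a logged
warning for anything unclassified, prefactors 1e15 s⁻¹ / 1e10
dm³ mol⁻¹ s⁻¹. It is total (every reaction gets finite parameters) and
deliberately crude: demo outputs are regression-tested for qualitative
invariants (net ethane decomposition at 1000 K) only.

## Kinetic integration

`build_rre` compiles a deduplicated network into ν⁻/ν⁺ stoichiometries,
a vectorizable mass-action RHS, and an analytic Jacobian whose nonzeros
follow the stoichiometric couplings (verified against central
differences). The default integrator is scipy's BDF (implicit,
adaptive-order, multistep — appropriate for the orders-of-magnitude rate
spans of real CRNs); the solver is pluggable by name. A+A→B carries the
stoichiometric factor 2 in dA/dt = −2kA².

*Continuous formalism*: the RHS evaluates k(conditions(t)) at every
integrator step. *Discrete formalism*: rates are precalculated at every
stop (matrix K_precalc, one column per stop), and integration proceeds
segment-by-segment between consecutive stops with the solver
reinitialized at each discontinuity — the integrator always lands
exactly on a stop, so no step straddles a parameter change. Between
stops the kinetics are static, so with coarse τ_r trajectories visibly
relax toward the frozen-k steady state before each update; with τ_r fine
relative to the condition program the two formalisms agree closely
(measured: ~5e−6 relative at τ_r = t_end/1000 on the reversible
Arrhenius toy under a double ramp, decreasing monotonically with τ_r).

*Pruning*: reaction i is removed iff k_i^max·c_max^order·t_end < rtol,
i.e. its largest possible concentration increment over the whole run is
below solver precision. k_i^max is taken as the per-reaction maximum of
the calculator over a 201-point grid of the solved profiles (exact for
rate laws monotone in the conditions, e.g. Arrhenius in T). The default
concentration bound is 2× the total initial concentration, configurable.

*Chunking*: a run splits into chunks of length τ_c; each chunk restarts
the inner solve at local time 0 from the previous final concentrations,
and t_global = n_c·τ_c + t_local is maintained as an exact bookkeeping
identity. Global stops map into chunk n_c as t − n_c·τ_c for
t ∈ (n_c·τ_c, (n_c+1)·τ_c]; chunk boundaries colliding with stops
deduplicate. The rationale: accumulating a step against t_global fails
once the step is below t_global·ε with ε = 2⁻⁵³ for 64-bit floats, so
accumulating against the small t_local instead arbitrarily extends the
usable precision. The identity and the mapping are unit-tested; an
actual underflow run is not constructed in the test suite (it requires
extreme time-scale separations that add nothing to the correctness
argument).

Solution objects carry the output-grid trajectories, condition traces,
and per-species c_max (the quantity driving seed selection). Asserted on
every fixture solve: element totals drift < 1e−6 relative,
concentrations ≥ −atol, and fixed-condition reversible systems reach
detailed-balance steady states (‖dc/dt‖∞ < 1e−8·max c after ~100
relaxation times).

## Synthetic fixtures: what they show and what they don't

The five-species reversible toy (A+B⇌C, C⇌D, D+A⇌E over two abstract
elements) checks equilibria against an independent root-finding oracle;
the H₂/H chemistry is small enough that the *entire* move space can be
enumerated deterministically, which is what makes the three-way
exploration equivalence (direct = iterative = enumeration) a sharp test;
random stiff networks (two mass tiers, log-uniform rate spans) exercise
the stiff-solver path. None of these emulate real thermochemistry,
pressure dependence, or transport; passing tests demonstrate the
*machinery* — conservation, convergence accounting, formalism agreement,
reproducibility — not predictive accuracy for any laboratory system.
Problem sizes in the test suite and the acceptance script (H₂/H and
2-ethane systems, toy RREs, 10–16-reaction stiff nets) are chosen to
keep the full run in tens of seconds while still covering every code
path end-to-end.

## Known limitations

- No double-ended (target-product) searches; sampling is single-ended.
- No template/SMARTS reaction rules; reactivity is expressed only through
  graph moves.
- The continuous formalism requires rate laws expressible as functions of
  instantaneous condition values.
- Rate constants may not depend on concentrations (no feedback-coupled
  conditions).
- Geometry embedding quality is limited by the GRP's flat-bottom wells;
  the RefinerHook is the intended attachment point for a real optimizer.
- The surrogate kinetic table is for demonstrations; quantitative work
  needs user-supplied Ea/A per reaction.
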