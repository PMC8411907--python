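# Methods

This note records the semantics sbmlkit implements, the conventions chosen
where the format leaves room, the numerical choices, and what the test
models do and do not exercise.

## Scope of the format support

The toolkit reads and writes SBML Level 3 core (Version 1 and Version 2
namespaces on input; Version 2 on output by default, Version 1 on request)
plus two packages: Flux Balance Constraints (`fbc`, version 2 namespace)
and Qualitative Models (`qual`, version 1 namespace). Package
declarations carry a `required` attribute; a document that declares an
*unrecognized* package as required cannot be interpreted faithfully, so
reading it is a hard error by default and a diagnostic in permissive mode
(with the package content preserved opaquely and re-emitted verbatim).
For the two supported packages the writer declares `required="false"`,
since their content does not change the core-math interpretation of other
constructs; the reader accepts either value with a diagnostic on mismatch.

Out of scope by design: hierarchical composition and the other packages
(`comp`, `multi`, `groups`, `layout`, `render`, `distrib`, `spatial`,
`arrays`), algebraic rules (no DAE solver), the `delay` and `rateOf`
csymbols, `conversionFactor` attributes, and `fast` reactions. All are
rejected with explicit diagnostics rather than being silently misread.

## MathML subset

Math containers hold content MathML restricted to the operators commonly
used in Level 3 models: `plus`, `minus` (unary/binary), `times`, `divide`,
`power`, `root`, `exp`, `ln`, `log` (optional logbase), `abs`, `floor`,
`ceiling`, the relations `eq neq lt leq gt geq`, the logic `and or xor
not`, and `sin cos tan`. All numeric literals — including the `integer`,
`rational` and `e-notation` forms of `<cn>` — are folded to IEEE doubles.
Booleans and numbers are distinct domains and never coerce; mixing them is
a type error. This is stricter than some tools but prevents silent
misinterpretation of, e.g., a relational result used as a factor.
Piecewise evaluation returns the value of the *first* true condition, so
overlapping conditions make piece order significant (this is asserted by a
test). Function definitions are lambda bodies inlined (capture-free,
cycle-checked) before compilation, evaluation, or unit analysis.

## Validation catalog

Findings are data, not exceptions. The rule numbering (`E1001`–`E1009`
core, `W2001`/`W2002` units, `E3001`/`E3002` fbc, `E4001`/`E4002` qual) is
this toolkit's own stable catalog, documented in
`sbmlkit/validation.py`; the authoritative numbered rule sets live in the
specification documents of the format itself and are not reproduced.
Unit checks are warnings, never errors: units in real-world models are
frequently absent, and dimensional analysis is a verification aid.
Symbols without declared units propagate an "undeclared" result silently;
only a mismatch between two *declared* unit vectors warns. Unit algebra:
multiplication adds base-unit exponent maps, division subtracts, integer
constant powers scale; addition and comparisons require identical unit
vectors (including the scale/multiplier factor, compared at 1e-9 relative
tolerance).

Parsing is lenient where validation is strict: Level 3 has no defaults for
`constant`, `reversible`, `boundaryCondition`, `hasOnlySubstanceUnits`, so
missing required attributes are recorded on the element and reported as
E1006, while the reader continues with a best-effort document.

## ODE semantics

Internal state is always **amounts**; concentrations are a derived view
(amount / compartment size). This removes any ambiguity when compartment
sizes change, at the cost of one conversion when a rate rule or event
targets a concentration-view species. Inside kinetic laws a species symbol
evaluates to its concentration unless `hasOnlySubstanceUnits=true`; the
kinetic law itself is the reaction extent rate (substance/time).
Boundary-condition species get a zero stoichiometry row; constant species
are frozen bindings. Initial assignments are evaluated once at t = 0 from
the literal initial values and override them. Assignment rules are
topologically sorted by dependency; a cycle is a compile error (no
algebraic solving). A rate rule on a concentration-view species in a
non-constant compartment is rejected rather than guessed.

Integration uses LSODA (stiff-capable, adaptive) via scipy with
caller-supplied `rtol`/`atol` (defaults 1e-8/1e-10). Events are detected
by scanning the solver's dense output at the solver's own step points plus
midpoints for boolean trigger flips, then bisecting the flip to within
1e-9 time units. Delayed events are queued at trigger time + delay; with
`useValuesFromTriggerTime` the assignment values are frozen at the trigger
instant. Non-persistent triggers cancel their pending firings when the
trigger reverts (checked at the same sampling resolution — a trigger
excursion entirely inside one solver step could in principle be missed;
the midpoint sampling makes this unlikely at the step sizes LSODA takes).
Event priorities are not supported; simultaneous firings execute in
document order and leave a warning on the trajectory. A runaway guard
aborts after 10^6 firings. If an event assigns a compartment size while
concentration-view species exist, amounts are held fixed and
concentrations jump — a convention, documented here because the format
itself does not fix it.

Reported columns are one per species (amount if
`hasOnlySubstanceUnits`, else concentration) plus rule targets, on an
equally spaced grid including t = 0 and t_end; CSV export has `time`
first, then SIds in document order.

## Stochastic semantics

The Gillespie direct method interprets each kinetic law, evaluated with
current integer amounts substituted, directly as the propensity. No
mass-action rescaling from concentration units is attempted — converting
concentration-based laws involves volume factors the document may not
determine, so such models are rejected (`hasOnlySubstanceUnits=true` is a
precondition, as are integer amounts and stoichiometries and the absence
of rules and events). Waiting times are exponential with rate equal to
the total propensity; the next reaction is chosen proportionally.
Randomness comes from `numpy.random.Generator(PCG64)`; the generator
identity, seed, and replicate index are recorded in the trajectory
metadata (and a JSON sidecar next to CSV output), and replicate streams
are spawned from the seed so each replicate is independent yet exactly
reproducible.

## Flux balance analysis

The LP is built in "strict" fbc style: bounds must be references to
`constant=true` parameters (anything else is E3001). Mass-balance rows
S·v = 0 cover species that are neither boundary-condition nor constant.
The HiGHS backend of `scipy.optimize.linprog` solves the LP. Gene-product
associations are boolean trees; a knockout clamps both bounds of every
reaction whose association evaluates false to zero. FVA re-optimizes each
reaction's flux subject to the objective held within a caller-chosen
fraction of its optimum. Alternate optima are real: tests assert
objective values and feasibility, never a particular flux vector, except
where the optimum is provably unique (the chain's bottleneck). Chemical
formula and charge attributes are parsed and stored; elemental-balance
checking is not performed beyond that.

## Qualitative dynamics

A transition's ordered function terms are evaluated with input levels
bound as integers; the first boolean-true term's result level is the
target, else the default term. A species that is constant, or the output
of no transition, keeps its level; a species output by two transitions is
an error (ambiguous regulation). Synchronous updates move every species
to its target at once (out-degree exactly 1); asynchronous updates are
**unitary** — one species at a time, one level toward its target — the
common convention for multivalued logical models, chosen here and
documented because the format does not fix the update scheme. The state
space is enumerated explicitly (default cap 2^20 states); attractors are
the terminal strongly connected components of the state-transition graph,
computed with networkx and cross-checked in tests against a brute-force
reachability oracle. Input `sign`/`threshold` attributes are stored and
validated but do not affect dynamics — function terms are authoritative.
Priority classes and `transitionEffect="consumption"` on inputs are
rejected with a diagnostic.

## Canonical serialization

The writer emits attributes sorted lexicographically, two-space
indentation, and never self-closes ListOf containers; doubles use the
shortest representation that reparses identically. This makes
write∘read∘write byte-idempotent — a testable canonical form — while raw
(unrecognized) annotation fragments are preserved and re-emitted
byte-identically.

## Synthetic models and what the tests show

All test inputs are generated programmatically. The named fixtures carry
the canonical parameters used in the documentation (decay k=0.5, A0=10;
Michaelis–Menten Vmax=1, Km=0.5, S0=10; chain capacities 10/1000/1000;
Boolean toggle and negative-feedback circuits; death process k=0.5,
A0=100). `random_network(n_species, n_reactions, seed)` draws mass-action
reactions with 1–2 reactants/products uniformly and rate constants
log-uniform in [1e-2, 1e1] — species counts and rates typical of small
biochemical test models; `random_fbc_network` draws bounded
constraint-based networks with zero always feasible. Problem sizes in the
test and acceptance runs (50 round-trip networks, 1000 stochastic
replicates, 10^4 waiting times, 25 LP instances against the vertex
oracle, 20 conservation networks) were chosen so each statistical check
has clear resolving power while the whole suite stays interactive.

These models are small, well-scaled and mostly mass-action. Passing tests
demonstrate correctness of the implemented semantics on such models; they
do not probe genome-scale numerics (LP degeneracy at 10^4 reactions),
badly conditioned kinetics, deeply nested event cascades, or the long tail
of annotation conventions found in curated repositories.

## Known limitations

- No algebraic rules / DAEs; no `delay`/`rateOf`; no event priorities.
- SSA implements the direct method only (no tau-leaping or next-reaction),
  and does not support rules or events.
- Unit analysis covers the operator subset above; exponents must be
  integer constants for dimensioned bases.
- The validator catalog is this artifact's own; it is not a reproduction
  of the official numbered rule set.
- State-transition graphs are explicit; symbolic (decision-diagram)
  representations are out of scope, capping practical models near the
  2^20-state default limit.
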