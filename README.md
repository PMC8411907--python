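# sbmlkit

A self-contained Python toolkit for **SBML Level 3**, the XML exchange
format for computational models of biological processes. It provides:

- an in-memory **document model** for Level 3 core (compartments, species,
  parameters, reactions, rules, initial assignments, events, function and
  unit definitions, SBO/CV-term annotations);
- a **reader/writer** that handles package namespace declarations — a
  document declaring an unknown package with `required="true"` is refused
  (or read permissively with a diagnostic), and output is canonical so
  write∘read∘write is byte-stable;
- a **validator** with a stable catalog of structural, referential and
  unit-consistency rules (`E1001`–`E4002`, `W2001`/`W2002`);
- executable semantics for three modeling frameworks, plus logical models:
  - **ODE time courses**: d(amount of s)/dt = Σ_r ν_{s,r}·v_r with
    SBML's concentration/amount conventions, rules, initial assignments and
    discrete events (LSODA, event crossings refined to 1e-9);
  - **Gillespie stochastic simulation** (direct method) over integer
    amounts, with a named seedable generator (PCG64);
  - **flux balance analysis** (`fbc` package): S·v = 0, lb ≤ v ≤ ub,
    maximize/minimize c·v, with gene-product knockouts and flux
    variability analysis;
  - **qualitative models** (`qual` package): multi-level logical species,
    function-term transitions, synchronous/asynchronous state-transition
    graphs, and attractors as terminal strongly connected components.

Intended users: systems-biology tool builders and modelers who need a
transparent, dependency-light reference implementation of the format's
core semantics for testing, teaching, and small-to-medium models.

## Worked example

```python
from sbmlkit import (make_fixture, build_ode_system, simulate_ode,
                     solve_fba, flux_variability, build_stg, find_attractors,
                     validate_document)

doc = make_fixture("decay")          # A -> B, v = k*A, k = 0.5, A(0) = 10
print(validate_document(doc))        # []  (validator-clean)
tc = simulate_ode(build_ode_system(doc.model), t_end=2.0, n_out=5,
                  rtol=1e-9, atol=1e-12)
print(tc.to_csv())
```

```
time,A,B
0.0,10.0,0.0
0.5,7.7880078311832515,2.2119921688167477
1.0,6.065306596919227,3.9346934030807734
1.5,4.723665526200778,5.276334473799222
2.0,3.678794410737455,6.321205589262546
```

The trajectory matches the closed form A(t) = 10·e^{-0.5t}; at t = 2 the
amount is 10/e ≈ 3.6787944, and A+B stays at 10 (mass conservation).

Constraint-based analysis of the linear chain `in → A → B → out` with
capacities 10/1000/1000, maximizing the exit flux:

```python
chain = make_fixture("chain_fbc")
res = solve_fba(chain.model)
print(res.status, res.objective_value, res.fluxes)
# optimal 10.0 {'v1': 10.0, 'v2': 10.0, 'v3': 10.0}
print(flux_variability(chain.model, 1.0)["v2"])
# {'min': 10.0, 'max': 10.0}          # the bottleneck pins the flux
print(solve_fba(chain.model, knockouts={"g1"}).objective_value)
# -0.0                                 # knocking out g1 shuts the chain
```

Logical dynamics of the Boolean toggle switch (A′ = ¬B, B′ = ¬A) under
asynchronous updates — two fixed points, as expected for a bistable switch:

```python
stg = build_stg(make_fixture("toggle_qual").model, "asynchronous")
for a in find_attractors(stg):
    print(a)
# Attractor(states=((0, 1),), fixed_point=True)
# Attractor(states=((1, 0),), fixed_point=True)
```

A command-line interface wraps the same operations
(`sbmlkit validate|simulate|fba|qual|fixture|info`); exit codes are 0
(success), 1 (validation errors), 2 (unsupported construct), 3 (runtime
failure).

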