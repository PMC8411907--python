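"""Canonical test models and a seeded random-network generator.

Every generator returns a validator-clean :class:`~sbmlkit.model.Document`
and is deterministic for identical arguments, so serialized output is
byte-identical across calls.  The named fixtures carry the canonical
parameters used throughout the documentation and tests:

``decay``
    irreversible conversion A -> B with mass-action law k*A, k = 0.5,
    A(0) = 10 (amounts; unit compartment), so A(t) = 10 e^{-0.5 t}.
``michaelis``
    S -> P with Michaelis-Menten law Vmax*S/(Km+S), Vmax = 1, Km = 0.5,
    S(0) = 10; S+P is conserved at 10.
``decay_event``
    the decay model plus a discrete event: when t >= 1, A := 10.
``chain_fbc``
    linear flux chain in -> A -> B -> out with capacities 10/1000/1000,
    objective: maximize the exit flux; gene product g1 controls the A -> B
    step.  The optimum is 10, pinned by the intake capacity.
``toggle_qual``
    Boolean toggle switch A' = NOT B, B' = NOT A.
``negfb_qual``
    Boolean negative-feedback loop A' = NOT B, B' = A (one 4-cycle under
    synchronous updates).
``ssa_death``
    pure death process A -> 0 with propensity k*A, k = 0.5, A(0) = 100.
"""

from __future__ import annotations

import numpy as np

from . import fbc as fbc_mod
from . import qual as qual_mod
from .mathml import apply_op, num, sym, TimeSymbol
from .model import (
    Document,
    Event,
    EventAssignment,
    KineticLaw,
    Model,
    Rule,
    SpeciesReference,
    Trigger,
)

FIXTURE_NAMES = (
    "decay", "michaelis", "decay_event", "chain_fbc", "toggle_qual",
    "negfb_qual", "ssa_death",
)


def make_fixture(name: str, params: dict | None = None) -> Document:
    """Build one of the canonical models, optionally overriding parameters."""
    builders = {
        "decay": _decay,
        "michaelis": _michaelis,
        "decay_event": _decay_event,
        "chain_fbc": _chain_fbc,
        "toggle_qual": _toggle_qual,
        "negfb_qual": _negfb_qual,
        "ssa_death": _ssa_death,
    }
    if name not in builders:
        raise ValueError(
            f"unknown fixture {name!r}; available: {', '.join(FIXTURE_NAMES)}"
        )
    return builders[name](params or {})


def _mass_action_species(m: Model, sid: str, amount: float) -> None:
    m.add_species(sid, compartment="c", initial_amount=amount,
                  has_only_substance_units=True, boundary_condition=False,
                  constant=False)


def _decay(params: dict) -> Document:
    k = params.get("k", 0.5)
    a0 = params.get("A0", 10.0)
    m = Model(id="decay")
    m.add_compartment("c", size=1.0, spatial_dimensions=3.0, constant=True)
    _mass_action_species(m, "A", a0)
    _mass_action_species(m, "B", 0.0)
    m.add_parameter("k", value=k, constant=True)
    m.add_reaction(
        "conv",
        reversible=False,
        reactants=[SpeciesReference("A", 1.0, constant=True)],
        products=[SpeciesReference("B", 1.0, constant=True)],
        kinetic_law=KineticLaw(math=apply_op("times", sym("k"), sym("A"))),
    )
    return Document(model=m)


def _michaelis(params: dict) -> Document:
    vmax = params.get("Vmax", 1.0)
    km = params.get("Km", 0.5)
    s0 = params.get("S0", 10.0)
    m = Model(id="michaelis")
    m.add_compartment("c", size=1.0, spatial_dimensions=3.0, constant=True)
    _mass_action_species(m, "S", s0)
    _mass_action_species(m, "P", 0.0)
    m.add_parameter("Vmax", value=vmax, constant=True)
    m.add_parameter("Km", value=km, constant=True)
    m.add_reaction(
        "catalysis",
        reversible=False,
        reactants=[SpeciesReference("S", 1.0, constant=True)],
        products=[SpeciesReference("P", 1.0, constant=True)],
        kinetic_law=KineticLaw(
            math=apply_op(
                "divide",
                apply_op("times", sym("Vmax"), sym("S")),
                apply_op("plus", sym("Km"), sym("S")),
            )
        ),
    )
    return Document(model=m)


def _decay_event(params: dict) -> Document:
    doc = _decay(params)
    t_fire = params.get("t_fire", 1.0)
    reset = params.get("reset", 10.0)
    doc.model.events.append(
        Event(
            id="refill",
            trigger=Trigger(
                math=apply_op("geq", TimeSymbol(), num(t_fire)),
                initial_value=True,
                persistent=True,
            ),
            use_values_from_trigger_time=False,
            assignments=[EventAssignment(variable="A", math=num(reset))],
        )
    )
    return doc


def _chain_fbc(params: dict) -> Document:
    cap_in = params.get("cap_in", 10.0)
    cap_mid = params.get("cap_mid", 1000.0)
    cap_out = params.get("cap_out", 1000.0)
    m = Model(id="chain_fbc")
    m.add_compartment("c", size=1.0, spatial_dimensions=3.0, constant=True)
    _mass_action_species(m, "A", 0.0)
    _mass_action_species(m, "B", 0.0)
    m.add_parameter("lb_zero", value=0.0, constant=True)
    m.add_parameter("cap_in", value=cap_in, constant=True)
    m.add_parameter("cap_mid", value=cap_mid, constant=True)
    m.add_parameter("cap_out", value=cap_out, constant=True)
    m.add_reaction(
        "v1", reversible=False,
        products=[SpeciesReference("A", 1.0, constant=True)],
        lower_flux_bound="lb_zero", upper_flux_bound="cap_in",
    )
    m.add_reaction(
        "v2", reversible=False,
        reactants=[SpeciesReference("A", 1.0, constant=True)],
        products=[SpeciesReference("B", 1.0, constant=True)],
        lower_flux_bound="lb_zero", upper_flux_bound="cap_mid",
        gene_association=fbc_mod.gpa_ref("g1"),
    )
    m.add_reaction(
        "v3", reversible=False,
        reactants=[SpeciesReference("B", 1.0, constant=True)],
        lower_flux_bound="lb_zero", upper_flux_bound="cap_out",
    )
    m.fbc = fbc_mod.FbcExtension(
        objectives=[
            fbc_mod.Objective(id="obj", type="maximize", terms=[("v3", 1.0)])
        ],
        active_objective="obj",
        gene_products=[fbc_mod.GeneProduct(id="g1", label="gene_1")],
        strict=True,
    )
    return Document(model=m)


def _boolean_not(target_of: str) -> list[qual_mod.FunctionTerm]:
    # result 1 exactly when the regulator is 0
    return [
        qual_mod.FunctionTerm(
            result_level=1, math=apply_op("eq", sym(target_of), num(0))
        )
    ]


def _toggle_qual(params: dict) -> Document:
    m = Model(id="toggle_qual")
    qm = qual_mod.QualModel()
    qm.species.append(qual_mod.QualSpecies(id="A", max_level=1,
                                           initial_level=1, constant=False))
    qm.species.append(qual_mod.QualSpecies(id="B", max_level=1,
                                           initial_level=0, constant=False))
    qm.transitions.append(
        qual_mod.QualTransition(
            id="tA",
            inputs=[qual_mod.QualInput(qual_species="B", sign="negative")],
            outputs=[qual_mod.QualOutput(qual_species="A")],
            function_terms=_boolean_not("B"),
            default_term=qual_mod.DefaultTerm(result_level=0),
        )
    )
    qm.transitions.append(
        qual_mod.QualTransition(
            id="tB",
            inputs=[qual_mod.QualInput(qual_species="A", sign="negative")],
            outputs=[qual_mod.QualOutput(qual_species="B")],
            function_terms=_boolean_not("A"),
            default_term=qual_mod.DefaultTerm(result_level=0),
        )
    )
    m.qual = qm
    return Document(model=m)


def _negfb_qual(params: dict) -> Document:
    m = Model(id="negfb_qual")
    qm = qual_mod.QualModel()
    qm.species.append(qual_mod.QualSpecies(id="A", max_level=1,
                                           initial_level=0, constant=False))
    qm.species.append(qual_mod.QualSpecies(id="B", max_level=1,
                                           initial_level=0, constant=False))
    qm.transitions.append(
        qual_mod.QualTransition(
            id="tA",
            inputs=[qual_mod.QualInput(qual_species="B", sign="negative")],
            outputs=[qual_mod.QualOutput(qual_species="A")],
            function_terms=_boolean_not("B"),
            default_term=qual_mod.DefaultTerm(result_level=0),
        )
    )
    qm.transitions.append(
        qual_mod.QualTransition(
            id="tB",
            inputs=[qual_mod.QualInput(qual_species="A", sign="positive")],
            outputs=[qual_mod.QualOutput(qual_species="B")],
            function_terms=[
                qual_mod.FunctionTerm(
                    result_level=1, math=apply_op("eq", sym("A"), num(1))
                )
            ],
            default_term=qual_mod.DefaultTerm(result_level=0),
        )
    )
    m.qual = qm
    return Document(model=m)


def _ssa_death(params: dict) -> Document:
    k = params.get("k", 0.5)
    a0 = params.get("A0", 100.0)
    m = Model(id="ssa_death")
    m.add_compartment("c", size=1.0, spatial_dimensions=3.0, constant=True)
    _mass_action_species(m, "A", a0)
    m.add_parameter("k", value=k, constant=True)
    m.add_reaction(
        "death", reversible=False,
        reactants=[SpeciesReference("A", 1.0, constant=True)],
        kinetic_law=KineticLaw(math=apply_op("times", sym("k"), sym("A"))),
    )
    return Document(model=m)


# ---------------------------------------------------------------------------
# Random networks
# ---------------------------------------------------------------------------


def random_network(n_species: int, n_reactions: int, seed: int) -> Document:
    """Seeded random mass-action network over amount-based species.

    Each reaction draws 1-2 distinct reactants and 1-2 distinct products
    uniformly, with a rate constant log-uniform in [1e-2, 1e1]; the kinetic
    law is k * product(reactant amounts).  Output is always validator-clean
    and byte-identical for the same arguments.
    """
    if n_species < 1 or n_reactions < 1:
        raise ValueError("need at least one species and one reaction")
    rng = np.random.default_rng(seed)
    m = Model(id=f"random_s{n_species}_r{n_reactions}_seed{seed}")
    m.add_compartment("c", size=1.0, spatial_dimensions=3.0, constant=True)
    sids = [f"S{i+1}" for i in range(n_species)]
    for sid in sids:
        _mass_action_species(m, sid, float(rng.integers(5, 21)))
    for j in range(n_reactions):
        k = float(10.0 ** rng.uniform(-2.0, 1.0))
        pid = f"k{j+1}"
        m.add_parameter(pid, value=k, constant=True)
        n_react = int(rng.integers(1, 3))
        n_prod = int(rng.integers(1, 3))
        reactants = list(rng.choice(n_species, size=min(n_react, n_species),
                                    replace=False))
        products = list(rng.choice(n_species, size=min(n_prod, n_species),
                                   replace=False))
        law = apply_op(
            "times", sym(pid), *[sym(sids[i]) for i in reactants]
        )
        m.add_reaction(
            f"r{j+1}", reversible=False,
            reactants=[SpeciesReference(sids[i], 1.0, constant=True)
                       for i in reactants],
            products=[SpeciesReference(sids[i], 1.0, constant=True)
                      for i in products],
            kinetic_law=KineticLaw(math=law),
        )
    return Document(model=m)


def random_fbc_network(n_species: int, n_reactions: int, seed: int) -> Document:
    """Seeded random constraint-based network with finite bounds.

    Stoichiometries are drawn like :func:`random_network`; every reaction
    gets bounds [0 or -cap, cap] via constant parameters (zero is always
    feasible), and the active objective maximizes a random non-trivial
    combination of reaction fluxes.
    """
    rng = np.random.default_rng(seed)
    m = Model(id=f"randfbc_s{n_species}_r{n_reactions}_seed{seed}")
    m.add_compartment("c", size=1.0, spatial_dimensions=3.0, constant=True)
    sids = [f"M{i+1}" for i in range(n_species)]
    for sid in sids:
        m.add_species(sid, compartment="c", initial_amount=0.0,
                      has_only_substance_units=True,
                      boundary_condition=bool(rng.random() < 0.3),
                      constant=False)
    for j in range(n_reactions):
        reversible = bool(rng.random() < 0.4)
        ub = float(np.round(rng.uniform(1.0, 20.0), 3))
        lb = -ub if reversible else 0.0
        lb_id, ub_id = f"lb{j+1}", f"ub{j+1}"
        m.add_parameter(lb_id, value=lb, constant=True)
        m.add_parameter(ub_id, value=ub, constant=True)
        n_react = int(rng.integers(1, 3))
        n_prod = int(rng.integers(1, 3))
        reactants = list(rng.choice(n_species, size=min(n_react, n_species),
                                    replace=False))
        products = list(rng.choice(n_species, size=min(n_prod, n_species),
                                   replace=False))
        m.add_reaction(
            f"r{j+1}", reversible=reversible,
            reactants=[SpeciesReference(sids[i], 1.0, constant=True)
                       for i in reactants],
            products=[SpeciesReference(sids[i], 1.0, constant=True)
                      for i in products],
            lower_flux_bound=lb_id, upper_flux_bound=ub_id,
        )
    terms = [(f"r{j+1}", 1.0) for j in range(n_reactions)
             if rng.random() < 0.5]
    if not terms:
        terms = [(f"r{n_reactions}", 1.0)]
    m.fbc = fbc_mod.FbcExtension(
        objectives=[fbc_mod.Objective(id="obj", type="maximize", terms=terms)],
        active_objective="obj",
        strict=True,
    )
    return Document(model=m)
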