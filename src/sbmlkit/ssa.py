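"""Discrete stochastic semantics: the Gillespie direct method.

The model is interpreted as a continuous-time Markov jump process over
integer species amounts.  Each reaction's kinetic-law math, evaluated with
the current amounts substituted, is taken directly as its propensity
a_r(x); no concentration-to-count conversion is attempted, which is why the
preconditions require every species to carry amounts
(``hasOnlySubstanceUnits=true``) with integer initial values, integer
stoichiometries, and no rules or events.

Direct method: with total propensity a0 = sum_r a_r, the waiting time to
the next firing is Exponential(a0) and reaction r fires with probability
a_r / a0; firing applies the integer stoichiometry change.  The random
source is numpy's Generator over the PCG64 bit generator; the generator
identity and seed are recorded in the trajectory metadata so runs are
reproducible bit-for-bit.
"""

from __future__ import annotations

import json
import math

import numpy as np
import pandas as pd

from .errors import SbmlError, UnsupportedModelError
from .mathml import EvalEnv, compile_evaluator, inline_function_definitions
from .model import Model
from .ode import TimeCourse

GENERATOR_NAME = "numpy.random.Generator(PCG64)"


def _check_preconditions(model: Model) -> None:
    if model.rules or model.events:
        raise UnsupportedModelError(
            "stochastic simulation supports neither rules nor events"
        )
    for s in model.species:
        if not s.has_only_substance_units:
            raise UnsupportedModelError(
                f"species {s.id!r} is concentration-based; stochastic "
                "simulation requires hasOnlySubstanceUnits=true"
            )
        amount = s.initial_amount if s.initial_amount is not None else 0.0
        if amount != int(amount):
            raise UnsupportedModelError(
                f"species {s.id!r} has non-integer initial amount {amount}"
            )
    for r in model.reactions:
        for ref in list(r.reactants) + list(r.products):
            if ref.stoichiometry != int(ref.stoichiometry):
                raise UnsupportedModelError(
                    f"reaction {r.id!r} has non-integer stoichiometry"
                )
        if r.kinetic_law is None or r.kinetic_law.math is None:
            raise UnsupportedModelError(
                f"reaction {r.id!r} has no kinetic law (propensity)"
            )


def simulate_ssa(model: Model, t_end: float, seed: int,
                 n_out: int = 101, replicate: int = 0,
                 collect_event_times: bool = False) -> TimeCourse:
    """One stochastic trajectory recorded on an equally spaced grid.

    Recording is last-value-carried-forward at grid times.  The same
    ``seed`` (and ``replicate`` index, which offsets the seed sequence)
    reproduces the trajectory exactly.  With ``collect_event_times`` the
    firing times are kept in ``metadata["event_times"]`` (useful for
    waiting-time statistics).
    """
    _check_preconditions(model)
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(replicate + 1)[replicate])

    species_ids = [s.id for s in model.species]
    amounts = {
        s.id: int(s.initial_amount or 0) for s in model.species
    }
    constants: dict[str, float] = {}
    for p in model.parameters:
        if p.value is not None:
            constants[p.id] = p.value
    for c in model.compartments:
        if c.size is not None:
            constants[c.id] = c.size

    defs = {f.id: f.math for f in model.function_definitions}
    propensity_fns = []
    overlays = []
    changes: list[list[tuple[str, int]]] = []
    changeable = {s.id for s in model.species
                  if not s.boundary_condition and not s.constant}
    for r in model.reactions:
        propensity_fns.append(
            compile_evaluator(
                inline_function_definitions(r.kinetic_law.math, defs))
        )
        overlays.append(
            {lp.id: (lp.value or 0.0)
             for lp in r.kinetic_law.local_parameters}
        )
        delta: dict[str, int] = {}
        for ref in r.reactants:
            if ref.species in changeable:
                delta[ref.species] = delta.get(ref.species, 0) - int(ref.stoichiometry)
        for ref in r.products:
            if ref.species in changeable:
                delta[ref.species] = delta.get(ref.species, 0) + int(ref.stoichiometry)
        changes.append(list(delta.items()))

    out_times = np.linspace(0.0, t_end, n_out)
    records = np.empty((n_out, len(species_ids)), dtype=np.int64)

    bindings: dict = dict(constants)
    bindings.update(amounts)
    env = EvalEnv(bindings=bindings, time=0.0)
    n_rxn = len(model.reactions)
    props = np.empty(n_rxn)

    t = 0.0
    out_idx = 0
    event_log: list[float] = []
    while True:
        for j in range(n_rxn):
            if overlays[j]:
                local = EvalEnv(
                    bindings={**bindings, **overlays[j]}, time=t)
                props[j] = propensity_fns[j](local)
            else:
                env.time = t
                props[j] = propensity_fns[j](env)
            if props[j] < 0:
                raise SbmlError(
                    f"negative propensity {props[j]} for reaction "
                    f"{model.reactions[j].id!r}"
                )
        a0 = props.sum()
        if a0 <= 0.0:
            # absorbing state: constant to t_end
            while out_idx < n_out:
                records[out_idx] = [bindings[sid] for sid in species_ids]
                out_idx += 1
            break
        tau = -math.log(rng.random()) / a0
        t_next = t + tau
        while out_idx < n_out and out_times[out_idx] < t_next:
            records[out_idx] = [bindings[sid] for sid in species_ids]
            out_idx += 1
        if out_idx >= n_out:
            break
        # choose reaction proportionally to propensity
        target = rng.random() * a0
        acc = 0.0
        j = 0
        for j in range(n_rxn):
            acc += props[j]
            if acc >= target:
                break
        for sid, d in changes[j]:
            bindings[sid] += d
        t = t_next
        if collect_event_times:
            event_log.append(t)

    data = pd.DataFrame(records, columns=species_ids)
    data.insert(0, "time", out_times)
    return TimeCourse(
        times=out_times,
        data=data,
        metadata={
            "seed": seed,
            "generator": GENERATOR_NAME,
            "replicate": replicate,
            **({"event_times": np.asarray(event_log)}
               if collect_event_times else {}),
        },
    )


def replicate_mean(model: Model, t_end: float, seed: int, n_replicates: int,
                   n_out: int = 101) -> pd.DataFrame:
    """Mean trajectory over replicates (each replicate gets an independent
    stream spawned from the same seed)."""
    total = None
    for k in range(n_replicates):
        tc = simulate_ssa(model, t_end, seed, n_out=n_out, replicate=k)
        vals = tc.data.drop(columns="time").to_numpy(dtype=float)
        total = vals if total is None else total + vals
    mean = total / n_replicates
    out = pd.DataFrame(mean, columns=[s.id for s in model.species])
    out.insert(0, "time", np.linspace(0.0, t_end, n_out))
    return out


def sidecar_json(tc: TimeCourse) -> str:
    """Reproducibility sidecar accompanying the CSV trajectory."""
    return json.dumps(
        {
            "seed": tc.metadata.get("seed"),
            "generator": tc.metadata.get("generator"),
            "replicate": tc.metadata.get("replicate"),
        },
        indent=2,
    ) + "\n"
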