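"""Continuous (ODE) semantics for core models.

A model compiles to amounts-based state equations: for each species ``s``
with ``boundaryCondition=false``, ``constant=false`` and no rate rule,

    d(amount of s)/dt = sum_r  nu_{s,r} * v_r(t, state)

where ``nu`` is the stoichiometry and ``v_r`` the reaction's kinetic-law
math, interpreted as the reaction extent rate (substance/time).  Inside
math, a species symbol evaluates to its *concentration* (amount divided by
compartment size) unless ``hasOnlySubstanceUnits=true``, in which case it
is the amount.  Boundary species keep a zero stoichiometry row (they change
only via rules); constant species never change.  Assignment rules hold at
all times (applied in topological order of their dependencies); initial
assignments are evaluated once at t=0 after literal initial values and
override them.

Internal state is always amounts — concentrations are a derived view, which
keeps the semantics unambiguous if a compartment size changes.  Integration
uses the stiff-capable LSODA method of :func:`scipy.integrate.solve_ivp`;
event triggers are detected by scanning the solver's dense output for
boolean flips and refining the crossing by bisection to within 1e-9 time
units.  Event priorities are not supported: simultaneous events execute in
document order (a warning is recorded on the trajectory).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .errors import (
    EventStormError,
    ModelCompileError,
    SimulationError,
)
from .mathml import EvalEnv, MathNode, compile_evaluator, free_symbols, \
    inline_function_definitions
from .model import Model, Species

MAX_EVENT_FIRINGS = 1_000_000
EVENT_TIME_TOL = 1e-9


@dataclass
class CompiledEvent:
    index: int
    trigger_fn: Callable[[EvalEnv], bool]
    delay_fn: Optional[Callable[[EvalEnv], float]]
    assignments: list[tuple[str, Callable[[EvalEnv], float]]]
    use_values_from_trigger_time: bool
    persistent: bool
    initial_value: bool


@dataclass
class ODESystem:
    """Compiled right-hand side, rules, and event specifications."""

    model: Model
    state_ids: list[str]
    initial_state: np.ndarray
    stoichiometry: np.ndarray  # reaction-driven species x reactions
    reaction_state_rows: list[int]  # state indices of the stoichiometry rows
    rate_fns: list[Callable[[EvalEnv], float]]
    local_overlays: list[dict[str, float]]
    assignment_order: list[tuple[str, Callable[[EvalEnv], float]]]
    rate_rules: list[tuple[int, Callable[[EvalEnv], float], float]]
    constants: dict[str, float]
    mutable_values: dict[str, float]
    species_view: dict[str, tuple[int, float]]  # sid -> (state idx, 1/size or 1)
    event_specs: list[CompiledEvent]
    reported: list[str]

    def state_index(self, sid: str) -> int:
        return self.state_ids.index(sid)


@dataclass
class TimeCourse:
    """Simulated trajectory on the output grid.

    Species columns report the amount when ``hasOnlySubstanceUnits`` else
    the concentration; ``event_times`` lists the discontinuities.
    """

    times: np.ndarray
    data: pd.DataFrame
    event_times: list[float] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __getitem__(self, column: str) -> np.ndarray:
        return self.data[column].to_numpy()

    def to_csv(self, path_or_buf=None):
        return self.data.to_csv(path_or_buf, index=False)


# ---------------------------------------------------------------------------
# Compilation
# ---------------------------------------------------------------------------


def _inline(model: Model, node: MathNode) -> MathNode:
    defs = {f.id: f.math for f in model.function_definitions}
    return inline_function_definitions(node, defs)


def _compartment_size(model: Model, species: Species) -> float:
    comp = model.compartment_by_id(species.compartment)
    if comp.size is None:
        raise ModelCompileError(
            f"species {species.id!r} needs a concentration conversion but "
            f"compartment {comp.id!r} has no size"
        )
    return comp.size


def _topo_sort_assignments(model: Model, rules) -> list:
    """Order assignment rules so dependencies come first; cycles fail."""
    targets = {r.variable for r in rules}
    deps: dict[str, set[str]] = {}
    for r in rules:
        fs = free_symbols(_inline(model, r.math))
        deps[r.variable] = fs.names & targets
    ordered: list = []
    done: set[str] = set()
    remaining = list(rules)
    while remaining:
        progressed = False
        for r in list(remaining):
            if deps[r.variable] <= done:
                ordered.append(r)
                done.add(r.variable)
                remaining.remove(r)
                progressed = True
        if not progressed:
            cyclic = sorted(r.variable for r in remaining)
            raise ModelCompileError(
                f"assignment rules form a dependency cycle: {cyclic}"
            )
    return ordered


def build_ode_system(model: Model) -> ODESystem:
    """Compile a validator-clean model into an executable ODE system."""
    assignment_rules = [r for r in model.rules if r.kind == "assignment"]
    rate_rules = [r for r in model.rules if r.kind == "rate"]
    assignment_targets = {r.variable for r in assignment_rules}
    rate_targets = {r.variable for r in rate_rules}

    state_ids: list[str] = []
    initial: list[float] = []
    species_view: dict[str, tuple[int, float]] = {}
    constants: dict[str, float] = {}
    mutable_values: dict[str, float] = {}

    def initial_species_amount(s: Species) -> float:
        if s.initial_amount is not None:
            return s.initial_amount
        if s.initial_concentration is not None:
            return s.initial_concentration * _compartment_size(model, s)
        return 0.0

    reaction_species: list[Species] = []
    for s in model.species:
        if s.constant:
            # fixed value view
            if s.has_only_substance_units:
                constants[s.id] = initial_species_amount(s)
            else:
                size = _compartment_size(model, s)
                constants[s.id] = initial_species_amount(s) / size
            continue
        if s.id in assignment_targets:
            continue  # computed each evaluation
        state_ids.append(s.id)
        initial.append(initial_species_amount(s))
        inv_size = 1.0
        if not s.has_only_substance_units:
            inv_size = 1.0 / _compartment_size(model, s)
        species_view[s.id] = (len(state_ids) - 1, inv_size)
        if s.id not in rate_targets:
            reaction_species.append(s)

    for c in model.compartments:
        if c.id in rate_targets:
            if c.size is None:
                raise ModelCompileError(
                    f"rate-ruled compartment {c.id!r} has no initial size"
                )
            state_ids.append(c.id)
            initial.append(c.size)
        elif c.id in assignment_targets:
            pass
        elif c.constant or c.size is not None:
            if c.size is not None:
                constants[c.id] = c.size
        # unset non-constant size without rules stays unbound; any use of it
        # in math surfaces as an unbound-symbol evaluation error
    for p in model.parameters:
        if p.id in rate_targets:
            state_ids.append(p.id)
            initial.append(p.value if p.value is not None else 0.0)
        elif p.id in assignment_targets:
            pass
        elif p.constant:
            if p.value is not None:
                constants[p.id] = p.value
        else:
            mutable_values[p.id] = p.value if p.value is not None else 0.0

    # stoichiometry over reaction-driven species
    sp_row = {s.id: i for i, s in enumerate(reaction_species)}
    n_rxn = len(model.reactions)
    stoich = np.zeros((len(reaction_species), n_rxn))
    rate_fns: list = []
    local_overlays: list[dict[str, float]] = []
    for j, r in enumerate(model.reactions):
        if r.kinetic_law is None or r.kinetic_law.math is None:
            raise ModelCompileError(
                f"reaction {r.id!r} has no kinetic law; cannot build ODEs"
            )
        for ref in r.reactants:
            s = model.species_by_id(ref.species)
            if not s.boundary_condition and ref.species in sp_row:
                stoich[sp_row[ref.species], j] -= ref.stoichiometry
        for ref in r.products:
            s = model.species_by_id(ref.species)
            if not s.boundary_condition and ref.species in sp_row:
                stoich[sp_row[ref.species], j] += ref.stoichiometry
        rate_fns.append(compile_evaluator(_inline(model, r.kinetic_law.math)))
        local_overlays.append(
            {
                lp.id: (lp.value if lp.value is not None else 0.0)
                for lp in r.kinetic_law.local_parameters
            }
        )

    reaction_state_rows = [state_ids.index(s.id) for s in reaction_species]

    ordered_rules = _topo_sort_assignments(model, assignment_rules)
    assignment_order = [
        (r.variable, compile_evaluator(_inline(model, r.math)))
        for r in ordered_rules
    ]

    compiled_rate_rules: list[tuple[int, Callable, float]] = []
    for r in rate_rules:
        idx = state_ids.index(r.variable)
        conv = 1.0
        try:
            s = model.species_by_id(r.variable)
            if not s.has_only_substance_units:
                comp = model.compartment_by_id(s.compartment)
                if not comp.constant:
                    raise ModelCompileError(
                        f"rate rule on concentration-view species "
                        f"{s.id!r} in a non-constant compartment is not "
                        "supported"
                    )
                conv = _compartment_size(model, s)
        except LookupError:
            pass
        compiled_rate_rules.append(
            (idx, compile_evaluator(_inline(model, r.math)), conv)
        )

    event_specs: list[CompiledEvent] = []
    for i, e in enumerate(model.events):
        event_specs.append(
            CompiledEvent(
                index=i,
                trigger_fn=compile_evaluator(_inline(model, e.trigger.math)),
                delay_fn=(
                    compile_evaluator(_inline(model, e.delay))
                    if e.delay is not None else None
                ),
                assignments=[
                    (ea.variable, compile_evaluator(_inline(model, ea.math)))
                    for ea in e.assignments
                ],
                use_values_from_trigger_time=e.use_values_from_trigger_time,
                persistent=e.trigger.persistent,
                initial_value=e.trigger.initial_value,
            )
        )

    reported = [s.id for s in model.species]
    for r in model.rules:
        if r.variable not in reported:
            reported.append(r.variable)

    system = ODESystem(
        model=model,
        state_ids=state_ids,
        initial_state=np.asarray(initial, dtype=float),
        stoichiometry=stoich,
        reaction_state_rows=reaction_state_rows,
        rate_fns=rate_fns,
        local_overlays=local_overlays,
        assignment_order=assignment_order,
        rate_rules=compiled_rate_rules,
        constants=constants,
        mutable_values=mutable_values,
        species_view=species_view,
        event_specs=event_specs,
        reported=reported,
    )
    _apply_initial_assignments(system)
    return system


def _make_env(system: ODESystem, t: float, y: np.ndarray) -> EvalEnv:
    bindings: dict = dict(system.constants)
    bindings.update(system.mutable_values)
    # rate-rule compartment/parameter states bind directly
    for i, sid in enumerate(system.state_ids):
        if sid not in system.species_view:
            bindings[sid] = y[i]
    for sid, (idx, inv_size) in system.species_view.items():
        bindings[sid] = y[idx] * inv_size
    env = EvalEnv(bindings=bindings, time=t)
    for sid, fn in system.assignment_order:
        bindings[sid] = fn(env)
    return env


def _apply_initial_assignments(system: ODESystem) -> None:
    model = system.model
    if not model.initial_assignments:
        return
    y = system.initial_state
    env = _make_env(system, 0.0, y)
    for ia in model.initial_assignments:
        value = compile_evaluator(_inline(model, ia.math))(env)
        _assign_value(system, y, ia.symbol, value)
        env = _make_env(system, 0.0, y)


def _assign_value(system: ODESystem, y: np.ndarray, sid: str, value) -> None:
    """Assign to a symbol's *value view* (species: conc unless hOSU)."""
    if sid in system.species_view:
        idx, inv_size = system.species_view[sid]
        y[idx] = value / inv_size
        return
    if sid in system.state_ids:
        y[system.state_index(sid)] = value
        return
    if sid in system.mutable_values:
        system.mutable_values[sid] = value
        return
    if sid in system.constants:
        # initial assignments may override literal constant values at t=0
        system.constants[sid] = value
        return
    raise ModelCompileError(f"cannot assign to symbol {sid!r}")


def _rhs(system: ODESystem, t: float, y: np.ndarray) -> np.ndarray:
    env = _make_env(system, t, y)
    dy = np.zeros_like(y)
    if system.rate_fns:
        v = np.empty(len(system.rate_fns))
        for j, fn in enumerate(system.rate_fns):
            overlay = system.local_overlays[j]
            if overlay:
                local_env = EvalEnv(
                    bindings={**env.bindings, **overlay}, time=t)
                v[j] = fn(local_env)
            else:
                v[j] = fn(env)
        flux = system.stoichiometry @ v
        for row, idx in enumerate(system.reaction_state_rows):
            dy[idx] += flux[row]
    for idx, fn, conv in system.rate_rules:
        dy[idx] = fn(env) * conv
    return dy


def _report_row(system: ODESystem, t: float, y: np.ndarray) -> list[float]:
    env = _make_env(system, t, y)
    return [env.bindings[sid] for sid in system.reported]


# ---------------------------------------------------------------------------
# Simulation with events
# ---------------------------------------------------------------------------


class _EventMachine:
    def __init__(self, system: ODESystem):
        self.system = system
        self.pending: list[dict] = []  # {time, event, frozen(env) or None}
        self.trig_state: list[bool] = []
        self.firings = 0
        self.event_times: list[float] = []
        self.warnings: list[str] = []

    def init(self, t: float, y: np.ndarray) -> None:
        for ev in self.system.event_specs:
            cur = bool(ev.trigger_fn(_make_env(self.system, t, y)))
            self.trig_state.append(cur)
        # initialValue=false triggers that are already true fire at t=0
        for ev in self.system.event_specs:
            if self.trig_state[ev.index] and not ev.initial_value:
                self._on_trigger(ev, t, y)
        self._execute_due(t, y)

    def _on_trigger(self, ev: CompiledEvent, t: float, y: np.ndarray) -> None:
        env = _make_env(self.system, t, y)
        delay = float(ev.delay_fn(env)) if ev.delay_fn is not None else 0.0
        frozen = None
        if ev.use_values_from_trigger_time:
            frozen = {sid: fn(env) for sid, fn in ev.assignments}
        self.pending.append({"time": t + delay, "event": ev, "frozen": frozen})

    def _execute_due(self, t: float, y: np.ndarray) -> None:
        guard = 0
        while True:
            due = [p for p in self.pending
                   if p["time"] <= t + EVENT_TIME_TOL]
            if not due:
                return
            if len(due) > 1:
                self.warnings.append(
                    f"simultaneous events at t={t:.9g} executed in document "
                    "order (priorities unsupported)"
                )
            due.sort(key=lambda p: (p["time"], p["event"].index))
            p = due[0]
            self.pending.remove(p)
            ev: CompiledEvent = p["event"]
            self.firings += 1
            if self.firings > MAX_EVENT_FIRINGS:
                raise EventStormError(
                    f"more than {MAX_EVENT_FIRINGS} event firings", t)
            if p["frozen"] is not None:
                values = p["frozen"]
            else:
                env = _make_env(self.system, t, y)
                values = {sid: fn(env) for sid, fn in ev.assignments}
            for sid, _ in ev.assignments:
                _assign_value(self.system, y, sid, values[sid])
            self.event_times.append(t)
            self.refresh_triggers(t, y)
            guard += 1
            if guard > MAX_EVENT_FIRINGS:
                raise EventStormError("event storm at a single instant", t)

    def refresh_triggers(self, t: float, y: np.ndarray) -> None:
        env = _make_env(self.system, t, y)
        for ev in self.system.event_specs:
            cur = bool(ev.trigger_fn(env))
            prev = self.trig_state[ev.index]
            if cur and not prev:
                self._on_trigger(ev, t, y)
            elif prev and not cur and not ev.persistent:
                self.pending = [
                    p for p in self.pending if p["event"] is not ev
                ]
            self.trig_state[ev.index] = cur

    def next_fire_time(self) -> float:
        return min((p["time"] for p in self.pending), default=math.inf)

    def trigger_vector(self, t: float, y: np.ndarray) -> tuple[bool, ...]:
        env = _make_env(self.system, t, y)
        return tuple(
            bool(ev.trigger_fn(env)) for ev in self.system.event_specs)


def simulate_ode(system: ODESystem, t_end: float, n_out: int = 101,
                 rtol: float = 1e-8, atol: float = 1e-10) -> TimeCourse:
    """Integrate the system from 0 to ``t_end`` on an equally spaced grid.

    Event trigger flips are located on the solver's dense output and
    refined by bisection to within 1e-9 time units; on firing, assignments
    are applied (at trigger-time values when ``useValuesFromTriggerTime``)
    and the integration restarts from the post-event state.
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    if n_out < 2:
        raise ValueError("n_out must be at least 2")
    out_times = np.linspace(0.0, t_end, n_out)
    y = system.initial_state.copy()
    t = 0.0
    machine = _EventMachine(system)
    machine.init(t, y)

    rows: list[list[float]] = []
    recorded: list[float] = []
    out_idx = 0
    # t=0 recorded after any initial firings
    rows.append(_report_row(system, t, y))
    recorded.append(0.0)
    out_idx = 1

    fun = lambda tt, yy: _rhs(system, tt, yy)
    has_events = bool(system.event_specs)

    while out_idx < n_out or machine.next_fire_time() <= t_end:
        next_out = out_times[out_idx] if out_idx < n_out else math.inf
        stop = min(next_out, machine.next_fire_time(), t_end)
        if stop <= t + EVENT_TIME_TOL:
            # stop reached without integration (e.g. zero-length segment)
            seg = None
        else:
            sol = solve_ivp(fun, (t, stop), y, method="LSODA",
                            dense_output=True, rtol=rtol, atol=atol)
            if not sol.success:
                raise SimulationError(
                    f"integration failed: {sol.message}", last_time=t)
            seg = sol
        flip_t = None
        if seg is not None and has_events:
            flip_t = _find_flip(system, machine, seg, t, stop)
        if flip_t is not None:
            # record outputs strictly before the flip
            while out_idx < n_out and out_times[out_idx] < flip_t - EVENT_TIME_TOL:
                tt = out_times[out_idx]
                rows.append(_report_row(system, tt, seg.sol(tt)))
                recorded.append(tt)
                out_idx += 1
            y = np.array(seg.sol(flip_t), dtype=float)
            t = flip_t
            machine.refresh_triggers(t, y)
            machine._execute_due(t, y)
            continue
        if seg is not None:
            while out_idx < n_out and out_times[out_idx] < stop - EVENT_TIME_TOL:
                tt = out_times[out_idx]
                rows.append(_report_row(system, tt, seg.sol(tt)))
                recorded.append(tt)
                out_idx += 1
            y = np.array(seg.y[:, -1], dtype=float)
            t = stop
        else:
            t = stop
        # handle exact-stop bookkeeping: fire due events first so that the
        # recorded value at an event time is the post-event state
        if has_events:
            machine.refresh_triggers(t, y)
            machine._execute_due(t, y)
        if out_idx < n_out and abs(out_times[out_idx] - t) <= EVENT_TIME_TOL:
            rows.append(_report_row(system, t, y))
            recorded.append(out_times[out_idx])
            out_idx += 1
        if t >= t_end - EVENT_TIME_TOL and out_idx >= n_out:
            break

    data = pd.DataFrame(rows, columns=system.reported)
    data.insert(0, "time", np.asarray(recorded))
    return TimeCourse(
        times=np.asarray(recorded),
        data=data,
        event_times=machine.event_times,
        warnings=machine.warnings,
        metadata={"rtol": rtol, "atol": atol, "method": "LSODA"},
    )


def _find_flip(system: ODESystem, machine: _EventMachine, sol, t0: float,
               t1: float) -> Optional[float]:
    """Earliest trigger-state change in (t0, t1], to within 1e-9."""
    knots = [tt for tt in sol.t if t0 < tt <= t1]
    sample = sorted(set([t0] + knots + [t1]))
    # add midpoints to reduce the chance of missing a short excursion
    refined = []
    for a, b in zip(sample[:-1], sample[1:]):
        refined.extend([a, 0.5 * (a + b)])
    refined.append(sample[-1])
    prev_t = refined[0]
    prev_state = tuple(machine.trig_state)
    for tt in refined[1:]:
        cur_state = machine.trigger_vector(tt, np.array(sol.sol(tt)))
        if cur_state != prev_state:
            lo, hi = prev_t, tt
            state_lo = prev_state
            while hi - lo > EVENT_TIME_TOL:
                mid = 0.5 * (lo + hi)
                if machine.trigger_vector(mid, np.array(sol.sol(mid))) == state_lo:
                    lo = mid
                else:
                    hi = mid
            return hi
        prev_t, prev_state = tt, cur_state
    return None
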