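"""Deterministic (ODE) and stochastic (direct-method SSA) simulation.

A :class:`Simulation` snapshots its model's meta-reactions and initial
amounts at construction, so reactions declared afterwards affect only later
simulation objects — this is what makes phase protocols ("grow first, then
enable annihilation") natural to write.  Summing simulations chains them:
each phase's final amounts seed the next phase's shared species.

Durations are either time quantities or boolean conditions over species
amounts; condition durations terminate the phase at the first (root-refined
for ODE, post-firing for SSA) time the condition holds.  Events fire at a
given time or on the rising edge of a condition, at most once each, with
atomic assignments.

The deterministic solver wraps ``scipy.integrate.solve_ivp`` (LSODA, relative
tolerance 1e-6, absolute 1e-9 by default); trigger times are located by
bisection on the dense output to 1e-9 of the phase duration.  The stochastic
solver is a classic direct-method SSA with falling-factorial propensities and
per-run seeds ``seed + run_index``.
"""

from __future__ import annotations

import itertools
import math
import warnings

import numpy as np
from scipy.integrate import solve_ivp

from .compiler import (CompiledEvent, CompiledModel, ExpressionRate,
                       MassActionRate, compile_condition, compile_model)
from .errors import SimulationError
from .model import Condition, MetaSpecies, Parameter, Query, SimGroup
from .units import Quantity, UnitDim


class Event:
    """Declared (uncompiled) event: a trigger plus atomic assignments."""

    def __init__(self, time=None, condition=None, assignments=None, label=""):
        self.time = time
        self.condition = condition
        self.assignments = list(assignments.items()) \
            if isinstance(assignments, dict) else list(assignments or [])
        self.label = label


DEFAULT_CONDITION_CAP = 1e6  # canonical time units; cap for condition durations


def _duration_seconds(duration) -> float:
    if isinstance(duration, Quantity):
        q = duration.to_canonical()
        if not (q.dim.dimensionless or q.dim == UnitDim(time=1)):
            raise SimulationError(f"duration has dim {q.dim}; expected a time")
        return q.magnitude
    return float(duration)


# ---------------------------------------------------------------------------
# rate evaluation shared by both solvers
# ---------------------------------------------------------------------------


class _ReactionRuntime:
    """Per-reaction cached indices and rate closures."""

    __slots__ = ("rate", "reactant_idx", "delta", "react_pairs")

    def __init__(self, reaction, index: dict):
        self.rate = reaction.rate
        # unit-slot indices for deterministic mass action (amount^stoich)
        if isinstance(reaction.rate, MassActionRate):
            self.reactant_idx = [index[n] for n in reaction.rate.slot_names]
        else:
            self.reactant_idx = []
        # aggregated (index, stoich) pairs for SSA falling factorials
        self.react_pairs = [(index[n], s) for n, s in reaction.reactants]
        delta: dict[int, int] = {}
        for n, s in reaction.reactants:
            delta[index[n]] = delta.get(index[n], 0) - s
        for n, s in reaction.products:
            delta[index[n]] = delta.get(index[n], 0) + s
        self.delta = [(i, d) for i, d in delta.items() if d != 0]

    def deterministic_rate(self, y, amounts, params, volume) -> float:
        if isinstance(self.rate, MassActionRate):
            v = self.rate.constant_value(params)
            if self.rate.volume_power:
                v *= volume ** -self.rate.volume_power
            for i in self.reactant_idx:
                v *= y[i] if y[i] > 0.0 else 0.0
            return v
        v = self.rate.expression.evaluate(amounts, params)
        if self.rate.volume_power == -1:
            v *= volume
        return v

    def propensity(self, y, amounts, params, volume) -> float:
        if isinstance(self.rate, MassActionRate):
            a = self.rate.constant_value(params)
            if self.rate.volume_power:
                a *= volume ** -self.rate.volume_power
            for i, s in self.react_pairs:
                x = y[i]
                for k in range(s):
                    a *= (x - k)
                a /= math.factorial(s)
            return max(a, 0.0)
        a = self.rate.expression.evaluate(amounts, params)
        if self.rate.volume_power == -1:
            a *= volume
        return max(a, 0.0)


def _runtime(compiled: CompiledModel):
    return [_ReactionRuntime(r, compiled.species_index) for r in compiled.reactions]


def _params_numeric(compiled: CompiledModel) -> dict:
    out = {}
    for name, v in compiled.parameters.items():
        out[name] = v.canonical_magnitude if isinstance(v, Quantity) else float(v)
    return out


def _apply_assignments(y, event: CompiledEvent, index: dict, params: dict):
    for target, value in event.assignments:
        if isinstance(target, tuple):  # ("param", name)
            params[target[1]] = value
        else:
            y[index[target]] = value


# ---------------------------------------------------------------------------
# deterministic solver
# ---------------------------------------------------------------------------


def run_ode(compiled: CompiledModel, y0, duration: float, terminate,
            grid_points: int = 250, rtol: float = 1e-6, atol: float = 1e-9):
    """Integrate the compiled model; returns (time, Y, t_stop, y_final).

    ``terminate`` is an optional CompiledCondition ending the phase at its
    first root-refined satisfaction time.
    """
    names = [s.name for s in compiled.species]
    index = compiled.species_index
    runtime = _runtime(compiled)
    params = _params_numeric(compiled)
    volume = compiled.volume_value
    n = len(names)

    def f(t, y):
        amounts = {nm: (y[i] if y[i] > 0.0 else 0.0) for i, nm in enumerate(names)}
        dy = np.zeros(n)
        for rr in runtime:
            v = rr.deterministic_rate(y, amounts, params, volume)
            for i, d in rr.delta:
                dy[i] += d * v
        return dy

    def amounts_at(y):
        return {nm: y[i] for i, nm in enumerate(names)}

    time_events = sorted([e for e in compiled.events if e.time is not None],
                         key=lambda e: e.time)
    cond_events = [e for e in compiled.events if e.condition is not None]
    fired = set()
    cond_armed = {id(e): not e.condition.evaluate(amounts_at(np.asarray(y0, float)))
                  for e in cond_events}

    refine_tol = max(duration * 1e-9, 1e-300)
    grid = np.linspace(0.0, duration, grid_points)
    Y = np.empty((grid_points, n))
    y = np.asarray(y0, dtype=float)
    Y[0] = y
    gi = 1
    t = 0.0
    t_stop = duration
    stopped = False

    def clip(vec):
        if np.any(vec < -1e-12):
            warnings.warn("deterministic solution went negative beyond tolerance; "
                          "clipping to zero", stacklevel=2)
        return np.clip(vec, 0.0, None)

    if terminate is not None and terminate.evaluate(amounts_at(y)):
        # condition already satisfied: stop at time zero
        return grid[:1], Y[:1].copy(), 0.0, y.copy()

    while t < duration and not stopped:
        # fire any time events due now, one per pass (assignments are atomic
        # per event; several events at the same instant fire in time order)
        due = next((e for e in time_events
                    if id(e) not in fired and e.time <= t + refine_tol), None)
        if due is not None:
            _apply_assignments(y, due, index, params)
            fired.add(id(due))
            for e in cond_events:
                if id(e) not in fired and not cond_armed[id(e)]:
                    cond_armed[id(e)] = not e.condition.evaluate(amounts_at(y))
            if terminate is not None and terminate.evaluate(amounts_at(y)):
                t_stop = t
                stopped = True
            continue

        t_next = min([e.time for e in time_events
                      if id(e) not in fired and e.time <= duration] + [duration])
        sol = solve_ivp(f, (t, t_next), y, method="LSODA", rtol=rtol,
                        atol=atol, dense_output=True)
        if not sol.success:
            raise SimulationError(f"ODE integration failed: {sol.message}")

        # locate the earliest rising-edge trigger in (t, t_next]
        scan = np.linspace(t, t_next, 400)
        trigger_t, trigger_ev = None, None
        active = [(None, terminate)] if terminate is not None else []
        active += [(e, e.condition) for e in cond_events
                   if id(e) not in fired and cond_armed[id(e)]]
        for ev, cond in active:
            prev_t = scan[0]
            prev_true = cond.evaluate(amounts_at(sol.sol(prev_t)))
            hit = None
            for ts in scan[1:]:
                cur = cond.evaluate(amounts_at(sol.sol(ts)))
                if cur and not prev_true:
                    lo, hi = prev_t, ts
                    while hi - lo > refine_tol:
                        mid = 0.5 * (lo + hi)
                        if cond.evaluate(amounts_at(sol.sol(mid))):
                            hi = mid
                        else:
                            lo = mid
                    hit = hi
                    break
                prev_t, prev_true = ts, cur
            if hit is not None and (trigger_t is None or hit < trigger_t):
                trigger_t, trigger_ev = hit, ev

        seg_end = trigger_t if trigger_t is not None else t_next
        while gi < grid_points and grid[gi] <= seg_end:
            Y[gi] = clip(sol.sol(grid[gi]))
            gi += 1
        y = clip(sol.sol(seg_end))
        t = seg_end

        # re-arm condition events whose condition has gone false
        for e in cond_events:
            if id(e) not in fired and not cond_armed[id(e)]:
                cond_armed[id(e)] = not e.condition.evaluate(amounts_at(y))

        if trigger_t is not None:
            if trigger_ev is None:
                t_stop = trigger_t
                stopped = True
            else:
                _apply_assignments(y, trigger_ev, index, params)
                fired.add(id(trigger_ev))

    if stopped:
        keep = grid <= t_stop
        time = np.append(grid[keep], t_stop)
        Y = np.vstack([Y[keep], y])
    else:
        if gi < grid_points:
            Y[gi:] = y
        time = grid
    return time, Y, t_stop, y.copy()


# ---------------------------------------------------------------------------
# stochastic solver (direct method)
# ---------------------------------------------------------------------------


def run_ssa(compiled: CompiledModel, y0, duration: float, terminate,
            grid_points: int, rng: np.random.Generator,
            max_steps: int = 10_000_000):
    """Direct-method SSA; returns (time, Y, t_stop, y_final).

    Initial amounts must be nonnegative integers; non-integers are rounded
    with a warning.  Conditions (events and termination) are checked after
    every firing.
    """
    names = [s.name for s in compiled.species]
    index = compiled.species_index
    runtime = _runtime(compiled)
    params = _params_numeric(compiled)
    volume = compiled.volume_value

    y = np.asarray(y0, dtype=float)
    if np.any(y < 0):
        raise SimulationError("negative initial amounts in stochastic phase")
    rounded = np.rint(y)
    if np.any(np.abs(rounded - y) > 1e-9):
        warnings.warn("non-integer initial amounts rounded for the stochastic "
                      "solver", stacklevel=2)
    y = rounded

    time_events = sorted([e for e in compiled.events if e.time is not None],
                         key=lambda e: e.time)
    cond_events = [e for e in compiled.events if e.condition is not None]
    fired = set()

    def amounts_at(vec):
        return {nm: vec[i] for i, nm in enumerate(names)}

    cond_armed = {id(e): not e.condition.evaluate(amounts_at(y)) for e in cond_events}

    grid = np.linspace(0.0, duration, grid_points)
    Y = np.empty((grid_points, len(names)))
    gi = 0
    t = 0.0
    t_stop = duration
    stopped = False
    te_idx = 0

    def record_until(t_now, vec):
        nonlocal gi
        while gi < grid_points and grid[gi] <= t_now:
            Y[gi] = vec
            gi += 1

    def check_conditions(t_now) -> bool:
        """Apply any triggered condition events; returns True on termination."""
        nonlocal stopped, t_stop
        amounts = amounts_at(y)
        if terminate is not None and terminate.evaluate(amounts):
            t_stop = t_now
            stopped = True
            return True
        for e in cond_events:
            if id(e) in fired:
                continue
            sat = e.condition.evaluate(amounts)
            if sat and cond_armed[id(e)]:
                _apply_assignments(y, e, index, params)
                fired.add(id(e))
                return check_conditions(t_now)
            if not sat:
                cond_armed[id(e)] = True
        return False

    record_until(0.0, y)
    if check_conditions(0.0):
        record_until(t_stop, y)
        keep = grid <= t_stop
        return (np.append(grid[keep], t_stop), np.vstack([Y[:keep.sum()], y]),
                t_stop, y.copy())

    for _ in range(max_steps):
        if stopped or t >= duration:
            break
        amounts = amounts_at(y)
        a = [rr.propensity(y, amounts, params, volume) for rr in runtime]
        a0 = sum(a)
        if any(ai < 0 for ai in a):
            bad = compiled.reactions[[ai < 0 for ai in a].index(True)]
            raise SimulationError(f"negative propensity in {bad.label()}")
        t_event = time_events[te_idx].time if te_idx < len(time_events) else np.inf
        if a0 <= 0.0:
            t_jump = min(t_event, duration)
            record_until(t_jump, y)
            t = t_jump
            if t_event <= duration and te_idx < len(time_events):
                ev = time_events[te_idx]
                te_idx += 1
                _apply_assignments(y, ev, index, params)
                fired.add(id(ev))
                if check_conditions(t):
                    break
                continue
            break
        tau = rng.exponential(1.0 / a0)
        if t + tau >= min(t_event, duration):
            t_jump = min(t_event, duration)
            record_until(t_jump, y)
            t = t_jump
            if t_event <= duration and te_idx < len(time_events):
                ev = time_events[te_idx]
                te_idx += 1
                _apply_assignments(y, ev, index, params)
                fired.add(id(ev))
                if check_conditions(t):
                    break
            continue
        t += tau
        record_until(t, y)
        r = rng.random() * a0
        acc = 0.0
        ri = len(a) - 1
        for i, ai in enumerate(a):
            acc += ai
            if r < acc:
                ri = i
                break
        for i, d in runtime[ri].delta:
            y[i] += d
        if check_conditions(t):
            break
    else:
        raise SimulationError("stochastic simulation exceeded the step budget")

    if stopped:
        record_until(t_stop, y)
        keep = grid <= t_stop
        time = np.append(grid[keep], t_stop)
        return time, np.vstack([Y[:keep.sum()], y]), t_stop, y.copy()
    record_until(duration, y)
    if gi < grid_points:
        Y[gi:] = y
    return grid, Y, duration, y.copy()


# ---------------------------------------------------------------------------
# simulation objects
# ---------------------------------------------------------------------------


class Simulation:
    """One phase: a snapshot of the model plus solver configuration.

    Attributes may be set after construction, mirroring the builder style:
    ``duration`` (time quantity or condition), ``method`` ("deterministic" or
    "stochastic"), ``volume``, ``runs``, ``seed``, ``output_points``,
    ``rtol``/``atol`` and ``condition_cap`` (time horizon for condition
    durations).
    """

    def __init__(self, species, model=None):
        if isinstance(species, MetaSpecies):
            members = [species]
        elif isinstance(species, SimGroup):
            members = list(species.members)
        elif isinstance(species, (list, tuple)):
            members = list(species)
        else:
            raise SimulationError(f"cannot simulate {species!r}")
        if not members:
            raise SimulationError("a simulation needs at least one meta-species")
        self.model = model if model is not None else members[0].model
        self.simulated = members
        self._reactions = list(self.model._reactions)  # snapshot at construction
        self._initials = list(self.model._initials)
        self.duration = None
        self.method = "deterministic"
        self.volume = Quantity(1.0)
        self.runs = 1
        self.seed = 0
        self.output_points = 250
        self.rtol = 1e-6
        self.atol = 1e-9
        self.condition_cap = DEFAULT_CONDITION_CAP
        self.events: list[Event] = []

    # -- events ------------------------------------------------------------------

    def event_time(self, time, assignments, label: str = "") -> Event:
        ev = Event(time=time, assignments=assignments, label=label)
        self.events.append(ev)
        return ev

    def event_condition(self, condition: Condition, assignments,
                        label: str = "") -> Event:
        if not isinstance(condition, Condition):
            raise SimulationError("event_condition needs a species condition")
        ev = Event(condition=condition, assignments=assignments, label=label)
        self.events.append(ev)
        return ev

    # -- compilation ----------------------------------------------------------------

    def compile(self) -> CompiledModel:
        params = {name: p.value for name, p in self.model._parameters.items()}
        return compile_model(self.simulated, self._reactions, self._initials,
                             self.volume, self.events, params)

    def generate_antimony(self, name: str | None = None):
        from .antimony import write_antimony
        return [write_antimony(self.compile(), name=name)]

    def generate_sbml(self, name: str | None = None):
        from .sbml import write_sbml
        return [write_sbml(self.compile(), name=name)]

    # -- chaining / running ------------------------------------------------------------

    def __add__(self, other):
        if isinstance(other, Simulation):
            return ChainedSimulation([self, other])
        if isinstance(other, ChainedSimulation):
            return ChainedSimulation([self] + other.phases)
        return NotImplemented

    def run(self, seed: int | None = None):
        return ChainedSimulation([self]).run(seed=seed)


class ChainedSimulation:
    """An ordered list of phases; phase i+1 inherits phase i's final amounts
    for shared species names, while new species use their declared initials."""

    def __init__(self, phases: list[Simulation]):
        if not phases:
            raise SimulationError("a chained simulation needs at least one phase")
        self.phases = phases

    def __add__(self, other):
        if isinstance(other, Simulation):
            return ChainedSimulation(self.phases + [other])
        if isinstance(other, ChainedSimulation):
            return ChainedSimulation(self.phases + other.phases)
        return NotImplemented

    @property
    def runs(self) -> int:
        return max(p.runs for p in self.phases)

    def run(self, seed: int | None = None):
        from .results import ResultSet, SweepResults, Trajectory
        model = self.phases[0].model
        sweep_params = model.sweep_parameters()
        if sweep_params:
            sweep = SweepResults()
            base = seed if seed is not None else self.phases[0].seed
            saved = [(p, p.value) for p in sweep_params]
            try:
                for cell_index, combo in enumerate(
                        itertools.product(*(p.values for p in sweep_params))):
                    for p, v in zip(sweep_params, combo):
                        p.value = v
                    cell = self._run_once(base + cell_index)
                    sweep.add(tuple((p.name, v) for p, v in
                                    zip(sweep_params, combo)), cell)
            finally:
                for p, v in saved:
                    p.value = v
            return sweep
        base = seed if seed is not None else self.phases[0].seed
        return self._run_once(base)

    def _run_once(self, base_seed: int):
        from .results import ResultSet, Trajectory
        compiled = [p.compile() for p in self.phases]
        n_runs = self.runs
        all_names: list[str] = []
        for cm in compiled:
            for s in cm.species:
                if s.name not in all_names:
                    all_names.append(s.name)
        simulated: list[MetaSpecies] = []
        for p in self.phases:
            for m in p.simulated:
                if m not in simulated:
                    simulated.append(m)

        det_cache: dict = {}
        trajectories = []
        for run_index in range(n_runs):
            rng = np.random.default_rng(base_seed + run_index)
            carry: dict[str, float] = {}
            t_offset = 0.0
            times, series = [], {nm: [] for nm in all_names}
            boundaries = [0.0]
            for phase, cm in zip(self.phases, compiled):
                if phase.duration is None:
                    raise SimulationError("phase has no duration")
                terminate = None
                if isinstance(phase.duration, Condition):
                    duration = _duration_seconds(phase.condition_cap)
                    terminate = compile_condition(phase.duration, phase.simulated,
                                                  cm.volume_value)
                else:
                    duration = _duration_seconds(phase.duration)
                y0 = np.array([carry.get(s.name, s.initial) for s in cm.species])

                if phase.method == "deterministic":
                    key = (id(phase), tuple(np.round(y0, 12)))
                    if key not in det_cache:
                        det_cache[key] = run_ode(cm, y0, duration, terminate,
                                                 phase.output_points, phase.rtol,
                                                 phase.atol)
                    t, Y, t_stop, y_final = det_cache[key]
                elif phase.method == "stochastic":
                    t, Y, t_stop, y_final = run_ssa(cm, y0, duration, terminate,
                                                    phase.output_points, rng)
                else:
                    raise SimulationError(f"unknown method {phase.method!r}")

                names = [s.name for s in cm.species]
                for i, nm in enumerate(names):
                    carry[nm] = float(y_final[i])
                times.append(t + t_offset)
                for nm in all_names:
                    if nm in cm.species_index:
                        series[nm].append(Y[:, cm.species_index[nm]])
                    else:
                        held = carry.get(nm, 0.0)
                        series[nm].append(np.full(len(t), held))
                t_offset += t_stop
                boundaries.append(t_offset)

            time = np.concatenate(times)
            amounts = {nm: np.concatenate(chunks) for nm, chunks in series.items()}
            trajectories.append(Trajectory(time, amounts, boundaries))
        return ResultSet(trajectories, simulated, all_names)
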