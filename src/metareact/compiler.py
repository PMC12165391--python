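"""Expansion of meta-species and meta-reactions into an explicit network.

Expansion is the heart of the package: every meta-reaction is unrolled over
the Cartesian product of its reactant slots' applicable bindings (ordered
tuples, no symmetric merging), products are paired with reactants by cyclic
round-robin matching on meta-species identity, product states start from the
matched reactant state (or the product meta-species' default when unmatched)
with dot-assignments overriding individual dimensions, and rates are resolved
per binding tuple: callbacks are invoked with reactant-state handles and their
result is classified as a mass-action constant or a full rate expression.

Mass-action deterministic rates for stoichiometry ``n`` use amount^n (no n!
factor); the stochastic solver uses falling-factorial propensities
``x(x-1).../n!``.  Concentration-based constants carry a volume power of
``order - 1`` so the count-based firing rate is ``k * V**-(order-1) * prod(x)``.
"""

from __future__ import annotations

import itertools
import warnings

from .errors import CompileError, UnitError
from .expressions import RateExpression
from .model import Condition, MetaSpecies, Parameter, Query, SpeciesState
from .reactions import (MetaReaction, ReactantHandle, Term,
                        classify_rate_result, invoke_rate_callback)
from .units import DIMLESS, Quantity, RateInfo, UnitDim, check_rate_units


class CompileWarning(UserWarning):
    """Non-fatal compilation diagnostics (e.g. a meta-reaction with no bindings)."""


class ConcreteSpecies:
    __slots__ = ("name", "initial", "state")

    def __init__(self, name: str, initial: float = 0.0, state: SpeciesState | None = None):
        self.name = name
        self.initial = initial
        self.state = state

    def __repr__(self):
        return f"ConcreteSpecies({self.name}={self.initial})"


class MassActionRate:
    """Mass-action kinetics: constant (possibly a swept parameter) + volume power."""

    __slots__ = ("constant", "volume_power", "slot_names")

    def __init__(self, constant, volume_power: int, slot_names: list[str]):
        self.constant = constant  # float or Parameter
        self.volume_power = volume_power
        self.slot_names = slot_names  # one entry per unit reactant slot

    def constant_value(self, params: dict) -> float:
        if isinstance(self.constant, Parameter):
            v = params.get(self.constant.name, self.constant.value)
            return v.canonical_magnitude if isinstance(v, Quantity) else float(v)
        return self.constant

    def render(self, volume_symbol: str = "_vol", namemap=None) -> str:
        from .expressions import format_number
        parts = [namemap(n) if namemap else n for n in self.slot_names]
        parts.append(self.constant.name if isinstance(self.constant, Parameter)
                     else format_number(self.constant))
        if self.volume_power > 0:
            parts.append(f"{volume_symbol}^-{self.volume_power}")
        elif self.volume_power < 0:
            parts.append(f"{volume_symbol}^{-self.volume_power}")
        return " * ".join(parts)


class ExpressionRate:
    """Full rate law: an expression tree evaluating to counts (or conc) per time."""

    __slots__ = ("expression", "volume_power")

    def __init__(self, expression: RateExpression, volume_power: int):
        self.expression = expression
        self.volume_power = volume_power  # -1 when the expression is conc/time

    def render(self, volume_symbol: str = "_vol", namemap=None) -> str:
        s = self.expression.render(namemap)
        if self.volume_power == -1:
            s = f"({s} * {volume_symbol})"
        return s


class ConcreteReaction:
    __slots__ = ("reactants", "products", "rate", "provenance")

    def __init__(self, reactants, products, rate, provenance):
        self.reactants = reactants  # list of (species name, stoichiometry)
        self.products = products
        self.rate = rate
        self.provenance = provenance  # (MetaReaction, tuple of bound SpeciesState)

    def label(self) -> str:
        def side(pairs):
            return " + ".join(f"{n} {s}" if n > 1 else s for s, n in pairs)
        return f"{side(self.reactants)} -> {side(self.products)}"

    def __repr__(self):
        return f"ConcreteReaction({self.label()})"


class CompiledEvent:
    __slots__ = ("time", "condition", "assignments", "label")

    def __init__(self, time: float | None, condition, assignments, label: str = ""):
        self.time = time  # canonical seconds, or None for condition triggers
        self.condition = condition  # CompiledCondition or None
        self.assignments = assignments  # list of (species name or ('param', name), value)
        self.label = label


class CompiledCondition:
    """Evaluable boolean tree over summed species amounts."""

    def __init__(self, kind: str, payload):
        self.kind = kind
        self.payload = payload

    def evaluate(self, amounts: dict) -> bool:
        if self.kind == "cmp":
            op, names, threshold = self.payload
            total = sum(amounts[n] for n in names)
            if op == "<=":
                return total <= threshold
            if op == "<":
                return total < threshold
            if op == ">=":
                return total >= threshold
            if op == ">":
                return total > threshold
            return total == threshold
        a, b = self.payload
        if self.kind == "or":
            return a.evaluate(amounts) or b.evaluate(amounts)
        return a.evaluate(amounts) and b.evaluate(amounts)

    def margin(self, amounts: dict) -> float:
        """Signed distance to the trigger surface (<= 0 once satisfied).

        Used by the deterministic solver to locate trigger times by bisection.
        """
        if self.kind == "cmp":
            op, names, threshold = self.payload
            total = sum(amounts[n] for n in names)
            if op in ("<=", "<"):
                return total - threshold
            if op in (">=", ">"):
                return threshold - total
            return abs(total - threshold)
        a, b = self.payload
        if self.kind == "or":
            return min(a.margin(amounts), b.margin(amounts))
        return max(a.margin(amounts), b.margin(amounts))


class CompiledModel:
    """The explicit network consumed by the solvers and exporters."""

    def __init__(self, species, reactions, parameters, events, volume: Quantity):
        self.species: list[ConcreteSpecies] = species
        self.reactions: list[ConcreteReaction] = reactions
        self.parameters: dict[str, object] = parameters
        self.events: list[CompiledEvent] = events
        self.volume = volume
        self.volume_value = _volume_value(volume)
        self.species_index = {s.name: i for i, s in enumerate(self.species)}

    def listing(self) -> str:
        lines = ["Species:"]
        for s in self.species:
            lines.append(f"  {s.name} = {s.initial:g}")
        if self.parameters:
            lines.append("Parameters:")
            for name, v in self.parameters.items():
                val = v.canonical_magnitude if isinstance(v, Quantity) else v
                lines.append(f"  {name} = {val:g}")
        lines.append(f"Volume: {self.volume_value:g}")
        lines.append("Reactions:")
        for i, r in enumerate(self.reactions):
            lines.append(f"  reaction_{i}: {r.label()}; {r.rate.render()}")
        for e in self.events:
            trig = f"t = {e.time:g} s" if e.time is not None else "condition"
            sets = ", ".join(f"{t}={v:g}" if not isinstance(t, tuple)
                             else f"{t[1]}={v:g}" for t, v in e.assignments)
            lines.append(f"Event ({trig}): {sets}")
        return "\n".join(lines)

    def __str__(self):
        return self.listing()


def _volume_value(volume: Quantity) -> float:
    q = volume.to_canonical() if isinstance(volume, Quantity) else Quantity(float(volume))
    if q.dim.dimensionless:
        return q.magnitude
    if q.dim == UnitDim(volume=1):
        return q.magnitude
    raise UnitError(f"volume has dim {q.dim}; expected a volume or a "
                    f"dimensionless scalar")


def amount_to_counts(amount, volume_value: float, where: str = "") -> float:
    """Convert a count or concentration quantity to molecule counts."""
    ctx = f" for {where}" if where else ""
    if isinstance(amount, (int, float)) and not isinstance(amount, bool):
        return float(amount)
    if isinstance(amount, Quantity):
        q = amount.to_canonical()
        d = q.dim
        if d.time != 0:
            raise UnitError(f"amount has dim {d}{ctx}; expected a count or "
                            f"concentration")
        if d.volume == 0 and d.substance in (0, 1):
            return q.magnitude
        if d.volume == -1 and d.substance in (0, 1):
            return q.magnitude * volume_value
        raise UnitError(f"amount has dim {d}{ctx}; expected a count or concentration")
    raise UnitError(f"amount {amount!r} is not a quantity{ctx}")


# ---------------------------------------------------------------------------
# expansion primitives
# ---------------------------------------------------------------------------


def applicable_bindings(term: Term, simulated: list[MetaSpecies]):
    """All (meta, state) pairs a reactant slot can bind among simulated species.

    Deterministic order: simulated-declaration order, then state order.
    """
    out = []
    for meta in simulated:
        if meta.descends_from(term.query.meta):
            for state in meta.states():
                if term.query.matches(state):
                    out.append((meta, state))
    return out


def match_products(reactant_metas: list[MetaSpecies],
                   product_metas: list[MetaSpecies]) -> list[int | None]:
    """Cyclic round-robin matching of product slots to reactant slots.

    For each product left-to-right, scan the reactant slots cyclically
    starting after the previous match for that product's meta-species; a match
    requires an identical meta-species.  Unmatched products get ``None``.
    """
    n = len(reactant_metas)
    last: dict[int, int] = {}
    matching: list[int | None] = []
    for meta in product_metas:
        found = None
        if n:
            start = last.get(id(meta), -1) + 1
            for i in range(n):
                j = (start + i) % n
                if reactant_metas[j] is meta:
                    found = j
                    break
        matching.append(found)
        if found is not None:
            last[id(meta)] = found
    return matching


def derive_product_state(bound: SpeciesState | None, product_term: Term,
                         simulated: list[MetaSpecies]) -> SpeciesState:
    """State of one product slot: matched reactant state or default, with
    the product term's dot-assignments overriding individual dimensions."""
    assignments = product_term.query.constraints
    if bound is not None:
        new_assignment = dict(bound.assignment)
        for dim, char in assignments.items():
            if dim not in new_assignment:
                raise CompileError(
                    f"product assigns characteristic {char.name!r} along a "
                    f"dimension absent from {bound.meta.name}")
            new_assignment[dim] = char
        return SpeciesState(bound.meta, new_assignment)
    meta = product_term.query.meta
    if meta not in simulated:
        raise CompileError(
            f"product meta-species {meta.name} is unmatched and not simulated; "
            f"cannot determine a concrete born state")
    state = meta.default_state()
    new_assignment = dict(state.assignment)
    for dim, char in assignments.items():
        new_assignment[dim] = char
    return SpeciesState(meta, new_assignment)


def _aggregate(names: list[str]) -> list[tuple[str, int]]:
    counts: dict[str, int] = {}
    for n in names:
        counts[n] = counts.get(n, 0) + 1
    return list(counts.items())


def _resolve_rate(meta_reaction: MetaReaction, handles: list[ReactantHandle],
                  order: int, volume: Quantity) -> RateInfo:
    rate = meta_reaction.rate
    where = meta_reaction.label()
    if callable(rate) and not isinstance(rate, (Quantity, RateExpression, Parameter)):
        result = invoke_rate_callback(rate, handles)
        if isinstance(result, Parameter):
            info = check_rate_units(result.value if isinstance(result.value, Quantity)
                                    else float(result.value), order, volume, where)
            info.constant = result
            return info
        kind, value = classify_rate_result(result)
        if kind == "expression":
            return check_rate_units(value, order, volume, where)
        return check_rate_units(value, order, volume, where)
    if isinstance(rate, Parameter):
        info = check_rate_units(rate.value if isinstance(rate.value, Quantity)
                                else float(rate.value), order, volume, where)
        info.constant = rate
        return info
    if isinstance(rate, RateExpression):
        expr = rate
        if expr.slot_indices():
            expr = expr.bind_slots([h.species_name for h in handles])
        if expr.contains_species():
            return check_rate_units(expr, order, volume, where)
        kind, value = classify_rate_result(expr)
        return check_rate_units(value, order, volume, where)
    return check_rate_units(rate, order, volume, where)


def expand(meta_reaction: MetaReaction, simulated: list[MetaSpecies],
           volume: Quantity) -> list[ConcreteReaction]:
    """One concrete reaction per ordered tuple of reactant-slot bindings."""
    # unroll multiplicities into unit slots, order preserved
    reactant_slots: list[Term] = []
    for t in meta_reaction.reactants:
        reactant_slots.extend([t] * t.multiplicity)
    product_slots: list[Term] = []
    for t in meta_reaction.products:
        product_slots.extend([t] * t.multiplicity)

    binding_lists = [applicable_bindings(t, simulated) for t in reactant_slots]
    if any(not b for b in binding_lists):
        warnings.warn(f"meta-reaction {meta_reaction.label()} has a reactant "
                      f"slot with no matching simulated species; it contributes "
                      f"no reactions", CompileWarning, stacklevel=2)
        return []

    slot_metas = [t.query.meta for t in reactant_slots]
    product_metas = [t.query.meta for t in product_slots]
    matching = match_products(slot_metas, product_metas)

    out: list[ConcreteReaction] = []
    for combo in itertools.product(*binding_lists):
        states = [state for _, state in combo]
        names = [state.name for state in states]
        handles = [ReactantHandle(s, s.name) for s in states]
        info = _resolve_rate(meta_reaction, handles, len(reactant_slots), volume)
        if info.kind == "mass_action" and not isinstance(info.constant, Parameter) \
                and info.constant == 0.0:
            continue  # zero-rate expanded reactions are dropped
        product_states = [derive_product_state(states[m] if m is not None else None,
                                               pt, simulated)
                          for m, pt in zip(matching, product_slots)]
        if info.kind == "mass_action":
            rate = MassActionRate(info.constant, info.volume_power, list(names))
        else:
            rate = ExpressionRate(info.expression, info.volume_power)
        out.append(ConcreteReaction(_aggregate(names),
                                    _aggregate([s.name for s in product_states]),
                                    rate, (meta_reaction, tuple(states))))
    return out


def resolve_initial_amounts(initials, simulated: list[MetaSpecies],
                            volume_value: float) -> dict[str, float]:
    """Map initial assignments to concrete species counts.

    A bare meta-species targets its all-default state; a query targets the
    unique default-completed state.  Later assignments override earlier ones;
    unassigned species default to 0 (handled by the caller).
    """
    amounts: dict[str, float] = {}
    for query, amount in initials:
        if isinstance(query, MetaSpecies):
            query = query._as_query()
        if query.meta not in simulated:
            continue  # assignment belongs to a phase simulating other species
        state = query.default_completed_state()
        amounts[state.name] = amount_to_counts(amount, volume_value, state.name)
    return amounts


def compile_condition(condition: Condition, simulated: list[MetaSpecies],
                      volume_value: float) -> CompiledCondition:
    if condition.kind == "cmp":
        op, query, value = condition.payload
        names = [s.name for meta in simulated if meta.descends_from(query.meta)
                 for s in meta.states() if query.matches(s)]
        if not names:
            raise CompileError(f"condition references {query.label}, which has "
                               f"no simulated species")
        threshold = amount_to_counts(value, volume_value, query.label)
        return CompiledCondition("cmp", (op, names, threshold))
    a, b = condition.payload
    return CompiledCondition(condition.kind,
                             (compile_condition(a, simulated, volume_value),
                              compile_condition(b, simulated, volume_value)))


def compile_model(simulated: list[MetaSpecies], reactions: list[MetaReaction],
                  initials, volume: Quantity, events=None,
                  parameters: dict | None = None) -> CompiledModel:
    """Compile a registry snapshot into an explicit reaction network.

    ``simulated`` is the ordered list of meta-species passed to the simulation;
    species are the union of their enumerations, reactions the concatenation of
    ``expand()`` over all applicable meta-reactions in declaration order.
    """
    volume_value = _volume_value(volume)

    species: list[ConcreteSpecies] = []
    seen: dict[str, MetaSpecies] = {}
    for meta in simulated:
        for state in meta.states():
            if state.name in seen:
                raise CompileError(f"species name collision: {state.name!r} is "
                                   f"generated by both {seen[state.name].name} "
                                   f"and {meta.name}")
            seen[state.name] = meta
            species.append(ConcreteSpecies(state.name, 0.0, state))

    amounts = resolve_initial_amounts(initials, simulated, volume_value)
    for sp in species:
        sp.initial = amounts.get(sp.name, 0.0)

    concrete: list[ConcreteReaction] = []
    for mr in reactions:
        applicable = any(meta.descends_from(t.query.meta)
                         for t in mr.reactants for meta in simulated)
        if mr.reactants and not applicable:
            continue  # acts only on species outside this simulation
        concrete.extend(expand(mr, simulated, volume))

    names = {sp.name for sp in species}
    for r in concrete:
        for n, _ in r.products:
            if n not in names:
                raise CompileError(f"reaction {r.label()} produces {n!r}, which "
                                   f"is not among the simulated species")

    compiled_events: list[CompiledEvent] = []
    for ev in (events or []):
        time = None
        cond = None
        if ev.time is not None:
            t = ev.time.to_canonical() if isinstance(ev.time, Quantity) \
                else Quantity(float(ev.time))
            if not (t.dim.dimensionless or t.dim == UnitDim(time=1)):
                raise UnitError(f"event time has dim {t.dim}")
            time = t.magnitude
        if ev.condition is not None:
            cond = compile_condition(ev.condition, simulated, volume_value)
        assignments = []
        for target, value in ev.assignments:
            if isinstance(target, Parameter):
                v = value.canonical_magnitude if isinstance(value, Quantity) \
                    else float(value)
                assignments.append((("param", target.name), v))
                continue
            if isinstance(target, MetaSpecies):
                target = target._as_query()
            if not isinstance(target, Query):
                raise CompileError(f"cannot assign to {target!r} in an event")
            if target.meta not in simulated:
                raise CompileError(f"event assigns to {target.meta.name}, which "
                                   f"is not simulated")
            state = target.default_completed_state()
            assignments.append((state.name,
                                amount_to_counts(value, volume_value, state.name)))
        compiled_events.append(CompiledEvent(time, cond, assignments, ev.label))

    params = dict(parameters or {})
    return CompiledModel(species, concrete, params, compiled_events, volume)
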