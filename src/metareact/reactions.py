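"""Meta-reaction declaration: ``>>``, ``Rev[...]``, ``Zero``, and rate handling.

A meta-reaction pairs reactant terms (query + multiplicity) with product terms
(assignments + multiplicity) and a rate specification.  The rate can be a
constant (number, :class:`~metareact.units.Quantity` or parameter), a Python
callback over reactant-state handles, or a symbolic expression.  Following the
trailing-bracket surface syntax, the rate attaches to the last product term
(``A >> 2 * A [1.05 / u.h]``) or, for reactions written without an inline
rate, to the finished reaction itself (``(A >> B)[k]`` and
``Rev[A + B >> C][kf, kb]``).
"""

from __future__ import annotations

import inspect

from .errors import ModelError
from .expressions import RateExpression, SpeciesRef
from .model import MetaSpecies, Parameter, Query, SpeciesState
from .units import Quantity


class Term:
    """One reactant or product term: a query with a positive multiplicity."""

    def __init__(self, query: Query, multiplicity: int = 1, rate=None):
        if multiplicity < 1:
            raise ModelError(f"term multiplicity must be >= 1, got {multiplicity}")
        self.query = query
        self.multiplicity = multiplicity
        self.rate = rate  # pending rate attached by the trailing bracket

    def __rmul__(self, n):
        if isinstance(n, int) and not isinstance(n, bool):
            return Term(self.query, self.multiplicity * n, rate=self.rate)
        return NotImplemented

    def __add__(self, other):
        return term_sum(self, other)

    def __radd__(self, other):
        return term_sum(other, self)

    def __rshift__(self, other):
        return make_reaction(self, other)

    def __rrshift__(self, other):
        return make_reaction(other, self)

    def __getitem__(self, rate):
        return Term(self.query, self.multiplicity, rate=rate)

    def __repr__(self):
        pre = f"{self.multiplicity}*" if self.multiplicity != 1 else ""
        return f"{pre}{self.query.label}"


class TermSum:
    def __init__(self, terms: list[Term]):
        self.terms = terms

    def __add__(self, other):
        return term_sum(self, other)

    def __rshift__(self, other):
        return make_reaction(self, other)

    def __rrshift__(self, other):
        return make_reaction(other, self)

    def __getitem__(self, rate):
        # rate after a sum attaches to the last term
        *rest, last = self.terms
        return TermSum(rest + [last[rate]])


def _to_terms(side) -> tuple[list[Term], object]:
    """Normalize one side of ``>>`` into (terms, attached_rate_or_None)."""
    if side is Zero:
        return [], None
    if isinstance(side, _RatedZero):
        return [], side.rate
    if isinstance(side, (MetaSpecies, Query)):
        return [Term(side._as_query(), 1)], None
    if isinstance(side, Term):
        return [side], None
    if isinstance(side, TermSum):
        return list(side.terms), None
    raise ModelError(f"cannot use {side!r} in a reaction")


def term_sum(a, b) -> TermSum:
    ta, ra = _to_terms(a)
    tb, rb = _to_terms(b)
    if ra is not None or rb is not None:
        raise ModelError("rate bracket must come after the full product side")
    return TermSum(ta + tb)


class _ZeroType:
    """The empty species set: absence of reactants (influx) or products (decay)."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __rshift__(self, other):
        return make_reaction(self, other)

    def __rrshift__(self, other):
        return make_reaction(other, self)

    def __getitem__(self, rate):
        return _RatedZero(rate)

    def __repr__(self):
        return "Zero"


Zero = _ZeroType()


class _RatedZero:
    def __init__(self, rate):
        self.rate = rate

    def __rrshift__(self, other):
        return make_reaction(other, self)


class MetaReaction:
    """A declared meta-reaction, recorded in its model's registry."""

    def __init__(self, reactants: list[Term], products: list[Term], rate,
                 model, index: int):
        self.reactants = reactants
        self.products = products
        self.rate = rate
        self.model = model
        self.index = index

    @property
    def order(self) -> int:
        return sum(t.multiplicity for t in self.reactants)

    def label(self) -> str:
        lhs = " + ".join(repr(t) for t in self.reactants) or "Zero"
        rhs = " + ".join(repr(t) for t in self.products) or "Zero"
        return f"{lhs} >> {rhs}"

    def __repr__(self):
        return f"MetaReaction({self.label()})"


def _infer_model(reactants, products):
    for t in reactants + products:
        return t.query.meta.model
    raise ModelError("a reaction needs at least one reactant or product "
                     "(Zero >> Zero is not a reaction)")


def declare_reaction(reactants: list[Term], products: list[Term], rate) -> MetaReaction:
    """Record a meta-reaction in the registry of the involved meta-species."""
    if rate is None:
        raise ModelError(f"reaction "
                         f"{' + '.join(map(repr, reactants)) or 'Zero'} >> "
                         f"{' + '.join(map(repr, products)) or 'Zero'} has no rate")
    model = _infer_model(reactants, products)
    for t in reactants + products:
        if t.query.meta.model is not model:
            raise ModelError("reaction mixes meta-species from different models")
    mr = MetaReaction(reactants, products, rate, model, len(model._reactions))
    model.add_reaction(mr)
    return mr


def declare_reversible(reactants, products, forward_rate, backward_rate):
    """Two one-directional declarations with swapped sides (the Rev operator)."""
    if forward_rate is None or backward_rate is None:
        raise ModelError("a reversible reaction needs a forward and a backward rate")
    fwd = declare_reaction(reactants, products, forward_rate)
    bwd = declare_reaction([Term(t.query, t.multiplicity) for t in products],
                           [Term(t.query, t.multiplicity) for t in reactants],
                           backward_rate)
    return fwd, bwd


def make_reaction(lhs, rhs):
    """Implement ``lhs >> rhs``: finalize if a rate is attached, else stay pending."""
    reactants, lhs_rate = _to_terms(lhs)
    products, rhs_rate = _to_terms(rhs)
    if lhs_rate is not None or any(t.rate is not None for t in reactants):
        raise ModelError("rate bracket attached to a reactant; rates follow "
                         "the product side")
    rates = [t.rate for t in products if t.rate is not None]
    if rhs_rate is not None:
        rates.append(rhs_rate)
    if len(rates) > 1:
        raise ModelError("more than one rate attached to a reaction")
    products = [Term(t.query, t.multiplicity) for t in products]
    if rates:
        return declare_reaction(reactants, products, rates[0])
    return PendingReaction(reactants, products)


class PendingReaction:
    """A ``>>`` expression awaiting its trailing rate bracket (or ``Rev``)."""

    def __init__(self, reactants, products):
        self.reactants = reactants
        self.products = products

    def __getitem__(self, rate):
        if isinstance(rate, tuple):
            if len(rate) != 2:
                raise ModelError("expected [forward_rate, backward_rate]")
            return declare_reversible(self.reactants, self.products, *rate)
        return declare_reaction(self.reactants, self.products, rate)


class _RevType:
    """``Rev[A + B >> C][kf, kb]`` declares the reaction and its reverse."""

    def __getitem__(self, reaction):
        if not isinstance(reaction, PendingReaction):
            raise ModelError("Rev[] takes a reaction whose rates follow in the "
                             "next bracket: Rev[A >> B][kf, kb]")
        return _RevPending(reaction)


class _RevPending:
    def __init__(self, pending: PendingReaction):
        self.pending = pending

    def __getitem__(self, rates):
        if not isinstance(rates, tuple) or len(rates) != 2:
            raise ModelError("Rev[...] requires exactly two rates: [forward, backward]")
        return declare_reversible(self.pending.reactants, self.pending.products, *rates)


Rev = _RevType()


class ReactantHandle:
    """The concrete state bound to one reactant slot during expansion.

    Passed to rate callbacks; supports characteristic tests (:meth:`has`),
    extraction of the characteristic along a named ancestor's dimension
    (calling the handle), and arithmetic, which builds a rate expression
    referencing the concrete species amount.
    """

    def __init__(self, state: SpeciesState, species_name: str):
        self.state = state
        self.species_name = species_name

    def __call__(self, base) -> str:
        if isinstance(base, str):
            base = self.state.meta.model[base]
        return self.state.characteristic_along(base)

    def has(self, characteristic: str) -> bool:
        return self.state.has(characteristic)

    def _to_node(self):
        return SpeciesRef(self.species_name)

    def __add__(self, other):
        return self._to_node() + other

    def __radd__(self, other):
        return other + self._to_node()

    def __sub__(self, other):
        return self._to_node() - other

    def __rsub__(self, other):
        return other - self._to_node()

    def __mul__(self, other):
        return self._to_node() * other

    def __rmul__(self, other):
        return other * self._to_node()

    def __truediv__(self, other):
        return self._to_node() / other

    def __rtruediv__(self, other):
        return other / self._to_node()

    def __pow__(self, n):
        return self._to_node() ** n

    def __le__(self, other):
        from .expressions import Comparison, _as_node
        return Comparison("<=", self._to_node(), _as_node(other))

    def __lt__(self, other):
        from .expressions import Comparison, _as_node
        return Comparison("<", self._to_node(), _as_node(other))

    def __ge__(self, other):
        from .expressions import Comparison, _as_node
        return Comparison(">=", self._to_node(), _as_node(other))

    def __gt__(self, other):
        from .expressions import Comparison, _as_node
        return Comparison(">", self._to_node(), _as_node(other))

    def __repr__(self):
        return f"ReactantHandle({self.state.name})"


def invoke_rate_callback(fn, handles: list[ReactantHandle]):
    """Call a rate callback with handles in reactant slot order.

    The callback may accept fewer positional arguments than there are slots,
    in which case it receives a prefix of the handles.
    """
    try:
        sig = inspect.signature(fn)
        n_pos = 0
        var = False
        for p in sig.parameters.values():
            if p.kind in (p.POSITIONAL_ONLY, p.POSITIONAL_OR_KEYWORD):
                n_pos += 1
            elif p.kind == p.VAR_POSITIONAL:
                var = True
    except (TypeError, ValueError):
        n_pos, var = len(handles), False
    if var or n_pos >= len(handles):
        return fn(*handles)
    return fn(*handles[:n_pos])


def classify_rate_result(value):
    """Classify a callback result as a mass-action constant or a full rate.

    Returns ``("expression", expr)`` when the result references at least one
    reactant, else ``("constant", quantity_or_number)``.
    """
    if isinstance(value, RateExpression):
        if value.contains_species():
            return "expression", value
        # parameter/quantity arithmetic without any reactant: a constant
        val = value.evaluate({}, None)
        return "constant", Quantity(val, value.dim)
    if isinstance(value, Parameter):
        return "constant", value.value if isinstance(value.value, Quantity) \
            else float(value.value)
    if isinstance(value, Quantity):
        return "constant", value
    if isinstance(value, (int, float)) and not isinstance(value, bool):
        return "constant", float(value)
    raise ModelError(f"rate callback returned {value!r}; expected a quantity, "
                     f"number, or rate expression")
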