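"""Symbolic rate expressions with unit propagation.

Rate callbacks receive reactant handles; arithmetic on a handle produces a
:class:`RateExpression` tree over concrete-species references, parameters and
quantities.  Dimensions propagate eagerly through the tree so that a
malformed combination (for example adding a volume to a rate) fails at the
point of construction rather than at simulation time.

Species references are dimensionless: species amounts are molecule counts,
which are pure numbers.  Models that mix counted species with united rate
constants therefore still check cleanly.
"""

from __future__ import annotations

from .errors import UnitError
from .units import DIMLESS, Quantity, UnitDim


def _as_node(value):
    if isinstance(value, RateExpression):
        return value
    if isinstance(value, Quantity):
        return Num(value.canonical_magnitude, value.dim)
    if isinstance(value, (int, float)) and not isinstance(value, bool):
        return Num(float(value))
    # Parameter and ReactantHandle convert themselves via _to_node
    to_node = getattr(value, "_to_node", None)
    if to_node is not None:
        return to_node()
    return None


class RateExpression:
    """Base class: an expression tree node with a propagated dimension."""

    dim: UnitDim = DIMLESS

    # -- interface -----------------------------------------------------------

    def evaluate(self, amounts, params=None) -> float:
        raise NotImplementedError

    def species_names(self) -> set:
        return set()

    def parameter_names(self) -> set:
        return set()

    def slot_indices(self) -> set:
        return set()

    def bind_slots(self, names) -> "RateExpression":
        """Replace file-level reactant slot references with species references."""
        return self

    def contains_species(self) -> bool:
        return bool(self.species_names()) or bool(self.slot_indices())

    def render(self, namemap=None) -> str:
        """Infix rendering used by the Antimony writer and listings.

        ``namemap`` optionally rewrites species names (exports sanitize dots).
        """
        raise NotImplementedError

    # -- operator sugar --------------------------------------------------------

    def _bin(self, other, op, swap=False):
        o = _as_node(other)
        if o is None:
            return NotImplemented
        left, right = (o, self) if swap else (self, o)
        return BinOp(op, left, right)

    def __add__(self, other):
        return self._bin(other, "+")

    def __radd__(self, other):
        return self._bin(other, "+", swap=True)

    def __sub__(self, other):
        return self._bin(other, "-")

    def __rsub__(self, other):
        return self._bin(other, "-", swap=True)

    def __mul__(self, other):
        return self._bin(other, "*")

    def __rmul__(self, other):
        return self._bin(other, "*", swap=True)

    def __truediv__(self, other):
        return self._bin(other, "/")

    def __rtruediv__(self, other):
        return self._bin(other, "/", swap=True)

    def __pow__(self, n):
        if isinstance(n, int):
            return Pow(self, n)
        o = _as_node(n)
        if o is None:
            return NotImplemented
        if isinstance(o, Num) and float(o.value).is_integer() and o.dim.dimensionless:
            return Pow(self, int(o.value))
        raise UnitError("expression exponents must be integers")

    def __neg__(self):
        return BinOp("-", Num(0.0), self)


def format_number(x: float) -> str:
    if float(x).is_integer() and abs(x) < 1e16:
        return str(int(x))
    return repr(float(x))


class Num(RateExpression):
    def __init__(self, value: float, dim: UnitDim = DIMLESS):
        self.value = float(value)
        self.dim = dim

    def evaluate(self, amounts, params=None):
        return self.value

    def render(self, namemap=None):
        return format_number(self.value)


class SpeciesRef(RateExpression):
    """Reference to a concrete species amount (a count, dimensionless)."""

    def __init__(self, name: str):
        self.name = name
        self.dim = DIMLESS

    def evaluate(self, amounts, params=None):
        return amounts[self.name]

    def species_names(self):
        return {self.name}

    def render(self, namemap=None):
        return namemap(self.name) if namemap else self.name


class SlotRef(RateExpression):
    """Reference to reactant slot ``index`` in a declarative model file.

    Resolved to a :class:`SpeciesRef` per expanded binding at compile time.
    """

    def __init__(self, index: int):
        self.index = index
        self.dim = DIMLESS

    def evaluate(self, amounts, params=None):
        raise UnitError("unresolved reactant slot reference")

    def slot_indices(self):
        return {self.index}

    def bind_slots(self, names):
        try:
            return SpeciesRef(names[self.index])
        except IndexError:
            raise UnitError(f"rate expression references reactant r{self.index + 1} "
                            f"but the reaction has only {len(names)} reactant slots") from None

    def render(self, namemap=None):
        return f"r{self.index + 1}"


class ParamRef(RateExpression):
    def __init__(self, parameter):
        self.parameter = parameter
        v = parameter.value
        self.dim = v.dim if isinstance(v, Quantity) else DIMLESS

    def evaluate(self, amounts, params=None):
        if params is not None and self.parameter.name in params:
            v = params[self.parameter.name]
        else:
            v = self.parameter.value
        return v.canonical_magnitude if isinstance(v, Quantity) else float(v)

    def parameter_names(self):
        return {self.parameter.name}

    def render(self, namemap=None):
        return self.parameter.name


class BinOp(RateExpression):
    def __init__(self, op: str, left: RateExpression, right: RateExpression):
        self.op = op
        self.left = left
        self.right = right
        if op in ("+", "-"):
            if left.dim != right.dim:
                raise UnitError(f"cannot {'add' if op == '+' else 'subtract'} "
                                f"dims {left.dim} and {right.dim}")
            self.dim = left.dim
        elif op == "*":
            self.dim = left.dim * right.dim
        elif op == "/":
            self.dim = left.dim / right.dim
        else:
            raise ValueError(f"unknown operator {op!r}")

    def evaluate(self, amounts, params=None):
        a = self.left.evaluate(amounts, params)
        b = self.right.evaluate(amounts, params)
        if self.op == "+":
            return a + b
        if self.op == "-":
            return a - b
        if self.op == "*":
            return a * b
        return a / b

    def species_names(self):
        return self.left.species_names() | self.right.species_names()

    def parameter_names(self):
        return self.left.parameter_names() | self.right.parameter_names()

    def slot_indices(self):
        return self.left.slot_indices() | self.right.slot_indices()

    def bind_slots(self, names):
        return BinOp(self.op, self.left.bind_slots(names), self.right.bind_slots(names))

    def render(self, namemap=None):
        return f"({self.left.render(namemap)}{self.op}{self.right.render(namemap)})"


class Pow(RateExpression):
    def __init__(self, base: RateExpression, exponent: int):
        self.base = base
        self.exponent = int(exponent)
        self.dim = base.dim ** self.exponent

    def evaluate(self, amounts, params=None):
        return self.base.evaluate(amounts, params) ** self.exponent

    def species_names(self):
        return self.base.species_names()

    def parameter_names(self):
        return self.base.parameter_names()

    def slot_indices(self):
        return self.base.slot_indices()

    def bind_slots(self, names):
        return Pow(self.base.bind_slots(names), self.exponent)

    def render(self, namemap=None):
        return f"({self.base.render(namemap)}^{self.exponent})"


class Comparison(RateExpression):
    """Boolean comparison node, valid only as the condition of a Piecewise."""

    _OPS = {"<=": lambda a, b: a <= b, "<": lambda a, b: a < b,
            ">=": lambda a, b: a >= b, ">": lambda a, b: a > b,
            "==": lambda a, b: a == b}

    def __init__(self, op: str, left: RateExpression, right: RateExpression):
        if left.dim != right.dim:
            raise UnitError(f"cannot compare dims {left.dim} and {right.dim}")
        self.op = op
        self.left = left
        self.right = right
        self.dim = DIMLESS

    def evaluate(self, amounts, params=None):
        return self._OPS[self.op](self.left.evaluate(amounts, params),
                                  self.right.evaluate(amounts, params))

    def species_names(self):
        return self.left.species_names() | self.right.species_names()

    def parameter_names(self):
        return self.left.parameter_names() | self.right.parameter_names()

    def slot_indices(self):
        return self.left.slot_indices() | self.right.slot_indices()

    def bind_slots(self, names):
        return Comparison(self.op, self.left.bind_slots(names),
                          self.right.bind_slots(names))

    def render(self, namemap=None):
        return (f"({self.left.render(namemap)} {self.op} "
                f"{self.right.render(namemap)})")


def piecewise(condition, if_true, if_false) -> "Piecewise":
    """Conditional rate expression: ``if_true`` where condition holds, else ``if_false``."""
    return Piecewise(condition, _as_node(if_true), _as_node(if_false))


class Piecewise(RateExpression):
    def __init__(self, condition: Comparison, if_true: RateExpression,
                 if_false: RateExpression):
        if not isinstance(condition, Comparison):
            raise UnitError("piecewise condition must be a comparison")
        if if_true.dim != if_false.dim:
            raise UnitError("piecewise branches must share a dimension")
        self.condition = condition
        self.if_true = if_true
        self.if_false = if_false
        self.dim = if_true.dim

    def evaluate(self, amounts, params=None):
        branch = self.if_true if self.condition.evaluate(amounts, params) else self.if_false
        return branch.evaluate(amounts, params)

    def species_names(self):
        return (self.condition.species_names() | self.if_true.species_names()
                | self.if_false.species_names())

    def parameter_names(self):
        return (self.condition.parameter_names() | self.if_true.parameter_names()
                | self.if_false.parameter_names())

    def slot_indices(self):
        return (self.condition.slot_indices() | self.if_true.slot_indices()
                | self.if_false.slot_indices())

    def bind_slots(self, names):
        return Piecewise(self.condition.bind_slots(names),
                         self.if_true.bind_slots(names),
                         self.if_false.bind_slots(names))

    def render(self, namemap=None):
        return (f"piecewise({self.if_true.render(namemap)}, "
                f"{self.condition.render(namemap)}, "
                f"{self.if_false.render(namemap)})")
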