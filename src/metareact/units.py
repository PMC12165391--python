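"""Dimensional analysis over the (time, volume, substance) axes.

The engine is deliberately small: biochemical reaction-network models need
rates (per time), volumes, counts and concentrations, and nothing else.
Quantities carry an integer exponent vector :class:`UnitDim` plus a scale
factor relative to the canonical basis (second, liter, count).  Moles are a
scaled substance unit (Avogadro's number of counts); molar is mol/liter.

Rate constants are checked against the total reactant multiplicity (reaction
order) by :func:`check_rate_units`, which also normalizes the constant for the
count-based simulation semantics used by the solvers.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass

from .errors import UnitError

AVOGADRO = 6.02214076e23


@dataclass(frozen=True)
class UnitDim:
    """Integer exponent vector over the base dimensions time, volume, substance."""

    time: int = 0
    volume: int = 0
    substance: int = 0

    def __mul__(self, other: "UnitDim") -> "UnitDim":
        return UnitDim(self.time + other.time, self.volume + other.volume,
                       self.substance + other.substance)

    def __truediv__(self, other: "UnitDim") -> "UnitDim":
        return UnitDim(self.time - other.time, self.volume - other.volume,
                       self.substance - other.substance)

    def __pow__(self, n: int) -> "UnitDim":
        return UnitDim(self.time * n, self.volume * n, self.substance * n)

    @property
    def dimensionless(self) -> bool:
        return self.time == 0 and self.volume == 0 and self.substance == 0

    def __str__(self) -> str:
        if self.dimensionless:
            return "dimensionless"
        parts = []
        for name, exp in (("s", self.time), ("L", self.volume), ("count", self.substance)):
            if exp == 1:
                parts.append(name)
            elif exp != 0:
                parts.append(f"{name}^{exp}")
        return "*".join(parts)


DIMLESS = UnitDim()
TIME = UnitDim(time=1)
VOLUME = UnitDim(volume=1)
SUBSTANCE = UnitDim(substance=1)


class Quantity:
    """A magnitude with a dimension and a scale relative to (second, liter, count).

    ``Quantity(2, TIME, 3600)`` is two hours: canonical magnitude 7200 seconds.
    Arithmetic follows exact exponent arithmetic on the dimension vector;
    addition requires equal dimensions and returns a canonical result.
    """

    __slots__ = ("magnitude", "dim", "scale")

    def __init__(self, magnitude: float, dim: UnitDim = DIMLESS, scale: float = 1.0):
        self.magnitude = float(magnitude)
        self.dim = dim
        self.scale = float(scale)

    # -- canonicalization ---------------------------------------------------

    @property
    def canonical_magnitude(self) -> float:
        return self.magnitude * self.scale

    def to_canonical(self) -> "Quantity":
        """Rescale to the (second, liter, count) basis; idempotent."""
        return Quantity(self.magnitude * self.scale, self.dim, 1.0)

    def to(self, unit: "Quantity") -> float:
        """Magnitude of this quantity expressed in ``unit`` (must share dim)."""
        if self.dim != unit.dim:
            raise UnitError(f"cannot express {self} in unit of dim {unit.dim}")
        return self.canonical_magnitude / unit.canonical_magnitude

    # -- arithmetic ----------------------------------------------------------

    @staticmethod
    def _coerce(other):
        if isinstance(other, Quantity):
            return other
        if isinstance(other, (int, float)) and not isinstance(other, bool):
            return Quantity(float(other))
        return None

    def __add__(self, other):
        q = self._coerce(other)
        if q is None:
            return NotImplemented
        if self.dim != q.dim:
            raise UnitError(f"cannot add quantities of dims {self.dim} and {q.dim}")
        return Quantity(self.canonical_magnitude + q.canonical_magnitude, self.dim)

    __radd__ = __add__

    def __sub__(self, other):
        q = self._coerce(other)
        if q is None:
            return NotImplemented
        if self.dim != q.dim:
            raise UnitError(f"cannot subtract quantities of dims {self.dim} and {q.dim}")
        return Quantity(self.canonical_magnitude - q.canonical_magnitude, self.dim)

    def __rsub__(self, other):
        q = self._coerce(other)
        if q is None:
            return NotImplemented
        return q.__sub__(self)

    def __mul__(self, other):
        q = self._coerce(other)
        if q is None:
            return NotImplemented
        return Quantity(self.magnitude * q.magnitude, self.dim * q.dim,
                        self.scale * q.scale)

    __rmul__ = __mul__

    def __truediv__(self, other):
        q = self._coerce(other)
        if q is None:
            return NotImplemented
        return Quantity(self.magnitude / q.magnitude, self.dim / q.dim,
                        self.scale / q.scale)

    def __rtruediv__(self, other):
        q = self._coerce(other)
        if q is None:
            return NotImplemented
        return q.__truediv__(self)

    def __pow__(self, n):
        if not isinstance(n, int):
            raise UnitError("quantity exponents must be integers")
        return Quantity(self.magnitude ** n, self.dim ** n, self.scale ** n)

    def __neg__(self):
        return Quantity(-self.magnitude, self.dim, self.scale)

    def __eq__(self, other):
        q = self._coerce(other)
        if q is None:
            return NotImplemented
        return self.dim == q.dim and math.isclose(
            self.canonical_magnitude, q.canonical_magnitude, rel_tol=1e-12, abs_tol=0.0)

    def __hash__(self):
        return hash((self.dim, round(self.canonical_magnitude, 12)))

    def __repr__(self):
        return f"Quantity({self.canonical_magnitude!r}, {self.dim})"


def to_canonical(q) -> Quantity:
    """Canonicalize a quantity or bare number to the (second, liter, count) basis."""
    if isinstance(q, Quantity):
        return q.to_canonical()
    return Quantity(float(q))


# -- unit registry ------------------------------------------------------------

_UNIT_TABLE: dict[str, Quantity] = {}


def _def(names, dim, scale):
    q = Quantity(1.0, dim, scale)
    for n in names:
        _UNIT_TABLE[n] = q


_def(["s", "sec", "second", "seconds"], TIME, 1.0)
_def(["min", "minute", "minutes"], TIME, 60.0)
_def(["h", "hr", "hour", "hours"], TIME, 3600.0)
_def(["day", "days", "d"], TIME, 86400.0)
_def(["year", "years", "yr"], TIME, 365.25 * 86400.0)  # Julian year
_def(["l", "L", "liter", "litre", "liters"], VOLUME, 1.0)
_def(["ml", "mL", "milliliter", "millilitre"], VOLUME, 1e-3)
_def(["ul", "uL", "microliter", "microlitre"], VOLUME, 1e-6)
_def(["nl", "nL", "nanoliter"], VOLUME, 1e-9)
_def(["count", "counts", "molecule", "molecules"], SUBSTANCE, 1.0)
_def(["mol", "mole", "moles"], SUBSTANCE, AVOGADRO)
_def(["mmol"], SUBSTANCE, AVOGADRO * 1e-3)
_def(["umol"], SUBSTANCE, AVOGADRO * 1e-6)
_def(["nmol"], SUBSTANCE, AVOGADRO * 1e-9)
_def(["molar", "M"], SUBSTANCE / VOLUME, AVOGADRO)
_def(["mM", "millimolar"], SUBSTANCE / VOLUME, AVOGADRO * 1e-3)
_def(["uM", "micromolar"], SUBSTANCE / VOLUME, AVOGADRO * 1e-6)
_def(["nM", "nanomolar"], SUBSTANCE / VOLUME, AVOGADRO * 1e-9)


class _UnitNamespace:
    """Attribute access to named units: ``u.h`` is one hour, ``1/u.ml`` a per-ml rate."""

    def __getattr__(self, name: str) -> Quantity:
        try:
            return _UNIT_TABLE[name]
        except KeyError:
            raise UnitError(f"unknown unit {name!r}") from None


u = _UnitNamespace()


# -- the small unit-string grammar --------------------------------------------
#
#   quantity := term (('*'|'/') term)*
#   term     := factor ('**'|'^') signed-int | factor
#   factor   := NUMBER | UNIT | 'u' '.' UNIT | '(' quantity ')'
#
# accepts strings such as "1.05/h", "5*1e-3*1/u.second", "10 / u.year", "1 ml".

_TOKEN = re.compile(
    r"\s*(?:(?P<num>\d+\.?\d*(?:[eE][+-]?\d+)?)|(?P<ident>[A-Za-z_][A-Za-z_0-9]*)"
    r"|(?P<op>\*\*|\^|[*/().])|(?P<neg>-))")


def parse_quantity(text) -> Quantity:
    """Parse a quantity string written in the unit grammar into a Quantity."""
    if isinstance(text, Quantity):
        return text
    if isinstance(text, (int, float)):
        return Quantity(float(text))
    tokens = []
    pos = 0
    s = str(text)
    while pos < len(s):
        m = _TOKEN.match(s, pos)
        if m is None:
            if s[pos:].strip() == "":
                break
            raise UnitError(f"cannot parse quantity {text!r} at {s[pos:]!r}")
        pos = m.end()
        if m.lastgroup:
            tokens.append((m.lastgroup, m.group(m.lastgroup)))
    tokens.append(("end", ""))

    idx = 0

    def peek():
        return tokens[idx]

    def take(kind=None, value=None):
        nonlocal idx
        k, v = tokens[idx]
        if kind is not None and k != kind or (value is not None and v != value):
            raise UnitError(f"cannot parse quantity {text!r} near {v!r}")
        idx += 1
        return v

    def parse_factor() -> Quantity:
        k, v = peek()
        if k == "num":
            take()
            return Quantity(float(v))
        if k == "ident":
            take()
            if v == "u" and peek() == ("op", "."):
                take()
                v = take("ident")
            if v not in _UNIT_TABLE:
                raise UnitError(f"unknown unit {v!r} in {text!r}")
            return _UNIT_TABLE[v]
        if (k, v) == ("op", "("):
            take()
            q = parse_expr()
            take("op", ")")
            return q
        raise UnitError(f"cannot parse quantity {text!r} near {v!r}")

    def parse_term() -> Quantity:
        base = parse_factor()
        k, v = peek()
        if (k, v) in (("op", "**"), ("op", "^")):
            take()
            sign = 1
            if peek() == ("neg", "-"):
                take()
                sign = -1
            exp = take("num")
            if "." in exp or "e" in exp or "E" in exp:
                raise UnitError("unit exponents must be integers")
            return base ** (sign * int(exp))
        return base

    def parse_expr() -> Quantity:
        q = parse_term()
        while True:
            k, v = peek()
            if (k, v) == ("op", "*"):
                take()
                q = q * parse_term()
            elif (k, v) == ("op", "/"):
                take()
                q = q / parse_term()
            elif k == "num" or k == "ident":
                # juxtaposition, e.g. "1 ml"
                q = q * parse_term()
            else:
                return q

    result = parse_expr()
    if peek()[0] != "end":
        raise UnitError(f"trailing input in quantity {text!r}")
    return result


# -- rate-constant checking ----------------------------------------------------


@dataclass
class RateInfo:
    """A normalized rate specification ready for the solvers.

    kind
        ``"mass_action"`` or ``"expression"``.
    constant
        For mass action: the canonical per-second constant. The count-based
        firing rate of a reaction with reactant counts ``x_i`` is
        ``constant * V**-volume_power * prod(x_i)`` (deterministic) where ``V``
        is the simulation volume in liters (or the dimensionless volume).
    volume_power
        ``order - 1`` for concentration-based constants, 0 for count-based.
    expression
        For expression rates: the unit-checked expression tree; its evaluation
        yields counts/second, after multiplication by ``V**-volume_power``
        (volume_power is 0 or -1 here; -1 means the expression is a
        concentration rate and must be multiplied by V).
    """

    kind: str
    order: int
    constant: float | None = None
    volume_power: int = 0
    expression: object | None = None


def check_rate_units(rate, order: int, volume: Quantity | None = None,
                     where: str = "") -> RateInfo:
    """Check and normalize a rate constant or expression for a reaction.

    ``order`` is the total reactant multiplicity. A mass-action constant must
    have dim time^-1 * concentration^(1-order); a pure time^-1 constant is
    accepted for any order and interpreted as a count-based propensity constant
    in the simulation volume. A full rate expression must have dim
    concentration/time or count/time; fully dimensionless rates are accepted
    for dimensionless models.
    """
    ctx = f" in {where}" if where else ""
    # expression rates -------------------------------------------------------
    from .expressions import RateExpression  # local import to avoid a cycle

    if isinstance(rate, RateExpression):
        d = rate.dim
        if d.dimensionless:
            return RateInfo("expression", order, expression=rate, volume_power=0)
        if d.time == -1 and d.substance in (0, 1):
            if d.volume == 0:
                return RateInfo("expression", order, expression=rate, volume_power=0)
            if d.volume == -1:
                return RateInfo("expression", order, expression=rate, volume_power=-1)
        raise UnitError(f"rate expression has dim {d}, expected count/time or "
                        f"concentration/time{ctx}")

    # constants ----------------------------------------------------------------
    if isinstance(rate, (int, float)) and not isinstance(rate, bool):
        # dimensionless constant: concentration-based semantics, volume factor
        # rendered explicitly (matches the dimensionless-volume export dialect)
        return RateInfo("mass_action", order, constant=float(rate),
                        volume_power=max(order - 1, 0) if order >= 1 else -1)
    if isinstance(rate, Quantity):
        q = rate.to_canonical()
        d = q.dim
        if d.dimensionless:
            return RateInfo("mass_action", order, constant=q.magnitude,
                            volume_power=max(order - 1, 0) if order >= 1 else -1)
        if d.time != -1:
            raise UnitError(f"rate constant has dim {d}; expected time^-1 *"
                            f" concentration^{1 - order}{ctx}")
        # concentration-based: dim time^-1 * (count/vol)^(1-order)
        if d.volume == order - 1 and d.substance in (1 - order, 0):
            return RateInfo("mass_action", order, constant=q.magnitude,
                            volume_power=order - 1)
        # count-based: pure time^-1 (substance exponent 1 allowed for order 0 influx)
        if d.volume == 0 and d.substance in (0, 1) and (order != 1 or d.substance == 1):
            if order == 1 and d.substance == 1:
                raise UnitError(f"order-1 rate constant has dim {d}; expected time^-1{ctx}")
            return RateInfo("mass_action", order, constant=q.magnitude, volume_power=0)
        if order == 1 and d.volume == 0 and d.substance == 0:
            return RateInfo("mass_action", order, constant=q.magnitude, volume_power=0)
        raise UnitError(f"rate constant has dim {d}; inconsistent with reaction "
                        f"order {order}{ctx}")
    raise UnitError(f"rate {rate!r} is neither a quantity nor an expression{ctx}")
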