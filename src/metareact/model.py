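"""The meta-species algebra.

A *base* meta-species contributes one fresh dimension (axis) to the state
space; characteristics added to it (via attribute access or :meth:`c`) become
the discrete values along that axis, the first one added being the default.
Product meta-species are built with ``*`` and take the Cartesian product of
their parts' state spaces, inheriting every meta-reaction registered on any
ancestor.  ``Model.new`` derives fresh meta-species that share a parent's
dimensions but have disjoint concrete species.

Dot access has reactant/product duality: ``Tree.young`` is a :class:`Query`
that *filters* states when used as a reactant (or an initial-value or event
target) and *assigns* the characteristic when used as a product.
"""

from __future__ import annotations

import itertools
from typing import Iterable

from .errors import ModelError
from .units import Quantity

_id_counter = itertools.count()


class Characteristic:
    """One discrete value along one dimension (e.g. ``young`` along Age)."""

    __slots__ = ("name", "dimension")

    def __init__(self, name: str, dimension: "Dimension"):
        self.name = name
        self.dimension = dimension

    def __repr__(self):
        return f"Characteristic({self.name!r})"


class Dimension:
    """One orthogonal axis of a state space with an ordered characteristic list.

    The first characteristic added is the dimension's default.  An empty
    dimension contributes exactly one implicit state to any product.
    """

    __slots__ = ("id", "characteristics", "base_name")

    def __init__(self, base_name: str):
        self.id = next(_id_counter)
        self.characteristics: list[Characteristic] = []
        self.base_name = base_name

    @property
    def default(self) -> Characteristic | None:
        return self.characteristics[0] if self.characteristics else None

    def __repr__(self):
        return f"Dimension({self.base_name}: {[c.name for c in self.characteristics]})"


class SpeciesState:
    """One concrete species: a total assignment over the non-empty dimensions."""

    __slots__ = ("meta", "assignment", "name")

    def __init__(self, meta: "MetaSpecies", assignment: dict):
        self.meta = meta
        self.assignment = assignment
        parts = [meta.name]
        for dim in meta.dimensions:
            if dim.characteristics:
                parts.append(assignment[dim].name)
        self.name = ".".join(parts)

    def characteristic_along(self, base: "MetaSpecies") -> str:
        """Name of this state's characteristic along ``base``'s own dimension."""
        dim = base.own_dimension
        if dim is None or dim not in self.assignment:
            raise ModelError(f"{base.name} does not contribute a characteristic "
                             f"dimension to {self.meta.name}")
        return self.assignment[dim].name

    def has(self, characteristic: str) -> bool:
        return any(c.name == characteristic for c in self.assignment.values())

    def __eq__(self, other):
        return (isinstance(other, SpeciesState) and self.meta is other.meta
                and self.assignment == other.assignment)

    def __hash__(self):
        return hash((id(self.meta), tuple(sorted((d.id, c.name)
                                                 for d, c in self.assignment.items()))))

    def __repr__(self):
        return f"SpeciesState({self.name})"


def _check_identifier(name: str, what: str = "name"):
    if not isinstance(name, str) or not name.isidentifier() or name.startswith("_"):
        raise ModelError(f"{what} {name!r} is not a valid identifier")


class _Reactable:
    """Operator sugar shared by MetaSpecies and Query: reaction and condition syntax."""

    def _as_query(self) -> "Query":
        raise NotImplementedError

    # reactions -------------------------------------------------------------

    def __rmul__(self, n):
        if isinstance(n, int) and not isinstance(n, bool):
            from .reactions import Term
            return Term(self._as_query(), n)
        return NotImplemented

    def __add__(self, other):
        from .reactions import term_sum
        return term_sum(self, other)

    def __radd__(self, other):
        from .reactions import term_sum
        return term_sum(other, self)

    def __rshift__(self, other):
        from .reactions import make_reaction
        return make_reaction(self, other)

    def __rrshift__(self, other):
        from .reactions import make_reaction
        return make_reaction(other, self)

    def __getitem__(self, rate):
        from .reactions import Term
        return Term(self._as_query(), 1, rate=rate)

    # conditions (duration / event triggers) --------------------------------

    def __le__(self, value):
        return Condition("cmp", ("<=", self._as_query(), value))

    def __lt__(self, value):
        return Condition("cmp", ("<", self._as_query(), value))

    def __ge__(self, value):
        return Condition("cmp", (">=", self._as_query(), value))

    def __gt__(self, value):
        return Condition("cmp", (">", self._as_query(), value))


class MetaSpecies(_Reactable):
    """A named set of concrete species spanned by its dimensions."""

    def __init__(self, name: str, model: "Model", dimensions: list,
                 ancestors: frozenset, own_dimension: Dimension | None):
        _check_identifier(name, "meta-species name")
        self.name = name
        self.model = model
        self.dimensions = dimensions
        self.ancestors = ancestors
        self.own_dimension = own_dimension  # set only for base meta-species
        self.construction = ("base", None)  # how this meta-species was built

    @property
    def is_base(self) -> bool:
        return self.own_dimension is not None

    # -- characteristics -----------------------------------------------------

    def __getattr__(self, name: str):
        if name.startswith("_") or not name.isidentifier():
            raise AttributeError(name)
        return self._characteristic_query(name)

    def c(self, value: str) -> "Query":
        """Characteristic access by string value: ``S.c(s)`` equals ``S.<s>``."""
        if not isinstance(value, str) or not value:
            raise ModelError(f"characteristic value must be a nonempty string, "
                             f"got {value!r}")
        _check_identifier(value, "characteristic")
        return self._characteristic_query(value)

    def _characteristic_query(self, name: str) -> "Query":
        owner = self.model._char_owner.get(name)
        if owner is not None:
            if owner in self.dimensions:
                char = next(c for c in owner.characteristics if c.name == name)
                return Query(self, {owner: char})
            raise ModelError(
                f"characteristic {name!r} belongs to {owner.base_name}, which is "
                f"not a dimension of {self.name}")
        # genuinely new characteristic
        if not self.is_base:
            raise ModelError(f"cannot add new characteristic {name!r} to the "
                             f"non-base meta-species {self.name}")
        char = Characteristic(name, self.own_dimension)
        self.own_dimension.characteristics.append(char)
        self.model._char_owner[name] = self.own_dimension
        return Query(self, {self.own_dimension: char})

    # -- state enumeration -----------------------------------------------------

    def states(self) -> list[SpeciesState]:
        """All concrete species, lexicographic over dimensions in dimension
        order, characteristics in insertion order."""
        nonempty = [d for d in self.dimensions if d.characteristics]
        result = []
        for combo in itertools.product(*(d.characteristics for d in nonempty)):
            result.append(SpeciesState(self, dict(zip(nonempty, combo))))
        return result

    @property
    def n_species(self) -> int:
        n = 1
        for d in self.dimensions:
            if d.characteristics:
                n *= len(d.characteristics)
        return n

    def default_state(self) -> SpeciesState:
        return SpeciesState(self, {d: d.default for d in self.dimensions
                                   if d.characteristics})

    # -- construction sugar ------------------------------------------------------

    def __mul__(self, other):
        if isinstance(other, MetaSpecies):
            return SpeciesProduct([self, other])
        if isinstance(other, SpeciesProduct):
            return SpeciesProduct([self] + other.parts)
        return NotImplemented

    def __or__(self, other):
        return SimGroup([self]) | other

    def __call__(self, amount):
        """Set the initial amount of this meta-species' default state."""
        self.model._initials.append((self._as_query(), amount))
        return self

    def _as_query(self) -> "Query":
        return Query(self, {})

    def descends_from(self, other: "MetaSpecies") -> bool:
        return other is self or other in self.ancestors

    def __repr__(self):
        return f"MetaSpecies({self.name})"


class Query(_Reactable):
    """A meta-species with at most one characteristic constraint per dimension.

    An empty constraint set matches all states of the meta-species.
    """

    def __init__(self, meta: MetaSpecies, constraints: dict):
        self.meta = meta
        self.constraints = constraints  # Dimension -> Characteristic

    def __getattr__(self, name: str):
        if name.startswith("_") or not name.isidentifier():
            raise AttributeError(name)
        return self._refine(name)

    def c(self, value: str) -> "Query":
        if not isinstance(value, str) or not value:
            raise ModelError(f"characteristic value must be a nonempty string, "
                             f"got {value!r}")
        return self._refine(value)

    def _refine(self, name: str) -> "Query":
        owner = self.meta.model._char_owner.get(name)
        if owner is None or owner not in self.meta.dimensions:
            raise ModelError(f"unknown characteristic {name!r} on {self.meta.name}")
        if owner in self.constraints:
            raise ModelError(
                f"query on {self.meta.name} constrains the {owner.base_name} "
                f"dimension twice ({self.constraints[owner].name!r} and {name!r})")
        char = next(c for c in owner.characteristics if c.name == name)
        return Query(self.meta, {**self.constraints, owner: char})

    def matches(self, state: SpeciesState) -> bool:
        if not state.meta.descends_from(self.meta):
            return False
        return all(state.assignment.get(dim) is char
                   for dim, char in self.constraints.items())

    def matching_states(self, meta: MetaSpecies | None = None) -> list[SpeciesState]:
        target = meta if meta is not None else self.meta
        return [s for s in target.states() if self.matches(s)]

    def default_completed_state(self, meta: MetaSpecies | None = None) -> SpeciesState:
        """The unique state equal to the default on unconstrained dimensions."""
        target = meta if meta is not None else self.meta
        assignment = {}
        for dim in target.dimensions:
            if dim.characteristics:
                assignment[dim] = self.constraints.get(dim, dim.default)
        return SpeciesState(target, assignment)

    def __call__(self, amount):
        self.meta.model._initials.append((self, amount))
        return self

    def _as_query(self) -> "Query":
        return self

    @property
    def label(self) -> str:
        chars = ".".join(c.name for d, c in sorted(self.constraints.items(),
                                                   key=lambda dc: dc[0].id))
        return self.meta.name + ("." + chars if chars else "")

    def __repr__(self):
        return f"Query({self.label})"


class SpeciesProduct:
    """Unnamed product expression ``A * B * ...`` awaiting registration or derivation."""

    def __init__(self, parts: list[MetaSpecies]):
        models = {p.model for p in parts}
        if len(models) > 1:
            raise ModelError("cannot combine meta-species from different models")
        self.parts = parts

    def __mul__(self, other):
        if isinstance(other, MetaSpecies):
            return SpeciesProduct(self.parts + [other])
        if isinstance(other, SpeciesProduct):
            return SpeciesProduct(self.parts + other.parts)
        return NotImplemented

    def __rmul__(self, other):
        if isinstance(other, MetaSpecies):
            return SpeciesProduct([other] + self.parts)
        return NotImplemented


class SimGroup:
    """``A | B | C``: the ordered set of meta-species passed to a Simulation."""

    def __init__(self, members: list[MetaSpecies]):
        self.members = members

    def __or__(self, other):
        if isinstance(other, MetaSpecies):
            return SimGroup(self.members + [other])
        if isinstance(other, SimGroup):
            return SimGroup(self.members + other.members)
        return NotImplemented


class Condition:
    """Boolean expression tree over species amounts.

    Leaves compare the summed amount of a query's matching species with a
    value; inner nodes are conjunction/disjunction.
    """

    def __init__(self, kind: str, payload):
        self.kind = kind  # "cmp" | "and" | "or"
        self.payload = payload

    def __or__(self, other):
        if isinstance(other, Condition):
            return Condition("or", (self, other))
        return NotImplemented

    def __and__(self, other):
        if isinstance(other, Condition):
            return Condition("and", (self, other))
        return NotImplemented

    def queries(self) -> list:
        if self.kind == "cmp":
            return [self.payload[1]]
        return self.payload[0].queries() + self.payload[1].queries()

    def __repr__(self):
        if self.kind == "cmp":
            op, q, v = self.payload
            return f"({q.label} {op} {v!r})"
        joiner = " | " if self.kind == "or" else " & "
        return f"({self.payload[0]!r}{joiner}{self.payload[1]!r})"


class Parameter:
    """A named model parameter; a list of values declares a factorial sweep axis."""

    def __init__(self, name: str, values, model: "Model"):
        _check_identifier(name, "parameter name")
        self.name = name
        if isinstance(values, (list, tuple)):
            if not values:
                raise ModelError(f"parameter {name!r} needs at least one value")
            self.values = list(values)
        else:
            self.values = [values]
        self.value = self.values[0]
        self.model = model

    def _to_node(self):
        from .expressions import ParamRef
        return ParamRef(self)

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

    def __repr__(self):
        return f"Parameter({self.name}={self.values})"


class Model:
    """Registry owning all meta-species, meta-reactions, parameters and initials.

    Characteristic names are unique per model (one dimension per name), which
    is what keeps dot-queries unambiguous.
    """

    def __init__(self):
        self._species: dict[str, MetaSpecies] = {}
        self._char_owner: dict[str, Dimension] = {}
        self._reactions: list = []
        self._initials: list = []
        self._parameters: dict[str, Parameter] = {}

    # -- species construction ---------------------------------------------------

    def _register(self, ms: MetaSpecies) -> MetaSpecies:
        if ms.name in self._species:
            raise ModelError(f"duplicate meta-species name {ms.name!r}")
        self._species[ms.name] = ms
        return ms

    def base_species(self, *names: str):
        """Create base meta-species, each with one fresh empty dimension."""
        if len(set(names)) != len(names):
            raise ModelError(f"duplicate names in base_species: {names}")
        created = tuple(
            self._register(MetaSpecies(n, self, [dim := Dimension(n)],
                                       frozenset(), dim))
            for n in names)
        return created[0] if len(created) == 1 else created

    def species(self, name: str, parts) -> MetaSpecies:
        """Combine meta-species into a named product (the ``*`` operator)."""
        if isinstance(parts, MetaSpecies):
            parts = [parts]
        elif isinstance(parts, SpeciesProduct):
            parts = parts.parts
        parts = list(parts)
        if not parts:
            raise ModelError("a product meta-species needs at least one part")
        for p in parts:
            if p.model is not self:
                raise ModelError("cannot combine meta-species from another model")
        dims: list[Dimension] = []
        for p in parts:
            for d in p.dimensions:
                if d not in dims:
                    dims.append(d)
        ancestors = frozenset().union(*({p} | p.ancestors for p in parts))
        ms = self._register(MetaSpecies(name, self, dims, ancestors, None))
        ms.construction = ("combined", [p.name for p in parts])
        return ms

    def new(self, parent, *names: str):
        """Derive fresh meta-species sharing ``parent``'s dimensions.

        Children inherit all of the parent's (or product parts') reactions but
        have concrete species disjoint from the parent's and from each other's.
        """
        if len(set(names)) != len(names):
            raise ModelError(f"duplicate names in new(): {names}")
        if isinstance(parent, SpeciesProduct):
            dims: list[Dimension] = []
            for p in parent.parts:
                for d in p.dimensions:
                    if d not in dims:
                        dims.append(d)
            ancestors = frozenset().union(*({p} | p.ancestors for p in parent.parts))
        elif isinstance(parent, MetaSpecies):
            dims = list(parent.dimensions)
            ancestors = frozenset({parent}) | parent.ancestors
        else:
            raise ModelError(f"cannot derive from {parent!r}")
        parent_names = [p.name for p in parent.parts] \
            if isinstance(parent, SpeciesProduct) else [parent.name]
        created = []
        for n in names:
            ms = self._register(MetaSpecies(n, self, list(dims), ancestors, None))
            ms.construction = ("derived", parent_names)
            created.append(ms)
        created = tuple(created)
        return created[0] if len(created) == 1 else created

    # -- parameters ----------------------------------------------------------------

    def parameter(self, name: str, values) -> Parameter:
        if name in self._parameters:
            raise ModelError(f"duplicate parameter name {name!r}")
        p = Parameter(name, values, self)
        self._parameters[name] = p
        return p

    def parameters(self, **named):
        """Declare several parameters at once; returns them in keyword order."""
        created = tuple(self.parameter(n, v) for n, v in named.items())
        return created[0] if len(created) == 1 else created

    def sweep_parameters(self) -> list[Parameter]:
        return [p for p in self._parameters.values() if len(p.values) > 1]

    # -- reaction registry -----------------------------------------------------------

    def add_reaction(self, reaction):
        self._reactions.append(reaction)
        return reaction

    def reactions_for(self, meta: MetaSpecies) -> list:
        """Meta-reactions visible to ``meta``: declared on it or any ancestor."""
        out = []
        for r in self._reactions:
            for term in r.reactants:
                if meta.descends_from(term.query.meta):
                    out.append(r)
                    break
        return out

    def set_initial(self, target, amount):
        """Record an initial-amount assignment (the call-operator core)."""
        if isinstance(target, MetaSpecies):
            target = target._as_query()
        self._initials.append((target, amount))

    def __contains__(self, name: str):
        return name in self._species

    def __getitem__(self, name: str) -> MetaSpecies:
        return self._species[name]
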