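"""Antimony text export.

The dialect is intentionally minimal: a ``model`` header, one line per
species initialization annotated ``dimensionless``, a ``_vol`` parameter
(the simulation volume), one line per reaction in compiled order, and
``end``.  Mass-action rates render as the product of the reactant species,
the constant and ``_vol^-(order-1)`` (the volume factor is omitted for
unimolecular reactions); expression rates render as parenthesized infix.

Species names containing dots (multi-characteristic species) are sanitized
to underscores, since dots are not valid in Antimony identifiers.
"""

from __future__ import annotations

from .compiler import CompiledModel
from .errors import CompileError
from .expressions import format_number
from .units import Quantity


def _sanitizer(compiled: CompiledModel):
    mapping = {}
    for sp in compiled.species:
        clean = sp.name.replace(".", "_")
        if clean in mapping.values() and sp.name.replace(".", "_") != sp.name:
            raise CompileError(f"species name {clean!r} collides after "
                               f"sanitizing dots for export")
        mapping[sp.name] = clean
    seen = {}
    for orig, clean in mapping.items():
        if clean in seen:
            raise CompileError(f"species {orig!r} and {seen[clean]!r} collide "
                               f"after sanitizing dots for export")
        seen[clean] = orig
    return lambda name: mapping.get(name, name)


def write_antimony(compiled: CompiledModel, name: str | None = None) -> str:
    """Render a compiled model as Antimony text."""
    name = name or "metareact_model"
    namemap = _sanitizer(compiled)
    lines = [f"model {name}"]
    for sp in compiled.species:
        lines.append(f"{namemap(sp.name)} = {format_number(sp.initial)} dimensionless")
    for pname, value in compiled.parameters.items():
        v = value.canonical_magnitude if isinstance(value, Quantity) else float(value)
        lines.append(f"{pname} = {format_number(v)} dimensionless")
    lines.append(f"_vol = {format_number(compiled.volume_value)} dimensionless")
    for i, r in enumerate(compiled.reactions):
        def side(pairs):
            return " + ".join(f"{n} {namemap(s)}" if n > 1 else namemap(s)
                              for s, n in pairs)
        rate = r.rate.render("_vol", namemap)
        lines.append(f"reaction_{i}: {side(r.reactants)} -> {side(r.products)}; {rate}")
    lines.append("end")
    return "\n".join(lines) + "\n"
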