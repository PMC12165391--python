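"""SBML Level 3 Version 1 export.

Species are exported as substance amounts (counts) in a single compartment
whose size is the simulation volume; kinetic laws are MathML formula trees
built from the compiled rates, and events carry time or amount-condition
triggers.  The writer emits plain XML; the document structure follows the
SBML L3V1 core schema.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET

from .compiler import (CompiledCondition, CompiledModel, ExpressionRate,
                       MassActionRate)
from .errors import CompileError
from .expressions import (BinOp, Comparison, Num, ParamRef, Piecewise, Pow,
                          RateExpression, SpeciesRef)
from .units import Quantity

SBML_NS = "http://www.sbml.org/sbml/level3/version1/core"
MATHML_NS = "http://www.w3.org/1998/Math/MathML"


def _sanitize(name: str) -> str:
    return name.replace(".", "_")


# -- MathML builders -----------------------------------------------------------


def _math(parent):
    return ET.SubElement(parent, f"{{{MATHML_NS}}}math")


def _cn(parent, value: float):
    el = ET.SubElement(parent, f"{{{MATHML_NS}}}cn")
    el.text = repr(float(value))
    return el


def _ci(parent, name: str):
    el = ET.SubElement(parent, f"{{{MATHML_NS}}}ci")
    el.text = f" {name} "
    return el


def _apply(parent, op: str):
    ap = ET.SubElement(parent, f"{{{MATHML_NS}}}apply")
    ET.SubElement(ap, f"{{{MATHML_NS}}}{op}")
    return ap

_OPS = {"+": "plus", "-": "minus", "*": "times", "/": "divide",
        "<=": "leq", "<": "lt", ">=": "geq", ">": "gt", "==": "eq"}


def _expr_mathml(parent, node: RateExpression):
    if isinstance(node, Num):
        _cn(parent, node.value)
    elif isinstance(node, SpeciesRef):
        _ci(parent, _sanitize(node.name))
    elif isinstance(node, ParamRef):
        _ci(parent, node.parameter.name)
    elif isinstance(node, BinOp):
        ap = _apply(parent, _OPS[node.op])
        _expr_mathml(ap, node.left)
        _expr_mathml(ap, node.right)
    elif isinstance(node, Pow):
        ap = _apply(parent, "power")
        _expr_mathml(ap, node.base)
        _cn(ap, node.exponent)
    elif isinstance(node, Comparison):
        ap = _apply(parent, _OPS[node.op])
        _expr_mathml(ap, node.left)
        _expr_mathml(ap, node.right)
    elif isinstance(node, Piecewise):
        pw = ET.SubElement(parent, f"{{{MATHML_NS}}}piecewise")
        piece = ET.SubElement(pw, f"{{{MATHML_NS}}}piece")
        _expr_mathml(piece, node.if_true)
        _expr_mathml(piece, node.condition)
        other = ET.SubElement(pw, f"{{{MATHML_NS}}}otherwise")
        _expr_mathml(other, node.if_false)
    else:
        raise CompileError(f"unsupported construct in SBML export: {node!r}")


def _condition_mathml(parent, cond: CompiledCondition):
    if cond.kind == "cmp":
        op, names, threshold = cond.payload
        ap = _apply(parent, _OPS.get(op, "eq"))
        if len(names) == 1:
            _ci(ap, _sanitize(names[0]))
        else:
            total = _apply(ap, "plus")
            for n in names:
                _ci(total, _sanitize(n))
        _cn(ap, threshold)
        return
    a, b = cond.payload
    ap = _apply(parent, "or" if cond.kind == "or" else "and")
    _condition_mathml(ap, a)
    _condition_mathml(ap, b)


def _rate_mathml(parent, rate, params: dict):
    if isinstance(rate, MassActionRate):
        factors = len(rate.slot_names) + (1 if rate.volume_power else 0)
        target = parent if factors == 0 else _apply(parent, "times")
        if factors == 0:
            _cn(parent, rate.constant_value(params))
            return
        for n in rate.slot_names:
            _ci(target, _sanitize(n))
        from .model import Parameter
        if isinstance(rate.constant, Parameter):
            _ci(target, rate.constant.name)
        else:
            _cn(target, rate.constant)
        if rate.volume_power:
            ap = _apply(target, "power")
            _ci(ap, "_vol")
            _cn(ap, -rate.volume_power)
    elif isinstance(rate, ExpressionRate):
        if rate.volume_power == -1:
            ap = _apply(parent, "times")
            _expr_mathml(ap, rate.expression)
            _ci(ap, "_vol")
        else:
            _expr_mathml(parent, rate.expression)
    else:
        raise CompileError(f"unsupported rate {rate!r} in SBML export")


def write_sbml(compiled: CompiledModel, name: str | None = None) -> str:
    """Render a compiled model as an SBML L3V1 document string."""
    ET.register_namespace("", SBML_NS)
    ET.register_namespace("math", MATHML_NS)
    root = ET.Element(f"{{{SBML_NS}}}sbml", attrib={"level": "3", "version": "1"})
    model = ET.SubElement(root, f"{{{SBML_NS}}}model",
                          attrib={"id": name or "metareact_model"})

    compartments = ET.SubElement(model, f"{{{SBML_NS}}}listOfCompartments")
    ET.SubElement(compartments, f"{{{SBML_NS}}}compartment", attrib={
        "id": "c1", "size": repr(compiled.volume_value), "constant": "true",
        "spatialDimensions": "3"})

    species_el = ET.SubElement(model, f"{{{SBML_NS}}}listOfSpecies")
    for sp in compiled.species:
        ET.SubElement(species_el, f"{{{SBML_NS}}}species", attrib={
            "id": _sanitize(sp.name), "compartment": "c1",
            "initialAmount": repr(float(sp.initial)),
            "hasOnlySubstanceUnits": "true", "boundaryCondition": "false",
            "constant": "false"})

    params_el = ET.SubElement(model, f"{{{SBML_NS}}}listOfParameters")
    ET.SubElement(params_el, f"{{{SBML_NS}}}parameter", attrib={
        "id": "_vol", "value": repr(compiled.volume_value), "constant": "true"})
    for pname, value in compiled.parameters.items():
        v = value.canonical_magnitude if isinstance(value, Quantity) else float(value)
        ET.SubElement(params_el, f"{{{SBML_NS}}}parameter", attrib={
            "id": pname, "value": repr(v), "constant": "false"})

    reactions_el = ET.SubElement(model, f"{{{SBML_NS}}}listOfReactions")
    for i, r in enumerate(compiled.reactions):
        rx = ET.SubElement(reactions_el, f"{{{SBML_NS}}}reaction", attrib={
            "id": f"reaction_{i}", "reversible": "false"})
        if r.reactants:
            lst = ET.SubElement(rx, f"{{{SBML_NS}}}listOfReactants")
            for n, s in r.reactants:
                ET.SubElement(lst, f"{{{SBML_NS}}}speciesReference", attrib={
                    "species": _sanitize(n), "stoichiometry": str(s),
                    "constant": "true"})
        if r.products:
            lst = ET.SubElement(rx, f"{{{SBML_NS}}}listOfProducts")
            for n, s in r.products:
                ET.SubElement(lst, f"{{{SBML_NS}}}speciesReference", attrib={
                    "species": _sanitize(n), "stoichiometry": str(s),
                    "constant": "true"})
        kl = ET.SubElement(rx, f"{{{SBML_NS}}}kineticLaw")
        math = _math(kl)
        _rate_mathml(math, r.rate, compiled.parameters)

    if compiled.events:
        events_el = ET.SubElement(model, f"{{{SBML_NS}}}listOfEvents")
        for j, ev in enumerate(compiled.events):
            ev_el = ET.SubElement(events_el, f"{{{SBML_NS}}}event", attrib={
                "id": f"event_{j}", "useValuesFromTriggerTime": "true"})
            trig = ET.SubElement(ev_el, f"{{{SBML_NS}}}trigger", attrib={
                "initialValue": "true", "persistent": "true"})
            math = _math(trig)
            if ev.time is not None:
                ap = _apply(math, "geq")
                ci = ET.SubElement(ap, f"{{{MATHML_NS}}}csymbol", attrib={
                    "encoding": "text",
                    "definitionURL": "http://www.sbml.org/sbml/symbols/time"})
                ci.text = " t "
                _cn(ap, ev.time)
            else:
                _condition_mathml(math, ev.condition)
            assigns = ET.SubElement(ev_el, f"{{{SBML_NS}}}listOfEventAssignments")
            for target, value in ev.assignments:
                var = target[1] if isinstance(target, tuple) else _sanitize(target)
                ea = ET.SubElement(assigns, f"{{{SBML_NS}}}eventAssignment",
                                   attrib={"variable": var})
                _cn(_math(ea), value)

    ET.indent(root)
    return ('<?xml version="1.0" encoding="UTF-8"?>\n'
            + ET.tostring(root, encoding="unicode") + "\n")
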