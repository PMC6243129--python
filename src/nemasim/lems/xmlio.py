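"""LEMS XML export/import for the implemented subset.

Exported documents embed the ComponentType definitions (dynamics) alongside
the Component instances (parameter bindings), so a document is self-contained
and can be re-imported or handed to the reference interpreter.  Constructs
outside the subset — kinetic schemes, structure/for-each templates, nested
component types — raise :class:`UnsupportedConstructError` on import rather
than being silently dropped.
"""

from __future__ import annotations

import importlib.resources

from lxml import etree

from ..expressions import parse_expression, parse_predicate
from ..units import DIMENSIONS, Dimension, parse_quantity
from .types import (
    Component,
    ComponentType,
    EventLink,
    Link,
    ModelError,
    NeuronModel,
    OnCondition,
    OnEvent,
    compose_model,
    instantiate,
)

__all__ = [
    "LemsXMLError",
    "UnsupportedConstructError",
    "export_lems",
    "import_lems",
    "lems_schema_path",
]


class LemsXMLError(ValueError):
    pass


class UnsupportedConstructError(LemsXMLError):
    """Document uses a LEMS construct outside the implemented subset."""


_DIM_NAME = {v: k for k, v in DIMENSIONS.items()}


def _dim_name(dim: Dimension) -> str:
    try:
        return _DIM_NAME[dim]
    except KeyError:  # pragma: no cover - library uses named dimensions only
        raise LemsXMLError(f"dimension {dim} has no registered name") from None


def _fmt(value: float) -> str:
    return format(float(value), ".12g")


# ------------------------------------------------------------------ export


def _export_component_type(parent, ct: ComponentType) -> None:
    el = etree.SubElement(parent, "ComponentType", name=ct.name)
    for name, dim in ct.parameters.items():
        etree.SubElement(el, "Parameter", name=name, dimension=_dim_name(dim))
    for name, dim in ct.requirements.items():
        etree.SubElement(el, "Requirement", name=name, dimension=_dim_name(dim))
    for exposure, local in ct.exposures.items():
        etree.SubElement(el, "Exposure", name=exposure, variable=local)
    for port, direction in ct.event_ports.items():
        etree.SubElement(el, "EventPort", name=port, direction=direction)
    dyn = etree.SubElement(el, "Dynamics")
    for name, dim in ct.state_variables.items():
        etree.SubElement(dyn, "StateVariable", name=name, dimension=_dim_name(dim))
    for name, expr in ct.derived_variables.items():
        etree.SubElement(dyn, "DerivedVariable", name=name, value=expr.to_text())
    for name, expr in ct.time_derivatives.items():
        etree.SubElement(dyn, "TimeDerivative", variable=name, value=expr.to_text())
    if ct.on_start:
        start = etree.SubElement(dyn, "OnStart")
        for name, expr in ct.on_start:
            etree.SubElement(start, "StateAssignment", variable=name, value=expr.to_text())
    for rule in ct.on_conditions:
        cond = etree.SubElement(dyn, "OnCondition", test=rule.test.to_text())
        for name, expr in rule.assignments:
            etree.SubElement(cond, "StateAssignment", variable=name, value=expr.to_text())
        if rule.event_out is not None:
            etree.SubElement(cond, "EventOut", port=rule.event_out)
    for handler in ct.on_events:
        ev = etree.SubElement(dyn, "OnEvent", port=handler.port)
        for name, expr in handler.assignments:
            etree.SubElement(ev, "StateAssignment", variable=name, value=expr.to_text())


def _export_component(parent, c: Component) -> None:
    el = etree.SubElement(parent, "Component", id=c.id, type=c.type.name)
    for name in c.type.parameters:  # type order: deterministic
        value, unit = c.bindings[name]
        text = _fmt(value) if unit.name == "none" else f"{_fmt(value)} {unit.name}"
        el.set(name, text)


def export_lems(model: NeuronModel) -> str:
    """Serialize a validated model to LEMS XML text (deterministic)."""
    # re-validate composition before writing
    compose_model(list(model.components), list(model.links),
                  list(model.event_links), root=model.root or None)
    root = etree.Element("Lems")
    seen: dict[str, ComponentType] = {}
    for c in model.components:
        if c.type.name in seen:
            if seen[c.type.name] != c.type:
                raise LemsXMLError(f"two distinct ComponentTypes named {c.type.name!r}")
        else:
            seen[c.type.name] = c.type
    for name in sorted(seen):
        _export_component_type(root, seen[name])
    for c in model.components:
        _export_component(root, c)
    model_el = etree.SubElement(root, "NeuronModel")
    if model.root:
        model_el.set("root", model.root)
    for link in model.links:
        etree.SubElement(
            model_el, "Link",
            **{"from": link.source, "exposure": link.exposure,
               "to": link.target, "requirement": link.requirement},
        )
    for el_ in model.event_links:
        etree.SubElement(
            model_el, "EventLink",
            **{"from": el_.source, "port": el_.port_out,
               "to": el_.target, "targetPort": el_.port_in},
        )
    return etree.tostring(root, pretty_print=True, encoding="unicode")


# ------------------------------------------------------------------ import


def _req(el, attr: str) -> str:
    v = el.get(attr)
    if v is None:
        raise LemsXMLError(f"<{el.tag}> missing attribute {attr!r}")
    return v


def _dimension(name: str) -> Dimension:
    try:
        return DIMENSIONS[name]
    except KeyError:
        raise UnsupportedConstructError(f"unknown dimension {name!r}") from None


def _import_component_type(el) -> ComponentType:
    parameters: dict[str, Dimension] = {}
    requirements: dict[str, Dimension] = {}
    exposures: dict[str, str] = {}
    event_ports: dict[str, str] = {}
    state_variables: dict[str, Dimension] = {}
    derived_variables = {}
    time_derivatives = {}
    on_start: list = []
    on_conditions: list = []
    on_events: list = []
    for child in el:
        if not isinstance(child.tag, str):
            continue
        if child.tag == "Parameter":
            parameters[_req(child, "name")] = _dimension(_req(child, "dimension"))
        elif child.tag == "Requirement":
            requirements[_req(child, "name")] = _dimension(_req(child, "dimension"))
        elif child.tag == "Exposure":
            exposures[_req(child, "name")] = _req(child, "variable")
        elif child.tag == "EventPort":
            event_ports[_req(child, "name")] = _req(child, "direction")
        elif child.tag == "Dynamics":
            for d in child:
                if not isinstance(d.tag, str):
                    continue
                if d.tag == "StateVariable":
                    state_variables[_req(d, "name")] = _dimension(_req(d, "dimension"))
                elif d.tag == "DerivedVariable":
                    derived_variables[_req(d, "name")] = parse_expression(_req(d, "value"))
                elif d.tag == "TimeDerivative":
                    time_derivatives[_req(d, "variable")] = parse_expression(_req(d, "value"))
                elif d.tag == "OnStart":
                    for a in d:
                        if a.tag != "StateAssignment":
                            raise UnsupportedConstructError(f"unsupported element <{a.tag}> in OnStart")
                        on_start.append((_req(a, "variable"), parse_expression(_req(a, "value"))))
                elif d.tag == "OnCondition":
                    assignments = []
                    event_out = None
                    for a in d:
                        if a.tag == "StateAssignment":
                            assignments.append((_req(a, "variable"), parse_expression(_req(a, "value"))))
                        elif a.tag == "EventOut":
                            event_out = _req(a, "port")
                        else:
                            raise UnsupportedConstructError(f"unsupported element <{a.tag}> in OnCondition")
                    on_conditions.append(OnCondition(parse_predicate(_req(d, "test")),
                                                     tuple(assignments), event_out))
                elif d.tag == "OnEvent":
                    assignments = []
                    for a in d:
                        if a.tag != "StateAssignment":
                            raise UnsupportedConstructError(f"unsupported element <{a.tag}> in OnEvent")
                        assignments.append((_req(a, "variable"), parse_expression(_req(a, "value"))))
                    on_events.append(OnEvent(_req(d, "port"), tuple(assignments)))
                else:
                    raise UnsupportedConstructError(f"unsupported dynamics element <{d.tag}>")
        else:
            raise UnsupportedConstructError(f"unsupported ComponentType element <{child.tag}>")
    ct = ComponentType(
        name=_req(el, "name"),
        parameters=parameters,
        state_variables=state_variables,
        derived_variables=derived_variables,
        time_derivatives=time_derivatives,
        on_start=tuple(on_start),
        on_conditions=tuple(on_conditions),
        on_events=tuple(on_events),
        event_ports=event_ports,
        exposures=exposures,
        requirements=requirements,
    )
    problems = ct.validate()
    if problems:
        raise LemsXMLError("; ".join(problems))
    return ct


def import_lems(document: str) -> NeuronModel:
    """Parse LEMS XML text back into a :class:`NeuronModel`."""
    try:
        root = etree.fromstring(document.encode() if isinstance(document, str) else document)
    except etree.XMLSyntaxError as exc:
        raise LemsXMLError(f"malformed XML: {exc}") from exc
    if root.tag != "Lems":
        raise LemsXMLError(f"unexpected root element {root.tag!r}")
    types: dict[str, ComponentType] = {}
    components: list[Component] = []
    links: list[Link] = []
    event_links: list[EventLink] = []
    model_root: str | None = None
    for child in root:
        if not isinstance(child.tag, str):
            continue
        if child.tag == "ComponentType":
            ct = _import_component_type(child)
            types[ct.name] = ct
        elif child.tag == "Component":
            tname = _req(child, "type")
            if tname not in types:
                raise LemsXMLError(f"component references undefined type {tname!r}")
            ct = types[tname]
            bindings = {}
            for attr, text in child.attrib.items():
                if attr in ("id", "type"):
                    continue
                value, unit = parse_quantity(text)
                bindings[attr] = (value, unit)
            try:
                components.append(instantiate(ct, bindings, id=_req(child, "id")))
            except ModelError as exc:
                raise LemsXMLError(str(exc)) from exc
        elif child.tag == "NeuronModel":
            model_root = child.get("root")
            for l_el in child:
                if l_el.tag == "Link":
                    links.append(Link(_req(l_el, "from"), _req(l_el, "exposure"),
                                      _req(l_el, "to"), _req(l_el, "requirement")))
                elif l_el.tag == "EventLink":
                    event_links.append(EventLink(_req(l_el, "from"), _req(l_el, "port"),
                                                 _req(l_el, "to"), _req(l_el, "targetPort")))
                else:
                    raise UnsupportedConstructError(f"unsupported wiring element <{l_el.tag}>")
        else:
            raise UnsupportedConstructError(f"unsupported top-level element <{child.tag}>")
    try:
        return compose_model(components, links, event_links, root=model_root)
    except ModelError as exc:
        raise LemsXMLError(str(exc)) from exc


def lems_schema_path() -> str:
    """Filesystem path of the shipped LEMS-subset XSD."""
    ref = importlib.resources.files("nemasim.lems") / "schema" / "lems_subset.xsd"
    return str(ref)
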