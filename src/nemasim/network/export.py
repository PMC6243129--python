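"""NeuroML-style network export: populations, connection lists, recording
directives, with the LEMS dynamics embedded so the document is
self-contained and executable by the reference interpreter."""

from __future__ import annotations

from dataclasses import dataclass, field

from lxml import etree

from ..lems.types import Component, ComponentType
from ..lems.xmlio import (
    LemsXMLError,
    UnsupportedConstructError,
    _export_component,
    _export_component_type,
    _import_component_type,
    _req,
)
from ..units import parse_quantity
from .config import ConfigError, NetworkConfiguration

__all__ = ["NetworkModel", "export_network", "import_network"]


@dataclass(frozen=True)
class ChemicalEdge:
    pre: str
    post: str
    synapse: str  # component id
    multiplicity: int = 1


@dataclass(frozen=True)
class GapJunctionEdge:
    a: str
    b: str
    component: str  # component id


@dataclass(frozen=True)
class NetworkModel:
    """Flattened, fully-resolved network ready for simulation.

    ``cell_of`` maps each neuron name to a component id in ``components``;
    gap junctions are symmetric single records (the interpreter expands each
    to two directed conductance terms).
    """

    components: dict[str, Component]  # id -> component (cells and synapses)
    cell_of: dict[str, str]  # neuron name -> component id
    chemical: tuple[ChemicalEdge, ...] = ()
    gap_junctions: tuple[GapJunctionEdge, ...] = ()
    recorded: tuple[tuple[str, str], ...] = ()  # (neuron, variable)

    def edge_multiset(self) -> list[tuple]:
        chem = sorted((e.pre, e.post, "chemical", e.multiplicity) for e in self.chemical)
        gaps = sorted((min(e.a, e.b), max(e.a, e.b), "gap_junction", 1) for e in self.gap_junctions)
        return chem + gaps


def _materialize(config: NetworkConfiguration) -> NetworkModel:
    """Resolve every neuron and connection to concrete components."""
    unmatched = config.unmatched_connections()
    if unmatched:
        c = unmatched[0]
        raise ConfigError(
            f"{len(unmatched)} connection(s) match no synapse rule, first: "
            f"{c.pre}->{c.post} ({c.kind})"
        )
    components: dict[str, Component] = {}
    signature_to_id: dict = {}

    def intern(component: Component, prefix: str) -> str:
        sig = (component.type.name, tuple(sorted(
            (k, v, u.name) for k, (v, u) in component.bindings.items())))
        if sig in signature_to_id:
            return signature_to_id[sig]
        cid = f"{prefix}{len(signature_to_id)}"
        signature_to_id[sig] = cid
        components[cid] = Component(id=cid, type=component.type, bindings=component.bindings)
        return cid

    cell_of = {
        name: intern(config.resolve_model(name), "comp")
        for name in config.connectome.names()
    }
    chemical = []
    gaps = []
    for conn in config.connectome.connections:
        syn_id = intern(config.resolve_synapse(conn), "comp")
        if conn.kind == "chemical":
            chemical.append(ChemicalEdge(conn.pre, conn.post, syn_id, conn.multiplicity))
        else:
            gaps.append(GapJunctionEdge(conn.pre, conn.post, syn_id))
    return NetworkModel(
        components=components,
        cell_of=cell_of,
        chemical=tuple(chemical),
        gap_junctions=tuple(gaps),
        recorded=tuple(config.recorded_variables),
    )


def export_network(config: NetworkConfiguration) -> str:
    """Serialize a fully-resolved configuration to network XML text.

    Refused (with the offending connection named) while any connection is
    unmatched or any neuron lacks a model.  Deterministic across runs.
    """
    model = _materialize(config)
    root = etree.Element("Lems")
    types: dict[str, ComponentType] = {}
    for c in model.components.values():
        types.setdefault(c.type.name, c.type)
    for name in sorted(types):
        _export_component_type(root, types[name])
    for cid in sorted(model.components):
        _export_component(root, model.components[cid])
    net = etree.SubElement(root, "Network")
    by_component: dict[str, list[str]] = {}
    for neuron, cid in model.cell_of.items():
        by_component.setdefault(cid, []).append(neuron)
    for cid in sorted(by_component):
        pop = etree.SubElement(net, "Population", component=cid)
        for neuron in sorted(by_component[cid]):
            etree.SubElement(pop, "Instance", neuron=neuron)
    for e in sorted(model.chemical, key=lambda e: (e.pre, e.post, e.synapse)):
        etree.SubElement(net, "ChemicalConnection", pre=e.pre, post=e.post,
                         synapse=e.synapse, multiplicity=str(e.multiplicity))
    for e in sorted(model.gap_junctions, key=lambda e: (e.a, e.b)):
        etree.SubElement(net, "GapJunction", a=e.a, b=e.b, component=e.component)
    for neuron, variable in model.recorded:
        etree.SubElement(net, "Record", neuron=neuron, variable=variable)
    return etree.tostring(root, pretty_print=True, encoding="unicode")


def import_network(document: str) -> NetworkModel:
    """Parse network XML text back into a :class:`NetworkModel`."""
    from ..lems.types import instantiate

    try:
        root = etree.fromstring(document.encode() if isinstance(document, str) else document)
    except etree.XMLSyntaxError as exc:
        raise LemsXMLError(f"malformed XML: {exc}") from exc
    if root.tag != "Lems":
        raise LemsXMLError(f"unexpected root element {root.tag!r}")
    types: dict[str, ComponentType] = {}
    components: dict[str, Component] = {}
    cell_of: dict[str, str] = {}
    chemical: list[ChemicalEdge] = []
    gaps: list[GapJunctionEdge] = []
    recorded: list[tuple[str, str]] = []
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
            bindings = {
                attr: parse_quantity(text)
                for attr, text in child.attrib.items()
                if attr not in ("id", "type")
            }
            cid = _req(child, "id")
            components[cid] = instantiate(types[tname], bindings, id=cid)
        elif child.tag == "Network":
            for el in child:
                if el.tag == "Population":
                    cid = _req(el, "component")
                    for inst in el:
                        if inst.tag != "Instance":
                            raise UnsupportedConstructError(f"unsupported element <{inst.tag}> in Population")
                        cell_of[_req(inst, "neuron")] = cid
                elif el.tag == "ChemicalConnection":
                    chemical.append(ChemicalEdge(
                        _req(el, "pre"), _req(el, "post"), _req(el, "synapse"),
                        int(el.get("multiplicity", "1"))))
                elif el.tag == "GapJunction":
                    gaps.append(GapJunctionEdge(_req(el, "a"), _req(el, "b"),
                                                _req(el, "component")))
                elif el.tag == "Record":
                    recorded.append((_req(el, "neuron"), _req(el, "variable")))
                else:
                    raise UnsupportedConstructError(f"unsupported network element <{el.tag}>")
        else:
            raise UnsupportedConstructError(f"unsupported top-level element <{child.tag}>")
    for cid in set(cell_of.values()):
        if cid not in components:
            raise LemsXMLError(f"population references undefined component {cid!r}")
    for e in chemical:
        if e.synapse not in components:
            raise LemsXMLError(f"connection references undefined synapse {e.synapse!r}")
        for endpoint in (e.pre, e.post):
            if endpoint not in cell_of:
                raise LemsXMLError(f"connection endpoint {endpoint!r} not in any population")
    for g in gaps:
        if g.component not in components:
            raise LemsXMLError(f"gap junction references undefined component {g.component!r}")
        for endpoint in (g.a, g.b):
            if endpoint not in cell_of:
                raise LemsXMLError(f"gap junction endpoint {endpoint!r} not in any population")
    return NetworkModel(
        components=components,
        cell_of=cell_of,
        chemical=tuple(chemical),
        gap_junctions=tuple(gaps),
        recorded=tuple(recorded),
    )
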