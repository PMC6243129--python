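"""Flattening models and networks into an executable update system.

Flattening turns the declarative description into an ordered evaluation
plan: parameter tables in SI, a global topological order over derived
variables (cycles are an error), requirement-resolution wiring (with
current-type requirements summing over all attached sources), edge-triggered
condition rules, and event routes.  The symbol table maps every runtime slot
back to its source component instance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from ..lems.types import Component, ComponentType, NeuronModel
from ..network.export import NetworkModel
from ..units import DIMENSIONS

__all__ = ["FlattenError", "Instance", "UpdateSystem", "flatten"]


class FlattenError(ValueError):
    pass


@dataclass
class Instance:
    """One live component: a cell, synapse, junction half, or generator."""

    id: str
    ctype: ComponentType
    parameters: dict[str, float]  # SI values
    # requirement -> list of (source instance id, source local variable, scale)
    requirement_sources: dict[str, list[tuple[str, str, float]]] = field(default_factory=dict)


@dataclass
class UpdateSystem:
    instances: dict[str, Instance]
    order: list[str]  # deterministic instance order (events, conditions, reporting)
    derived_plan: list[tuple[str, str]]  # (instance id, derived variable) topo-sorted
    event_routes: dict[tuple[str, str], list[tuple[str, str]]]  # (src, port) -> [(tgt, port)]
    cells: list[str]  # instance ids that represent neurons

    def state_slots(self) -> list[tuple[str, str]]:
        return [
            (iid, s)
            for iid in self.order
            for s in self.instances[iid].ctype.state_variables
        ]


def _derived_plan(instances: dict[str, Instance]) -> list[tuple[str, str]]:
    """Global topological order over (instance, derived variable) nodes,
    honoring cross-instance requirement edges."""
    g = nx.DiGraph()
    for iid, inst in instances.items():
        for name in inst.ctype.derived_variables:
            g.add_node((iid, name))
    for iid, inst in instances.items():
        ct = inst.ctype
        for name, expr in ct.derived_variables.items():
            deps = expr.free_variables()
            for dep in deps & ct.derived_variables.keys():
                g.add_edge((iid, dep), (iid, name))
            for req in deps & ct.requirements.keys():
                for src_id, src_var, _scale in inst.requirement_sources.get(req, []):
                    if src_var in instances[src_id].ctype.derived_variables:
                        g.add_edge((src_id, src_var), (iid, name))
    try:
        order = list(nx.lexicographical_topological_sort(g))
    except nx.NetworkXUnfeasible:
        raise FlattenError("cyclic derived-variable dependency across components") from None
    return order


_CURRENT = DIMENSIONS["current"]


def _flatten_neuron_model(model: NeuronModel) -> UpdateSystem:
    instances: dict[str, Instance] = {}
    for c in model.components:
        instances[c.id] = Instance(id=c.id, ctype=c.type, parameters=c.si_parameters())
    for link in model.links:
        src = instances[link.source]
        tgt = instances[link.target]
        local = src.ctype.exposures[link.exposure]
        tgt.requirement_sources.setdefault(link.requirement, []).append((src.id, local, 1.0))
    routes: dict[tuple[str, str], list[tuple[str, str]]] = {}
    for el in model.event_links:
        routes.setdefault((el.source, el.port_out), []).append((el.target, el.port_in))
    order = sorted(instances)
    cells = [model.root] if model.root else []
    return UpdateSystem(
        instances=instances,
        order=order,
        derived_plan=_derived_plan(instances),
        event_routes=routes,
        cells=cells,
    )


def _flatten_network(model: NetworkModel) -> UpdateSystem:
    instances: dict[str, Instance] = {}
    routes: dict[tuple[str, str], list[tuple[str, str]]] = {}

    def cell_component(neuron: str) -> Component:
        return model.components[model.cell_of[neuron]]

    for neuron in sorted(model.cell_of):
        c = cell_component(neuron)
        instances[neuron] = Instance(id=neuron, ctype=c.type, parameters=c.si_parameters())

    def spike_port(ct: ComponentType) -> str | None:
        for port, direction in ct.event_ports.items():
            if direction == "out":
                return port
        return None

    def in_port(ct: ComponentType) -> str:
        for port, direction in ct.event_ports.items():
            if direction == "in":
                return port
        raise FlattenError(f"synapse type {ct.name!r} has no input event port")

    def attach_current(target: str, source_id: str, exposure: str, scale: float) -> None:
        inst = instances[target]
        current_reqs = [r for r, d in inst.ctype.requirements.items() if d == _CURRENT]
        if not current_reqs:
            raise FlattenError(
                f"cell {target!r} ({inst.ctype.name}) accepts no current input"
            )
        local = instances[source_id].ctype.exposures[exposure]
        inst.requirement_sources.setdefault(current_reqs[0], []).append(
            (source_id, local, scale)
        )

    for i, edge in enumerate(sorted(model.chemical, key=lambda e: (e.pre, e.post, e.synapse))):
        syn = model.components[edge.synapse]
        sid = f"syn{i}:{edge.pre}->{edge.post}"
        inst = Instance(id=sid, ctype=syn.type, parameters=syn.si_parameters())
        # postsynaptic membrane potential feeds the synapse's v requirement
        if "v" in syn.type.requirements:
            post_v = instances[edge.post].ctype.exposures["v"]
            inst.requirement_sources["v"] = [(edge.post, post_v, 1.0)]
        instances[sid] = inst
        # synaptic current sums into the post cell, scaled by multiplicity
        attach_current(edge.post, sid, "i", float(edge.multiplicity))
        pre_port = spike_port(instances[edge.pre].ctype)
        if pre_port is None:
            raise FlattenError(f"presynaptic cell {edge.pre!r} emits no events")
        routes.setdefault((edge.pre, pre_port), []).append((sid, in_port(syn.type)))

    for i, edge in enumerate(sorted(model.gap_junctions, key=lambda e: (e.a, e.b))):
        gj = model.components[edge.component]
        # one symmetric record expands to two directed conductance terms
        for tag, this, peer in ((f"gap{i}a:{edge.a}<->{edge.b}", edge.a, edge.b),
                                (f"gap{i}b:{edge.b}<->{edge.a}", edge.b, edge.a)):
            inst = Instance(id=tag, ctype=gj.type, parameters=gj.si_parameters())
            inst.requirement_sources["v"] = [
                (this, instances[this].ctype.exposures["v"], 1.0)
            ]
            inst.requirement_sources["vpeer"] = [
                (peer, instances[peer].ctype.exposures["v"], 1.0)
            ]
            instances[tag] = inst
            attach_current(this, tag, "i", 1.0)

    order = sorted(model.cell_of) + sorted(set(instances) - set(model.cell_of))
    return UpdateSystem(
        instances=instances,
        order=order,
        derived_plan=_derived_plan(instances),
        event_routes=routes,
        cells=sorted(model.cell_of),
    )


def flatten(model: NeuronModel | NetworkModel) -> UpdateSystem:
    """Build the ordered evaluation plan for a single model or a network."""
    if isinstance(model, NeuronModel):
        system = _flatten_neuron_model(model)
    elif isinstance(model, NetworkModel):
        system = _flatten_network(model)
    else:
        raise TypeError(f"cannot flatten {type(model).__name__}")
    # every non-current requirement must be wired; current requirements
    # default to a zero sum (isolated cells still run)
    for iid in system.order:
        inst = system.instances[iid]
        for req, dim in inst.ctype.requirements.items():
            if req not in inst.requirement_sources and dim != _CURRENT:
                raise FlattenError(f"requirement {req!r} of {iid!r} is unwired")
    return system
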