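"""LEMS-style building blocks: dynamics templates and parameterized instances.

A :class:`ComponentType` holds model *dynamics* — state variables, derived
variables, time derivatives and event rules — while a :class:`Component`
binds the type's parameters to concrete values with units.  Two Components of
one ComponentType therefore share identical dynamics structure and differ
only in their bindings.  A :class:`NeuronModel` wires Components together by
linking one component's exposures to another's requirements, and connecting
event ports.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from ..expressions import ExpressionError, Node, parse_expression, parse_predicate
from ..units import DIMENSIONS, Dimension, Unit, get_unit

__all__ = [
    "ModelError",
    "OnCondition",
    "OnEvent",
    "ComponentType",
    "Component",
    "Link",
    "EventLink",
    "NeuronModel",
    "instantiate",
    "compose_model",
]

TIME_SYMBOL = "t"


class ModelError(ValueError):
    """Invalid component type, binding, or model composition."""


@dataclass(frozen=True)
class OnCondition:
    """Edge-triggered rule: fires when the predicate turns true."""

    test: Node
    assignments: tuple[tuple[str, Node], ...] = ()
    event_out: str | None = None  # output port to emit on

    @classmethod
    def parse(cls, test: str, assignments: dict[str, str] | None = None,
              event_out: str | None = None) -> "OnCondition":
        return cls(
            parse_predicate(test),
            tuple((k, parse_expression(v)) for k, v in (assignments or {}).items()),
            event_out,
        )


@dataclass(frozen=True)
class OnEvent:
    """Handler for events arriving on an input port."""

    port: str
    assignments: tuple[tuple[str, Node], ...] = ()

    @classmethod
    def parse(cls, port: str, assignments: dict[str, str]) -> "OnEvent":
        return cls(port, tuple((k, parse_expression(v)) for k, v in assignments.items()))


@dataclass(frozen=True)
class ComponentType:
    name: str
    parameters: dict[str, Dimension] = field(default_factory=dict)
    state_variables: dict[str, Dimension] = field(default_factory=dict)
    derived_variables: dict[str, Node] = field(default_factory=dict)
    time_derivatives: dict[str, Node] = field(default_factory=dict)
    on_start: tuple[tuple[str, Node], ...] = ()
    on_conditions: tuple[OnCondition, ...] = ()
    on_events: tuple[OnEvent, ...] = ()
    event_ports: dict[str, str] = field(default_factory=dict)  # name -> in|out
    exposures: dict[str, str] = field(default_factory=dict)  # exposure -> local var
    requirements: dict[str, Dimension] = field(default_factory=dict)

    # -- structural checks -------------------------------------------------

    def symbol_dimensions(self) -> dict[str, Dimension]:
        """Dimensions of every resolvable symbol, deriveds included."""
        dims: dict[str, Dimension] = {TIME_SYMBOL: DIMENSIONS["time"]}
        dims.update(self.parameters)
        dims.update(self.state_variables)
        dims.update(self.requirements)
        for name in self._derived_order():
            dims[name] = self.derived_variables[name].infer_dimension(dims)
        return dims

    def _derived_order(self) -> list[str]:
        """Derived variables topologically sorted; cycles are an error."""
        g = nx.DiGraph()
        g.add_nodes_from(self.derived_variables)
        for name, expr in self.derived_variables.items():
            for dep in expr.free_variables() & self.derived_variables.keys():
                g.add_edge(dep, name)
        try:
            order = list(nx.topological_sort(g))
        except nx.NetworkXUnfeasible:
            raise ModelError(
                f"{self.name}: cyclic derived-variable dependency"
            ) from None
        # stable order for determinism: topo generations sorted by name
        return sorted(order, key=lambda n: (len(nx.ancestors(g, n)), n))

    def validate(self) -> list[str]:
        """All structural invariant violations, as strings."""
        errors: list[str] = []
        cats = [
            ("parameter", self.parameters),
            ("state variable", self.state_variables),
            ("derived variable", self.derived_variables),
            ("requirement", self.requirements),
        ]
        seen: dict[str, str] = {}
        for label, names in cats:
            for n in names:
                if n == TIME_SYMBOL:
                    errors.append(f"{self.name}: symbol {n!r} shadows the time symbol")
                elif n in seen:
                    errors.append(
                        f"{self.name}: {label} {n!r} shadows a {seen[n]} of the same name"
                    )
                else:
                    seen[n] = label
        known = set(seen) | {TIME_SYMBOL}

        def check_expr(context: str, expr: Node) -> None:
            for sym in expr.free_variables() - known:
                errors.append(f"{self.name}: {context} references unknown symbol {sym!r}")

        for name, expr in self.derived_variables.items():
            check_expr(f"derived variable {name!r}", expr)
        for name, expr in self.time_derivatives.items():
            if name not in self.state_variables:
                errors.append(f"{self.name}: time derivative for non-state {name!r}")
            check_expr(f"d{name}/dt", expr)
        for name, expr in self.on_start:
            if name not in self.state_variables:
                errors.append(f"{self.name}: on-start assignment to non-state {name!r}")
            check_expr("on-start assignment", expr)
        for rule in self.on_conditions:
            check_expr("condition predicate", rule.test)
            for name, expr in rule.assignments:
                if name not in self.state_variables:
                    errors.append(f"{self.name}: condition assigns non-state {name!r}")
                check_expr("condition assignment", expr)
            if rule.event_out is not None and self.event_ports.get(rule.event_out) != "out":
                errors.append(f"{self.name}: condition emits on non-output port {rule.event_out!r}")
        for handler in self.on_events:
            if self.event_ports.get(handler.port) != "in":
                errors.append(f"{self.name}: handler on non-input port {handler.port!r}")
            for name, expr in handler.assignments:
                if name not in self.state_variables:
                    errors.append(f"{self.name}: event handler assigns non-state {name!r}")
                check_expr("event assignment", expr)
        for exposure, local in self.exposures.items():
            if local not in set(self.state_variables) | set(self.derived_variables) | set(self.parameters):
                errors.append(f"{self.name}: exposure {exposure!r} references undefined variable {local!r}")
        if not errors:
            try:
                self._derived_order()
                self.check_dimensions()
            except (ModelError, ExpressionError) as exc:
                errors.append(str(exc))
        return errors

    def check_dimensions(self) -> None:
        """Dimensional closure: every derived/derivative expression is
        well-dimensioned and d(state)/dt has dimension(state)/time."""
        dims = self.symbol_dimensions()
        time = DIMENSIONS["time"]
        for name, expr in self.time_derivatives.items():
            d = expr.infer_dimension(dims)
            expected = self.state_variables[name] / time
            if d != expected:
                raise ModelError(
                    f"{self.name}: d{name}/dt has dimension {d}, expected {expected}"
                )
        for name, expr in self.on_start:
            if expr.infer_dimension(dims) != self.state_variables[name]:
                raise ModelError(f"{self.name}: on-start assignment to {name!r} has wrong dimension")
        for rule in self.on_conditions:
            rule.test.infer_dimension(dims)
            for name, expr in rule.assignments:
                if expr.infer_dimension(dims) != self.state_variables[name]:
                    raise ModelError(
                        f"{self.name}: condition assignment to {name!r} has wrong dimension"
                    )
        for handler in self.on_events:
            for name, expr in handler.assignments:
                if expr.infer_dimension(dims) != self.state_variables[name]:
                    raise ModelError(
                        f"{self.name}: event assignment to {name!r} has wrong dimension"
                    )

    def exposure_dimension(self, exposure: str) -> Dimension:
        return self.symbol_dimensions()[self.exposures[exposure]]


@dataclass(frozen=True)
class Component:
    """A fully parameterized instance of a ComponentType."""

    id: str
    type: ComponentType
    bindings: dict[str, tuple[float, Unit]] = field(default_factory=dict)

    def si_parameters(self) -> dict[str, float]:
        """Parameter values converted to SI."""
        return {name: unit.to_si(value) for name, (value, unit) in self.bindings.items()}


def instantiate(ctype: ComponentType, bindings: dict[str, object], id: str = "") -> Component:
    """Bind every parameter of ``ctype`` exactly once, with unit checking.

    ``bindings`` maps parameter names to ``(value, unit_name)`` pairs or to
    quantity strings like ``"5 mV"``.  All problems (unbound, unknown,
    dimensionally wrong) are reported together in one :class:`ModelError`.
    """
    from ..units import parse_quantity

    errors = []
    resolved: dict[str, tuple[float, Unit]] = {}
    for name, spec in bindings.items():
        if name not in ctype.parameters:
            errors.append(f"unknown parameter {name!r} for type {ctype.name!r}")
            continue
        try:
            if isinstance(spec, str):
                value, unit = parse_quantity(spec)
            else:
                value, unit_name = spec
                unit = get_unit(unit_name) if isinstance(unit_name, str) else unit_name
            value = float(value)
        except (ValueError, TypeError) as exc:
            errors.append(f"bad binding for {name!r}: {exc}")
            continue
        if unit.dimension != ctype.parameters[name]:
            errors.append(
                f"parameter {name!r} has dimension {ctype.parameters[name]}, "
                f"but unit {unit.name!r} has dimension {unit.dimension}"
            )
            continue
        resolved[name] = (value, unit)
    for name in ctype.parameters:
        if name not in bindings:
            errors.append(f"unbound parameter {name!r} of type {ctype.name!r}")
    if errors:
        raise ModelError("; ".join(errors))
    return Component(id=id or ctype.name, type=ctype, bindings=resolved)


@dataclass(frozen=True)
class Link:
    """Wire a source component's exposure into a target's requirement."""

    source: str
    exposure: str
    target: str
    requirement: str


@dataclass(frozen=True)
class EventLink:
    source: str
    port_out: str
    target: str
    port_in: str


@dataclass(frozen=True)
class NeuronModel:
    """A root component plus linked child building blocks."""

    root: str  # component id
    components: tuple[Component, ...]
    links: tuple[Link, ...] = ()
    event_links: tuple[EventLink, ...] = ()

    def component(self, cid: str) -> Component:
        for c in self.components:
            if c.id == cid:
                return c
        raise ModelError(f"no component with id {cid!r}")

    def component_ids(self) -> list[str]:
        return [c.id for c in self.components]


def compose_model(
    components: list[Component],
    links: list[Link] = (),
    event_links: list[EventLink] = (),
    root: str | None = None,
) -> NeuronModel:
    """Assemble components into a validated :class:`NeuronModel`.

    Every requirement of every component must be satisfied by exactly one
    link; link endpoints must exist and be dimension-compatible; dangling
    event connections are rejected.
    """
    errors: list[str] = []
    by_id: dict[str, Component] = {}
    for c in components:
        if c.id in by_id:
            errors.append(f"duplicate component id {c.id!r}")
        by_id[c.id] = c
    seen_links = set()
    satisfied: dict[tuple[str, str], int] = {}
    for link in links:
        if link in seen_links:
            errors.append(f"duplicate link {link}")
            continue
        seen_links.add(link)
        src = by_id.get(link.source)
        tgt = by_id.get(link.target)
        if src is None or tgt is None:
            errors.append(f"link endpoint missing: {link}")
            continue
        if link.exposure not in src.type.exposures:
            errors.append(f"{link.source!r} has no exposure {link.exposure!r}")
            continue
        if link.requirement not in tgt.type.requirements:
            errors.append(f"{link.target!r} has no requirement {link.requirement!r}")
            continue
        d_src = src.type.exposure_dimension(link.exposure)
        d_req = tgt.type.requirements[link.requirement]
        if d_src != d_req:
            errors.append(
                f"dimension-incompatible link {link.source}.{link.exposure} "
                f"({d_src}) -> {link.target}.{link.requirement} ({d_req})"
            )
            continue
        satisfied[(link.target, link.requirement)] = (
            satisfied.get((link.target, link.requirement), 0) + 1
        )
    for c in components:
        for req in c.type.requirements:
            n = satisfied.get((c.id, req), 0)
            if n == 0:
                errors.append(f"unresolved requirement {req!r} of component {c.id!r}")
            elif n > 1:
                errors.append(f"requirement {req!r} of {c.id!r} satisfied by {n} links")
    for el in event_links:
        src = by_id.get(el.source)
        tgt = by_id.get(el.target)
        if src is None or tgt is None:
            errors.append(f"event link endpoint missing: {el}")
            continue
        if src.type.event_ports.get(el.port_out) != "out":
            errors.append(f"{el.source!r} has no output port {el.port_out!r}")
        if tgt.type.event_ports.get(el.port_in) != "in":
            errors.append(f"{el.target!r} has no input port {el.port_in!r}")
    if root is None and components:
        root = components[0].id
    if root is not None and root not in by_id:
        errors.append(f"root component {root!r} not among components")
    if errors:
        raise ModelError("; ".join(errors))
    return NeuronModel(
        root=root or "",
        components=tuple(components),
        links=tuple(links),
        event_links=tuple(event_links),
    )
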