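"""Network configuration: assigning models to a fixed connectome.

The workflow mirrors the default-then-customize pattern: set a generic
neuron model and synapse model for the whole worm, then override groups or
single neurons/connections with ordered selector rules (later assignments
win).  Topology is never modified — only annotations change.  Recorded
variables are auto-selected once every neuron resolves to a model: the
membrane-potential exposure plus all state variables of the resolved model.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum

from ..lems.types import Component, ModelError, instantiate
from .connectome import Connection, Connectome, Neuron

__all__ = [
    "ConfigError",
    "NeuronSelector",
    "SynapseSelector",
    "NetworkConfiguration",
    "SelectionMode",
    "SelectionSession",
    "assign_models",
    "assign_synapses",
    "override_parameters",
    "auto_select_recorded_variables",
]


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class NeuronSelector:
    """Match neurons by explicit names, class, or functional category.

    Empty selector (no constraints) matches every neuron.
    """

    names: tuple[str, ...] = ()
    neuron_class: str | None = None
    category: str | None = None  # sensory | inter | motor

    def matches(self, neuron: Neuron) -> bool:
        if self.names and neuron.name not in self.names:
            return False
        if self.neuron_class is not None and neuron.neuron_class != self.neuron_class:
            return False
        if self.category is not None and neuron.category != self.category:
            return False
        return True


@dataclass(frozen=True)
class SynapseSelector:
    """Match connections by kind, putative neurotransmitter, or endpoints."""

    kind: str | None = None  # chemical | gap_junction
    neurotransmitter: str | None = None
    pre: str | None = None
    post: str | None = None

    def matches(self, conn: Connection) -> bool:
        if self.kind is not None and conn.kind != self.kind:
            return False
        if self.neurotransmitter is not None and conn.neurotransmitter != self.neurotransmitter:
            return False
        if self.pre is not None and conn.pre != self.pre:
            return False
        if self.post is not None and conn.post != self.post:
            return False
        return True


def _is_cell(component: Component) -> bool:
    # a cell exposes a membrane potential and integrates current
    return "v" in component.type.exposures and "v" in component.type.state_variables


def _is_chemical_synapse(component: Component) -> bool:
    return any(d == "in" for d in component.type.event_ports.values())


def _is_gap_junction(component: Component) -> bool:
    return "vpeer" in component.type.requirements


@dataclass(frozen=True)
class NetworkConfiguration:
    """Immutable annotation layer over a fixed-topology connectome."""

    connectome: Connectome
    default_model: Component | None = None
    model_rules: tuple[tuple[NeuronSelector, Component], ...] = ()
    synapse_rules: tuple[tuple[SynapseSelector, Component], ...] = ()
    parameter_overrides: tuple[tuple[str, str, float, str], ...] = ()  # neuron, param, value, unit
    recorded_variables: tuple[tuple[str, str], ...] = ()

    # -- resolution --------------------------------------------------------

    def resolve_model(self, neuron_name: str) -> Component:
        """The model for one neuron: last matching override, else the default,
        with any per-neuron parameter overrides rebound."""
        neuron = self.connectome.neuron(neuron_name)
        component = self.default_model
        for selector, candidate in self.model_rules:
            if selector.matches(neuron):
                component = candidate
        if component is None:
            raise ConfigError(f"neuron {neuron_name!r} resolves to no model")
        overrides = {
            param: (value, unit)
            for name, param, value, unit in self.parameter_overrides
            if name == neuron_name
        }
        if overrides:
            bindings = {k: v for k, v in component.bindings.items()}
            bindings.update(overrides)
            try:
                component = instantiate(component.type, bindings, id=component.id)
            except ModelError as exc:
                raise ConfigError(f"override for {neuron_name!r}: {exc}") from exc
        return component

    def resolve_synapse(self, conn: Connection) -> Component:
        component = None
        for selector, candidate in self.synapse_rules:
            if selector.matches(conn):
                component = candidate
        if component is None:
            raise ConfigError(
                f"connection {conn.pre}->{conn.post} ({conn.kind}) matches no synapse rule"
            )
        return component

    def unmatched_connections(self) -> list[Connection]:
        out = []
        for conn in self.connectome.connections:
            try:
                self.resolve_synapse(conn)
            except ConfigError:
                out.append(conn)
        return out

    def is_fully_resolved(self) -> bool:
        try:
            for name in self.connectome.names():
                self.resolve_model(name)
        except ConfigError:
            return False
        return not self.unmatched_connections()


def assign_models(
    config: NetworkConfiguration,
    selector: NeuronSelector,
    component: Component,
) -> NetworkConfiguration:
    """Append an ordered model-assignment rule (later assignments win).

    An empty selector match is reported as a warning, not an error.
    """
    if not _is_cell(component):
        raise ConfigError(
            f"component {component.id!r} of type {component.type.name!r} is not a cell model"
        )
    matched = [n for n in config.connectome.neurons if selector.matches(n)]
    if not matched:
        import warnings

        warnings.warn(f"selector {selector} matches no neuron", stacklevel=2)
    if selector == NeuronSelector():  # unconstrained: this is the new default
        return replace(config, default_model=component)
    return replace(config, model_rules=config.model_rules + ((selector, component),))


def assign_synapses(
    config: NetworkConfiguration,
    selector: SynapseSelector,
    component: Component,
) -> NetworkConfiguration:
    """Append an ordered synapse-assignment rule, with kind checking."""
    if selector.kind == "gap_junction" and not _is_gap_junction(component):
        raise ConfigError(
            f"component {component.id!r} is not a gap junction but the selector targets gap junctions"
        )
    if selector.kind == "chemical" and not _is_chemical_synapse(component):
        raise ConfigError(
            f"component {component.id!r} is not a chemical synapse but the selector targets chemical connections"
        )
    if selector.kind is None and not (_is_chemical_synapse(component) or _is_gap_junction(component)):
        raise ConfigError(f"component {component.id!r} is neither synapse nor gap junction")
    matched = [c for c in config.connectome.connections if selector.matches(c)]
    if not matched:
        import warnings

        warnings.warn(f"selector {selector} matches no connection", stacklevel=2)
    return replace(config, synapse_rules=config.synapse_rules + ((selector, component),))


def override_parameters(
    config: NetworkConfiguration,
    neuron: str,
    overrides: dict[str, tuple[float, str]],
) -> NetworkConfiguration:
    """Per-neuron parameter overrides, e.g. ``{"thresh": (-45.0, "mV")}``."""
    config.connectome.neuron(neuron)
    added = tuple((neuron, p, float(v), u) for p, (v, u) in overrides.items())
    return replace(config, parameter_overrides=config.parameter_overrides + added)


def auto_select_recorded_variables(config: NetworkConfiguration) -> NetworkConfiguration:
    """Record, for every neuron, the membrane-potential exposure plus all
    state variables of its resolved model.  Idempotent; the user may edit the
    resulting list afterwards."""
    recorded: list[tuple[str, str]] = []
    for name in config.connectome.names():
        component = config.resolve_model(name)  # raises if unresolved
        variables = []
        if "v" in component.type.exposures:
            variables.append(component.type.exposures["v"])
        for state in component.type.state_variables:
            if state not in variables:
                variables.append(state)
        recorded.extend((name, var) for var in variables)
    return replace(config, recorded_variables=tuple(recorded))


class SelectionMode(str, Enum):
    NEURON_SELECTION = "neuron_selection"
    NEURON_PARAMETER = "neuron_parameter"
    SYNAPSE_SELECTION = "synapse_selection"


class SelectionSession:
    """Stateful wrapper enforcing the three display modes: each operation is
    only legal in its own mode."""

    def __init__(self, config: NetworkConfiguration,
                 mode: SelectionMode = SelectionMode.NEURON_SELECTION):
        self.config = config
        self.mode = mode

    def set_mode(self, mode: SelectionMode) -> None:
        self.mode = SelectionMode(mode)

    def _require(self, mode: SelectionMode) -> None:
        if self.mode is not mode:
            raise ConfigError(f"operation requires {mode.value} mode, current mode is {self.mode.value}")

    def assign_models(self, selector: NeuronSelector, component: Component) -> None:
        self._require(SelectionMode.NEURON_SELECTION)
        self.config = assign_models(self.config, selector, component)

    def override_parameters(self, neuron: str, overrides: dict[str, tuple[float, str]]) -> None:
        self._require(SelectionMode.NEURON_PARAMETER)
        self.config = override_parameters(self.config, neuron, overrides)

    def assign_synapses(self, selector: SynapseSelector, component: Component) -> None:
        self._require(SelectionMode.SYNAPSE_SELECTION)
        self.config = assign_synapses(self.config, selector, component)
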