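"""Reference integrator for flattened update systems.

The default scheme is forward Euler (the kind of update rule hardware
implementations use), with a classical Runge–Kutta (RK4) option as a
cross-check for smooth dynamics.  Event semantics: condition predicates are
edge-triggered and tested after each state update, in instance-name order;
reset assignments apply before event delivery within the same step; events
are delivered synchronously within the step.  The run is fully
deterministic — identical specs produce bit-identical results.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..lems.types import NeuronModel
from ..network.export import NetworkModel
from .flatten import FlattenError, UpdateSystem, flatten
from .waveform import Waveform

__all__ = ["SimulationSpec", "SimulationResultSet", "SimulationError", "run"]


class SimulationError(RuntimeError):
    pass


@dataclass(frozen=True)
class SimulationSpec:
    """What to simulate: model/network, clock, injections, recordings."""

    model: NeuronModel | NetworkModel
    duration: float  # ms
    dt: float = 0.05  # ms
    injections: tuple[tuple[str, Waveform], ...] = ()  # (target instance, nA waveform)
    recorded: tuple[tuple[str, str], ...] | None = None  # None: auto
    method: str = "euler"  # euler | rk4

    def validate(self, system: UpdateSystem) -> None:
        if not 0 < self.dt <= self.duration:
            raise ValueError(f"need 0 < dt <= duration, got dt={self.dt}, duration={self.duration}")
        if self.method not in ("euler", "rk4"):
            raise ValueError(f"unknown integration method {self.method!r}")
        for target, _wf in self.injections:
            if target not in system.instances:
                raise ValueError(f"injection targets unknown instance {target!r}")


@dataclass
class SimulationResultSet:
    """Per-(instance, variable) traces on one uniform clock, plus spikes."""

    times: np.ndarray  # ms, length floor(duration/dt)+1
    dt: float  # ms
    traces: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)
    spikes: dict[str, list[float]] = field(default_factory=dict)  # instance -> spike times ms

    def trace(self, instance: str, variable: str) -> np.ndarray:
        return self.traces[(instance, variable)]


def _default_recordings(system: UpdateSystem) -> list[tuple[str, str]]:
    """Membrane potential plus state variables for every cell instance."""
    out = []
    targets = system.cells or system.order
    for iid in targets:
        ct = system.instances[iid].ctype
        variables = []
        if "v" in ct.exposures:
            variables.append(ct.exposures["v"])
        for s in ct.state_variables:
            if s not in variables:
                variables.append(s)
        out.extend((iid, v) for v in variables)
    return out


class _Evaluator:
    """Evaluates the system's algebraic layer at a given state and time."""

    def __init__(self, system: UpdateSystem, injections):
        self.system = system
        self.inj: dict[str, list[Waveform]] = {}
        for target, wf in injections:
            self.inj.setdefault(target, []).append(wf)
        # precompute which requirement each injection feeds (first current req)
        from ..units import DIMENSIONS

        current = DIMENSIONS["current"]
        self.inj_req: dict[str, str] = {}
        for target in self.inj:
            reqs = [r for r, d in system.instances[target].ctype.requirements.items()
                    if d == current]
            if not reqs:
                raise FlattenError(f"injection target {target!r} accepts no current input")
            self.inj_req[target] = reqs[0]

    def algebra(self, states: dict, t_si: float) -> dict[str, dict[str, float]]:
        """Per-instance environments with requirements and deriveds filled in."""
        system = self.system
        envs: dict[str, dict[str, float]] = {}
        for iid in system.order:
            inst = system.instances[iid]
            env = dict(inst.parameters)
            env["t"] = t_si
            for s in inst.ctype.state_variables:
                env[s] = states[(iid, s)]
            envs[iid] = env
        # requirements that depend only on states/params can resolve in any
        # order; those sourced from deriveds resolve along the derived plan
        def resolve_requirements(iid: str) -> None:
            inst = system.instances[iid]
            env = envs[iid]
            for req in inst.ctype.requirements:
                total = 0.0
                for src_id, src_var, scale in inst.requirement_sources.get(req, ()):
                    total += scale * envs[src_id][src_var]
                if iid in self.inj and self.inj_req[iid] == req:
                    t_ms = t_si * 1e3
                    total += sum(wf.value(t_ms) for wf in self.inj[iid]) * 1e-9
                env[req] = total

        # first pass: requirements sourced from states (cell v into synapses)
        for iid in system.order:
            inst = system.instances[iid]
            ok = all(
                src_var not in system.instances[src_id].ctype.derived_variables
                for req in inst.ctype.requirements
                for src_id, src_var, _ in inst.requirement_sources.get(req, ())
            )
            if ok:
                resolve_requirements(iid)
        for iid, name in system.derived_plan:
            inst = system.instances[iid]
            # requirements must be current before a derived that reads them
            resolve_requirements(iid)
            envs[iid][name] = inst.ctype.derived_variables[name].evaluate(envs[iid])
        # final requirement pass: instances whose requirements read deriveds
        for iid in system.order:
            resolve_requirements(iid)
        return envs

    def derivatives(self, states: dict, t_si: float) -> dict:
        envs = self.algebra(states, t_si)
        out = {}
        for (iid, s) in states:
            expr = self.system.instances[iid].ctype.time_derivatives.get(s)
            out[(iid, s)] = expr.evaluate(envs[iid]) if expr is not None else 0.0
        return out


def run(spec: SimulationSpec) -> SimulationResultSet:
    """Integrate the spec's model and return fully-populated traces.

    Raises :class:`SimulationError` with the offending time and instance on
    numerical overflow.
    """
    system = flatten(spec.model)
    spec.validate(system)
    dt_si = spec.dt * 1e-3
    n_steps = int(np.floor(spec.duration / spec.dt + 1e-9))
    times = np.arange(n_steps + 1) * spec.dt
    recorded = list(spec.recorded) if spec.recorded is not None else _default_recordings(system)
    if spec.recorded is None and isinstance(spec.model, NetworkModel) and spec.model.recorded:
        recorded = list(spec.model.recorded)
    evaluator = _Evaluator(system, spec.injections)

    # initial state: on-start assignments evaluated in a parameter env
    states: dict[tuple[str, str], float] = {}
    for iid in system.order:
        inst = system.instances[iid]
        env = dict(inst.parameters)
        env["t"] = 0.0
        for s in inst.ctype.state_variables:
            states[(iid, s)] = 0.0
            env[s] = 0.0
        for name, expr in inst.ctype.on_start:
            value = expr.evaluate(env)
            states[(iid, name)] = value
            env[name] = value

    prev_tests: dict[tuple[str, int], bool] = {
        (iid, k): False
        for iid in system.order
        for k in range(len(system.instances[iid].ctype.on_conditions))
    }
    result = SimulationResultSet(times=times, dt=spec.dt)
    buffers = {key: np.empty(n_steps + 1) for key in recorded}
    spikes: dict[str, list[float]] = {iid: [] for iid in system.cells or system.order}

    def apply_events_and_conditions(t_si: float, t_ms: float) -> None:
        envs = evaluator.algebra(states, t_si)
        emitted: list[tuple[str, str]] = []
        for iid in system.order:  # deterministic name-order tie-break
            inst = system.instances[iid]
            for k, rule in enumerate(inst.ctype.on_conditions):
                value = bool(rule.test.evaluate(envs[iid]))
                if value and not prev_tests[(iid, k)]:
                    env = envs[iid]
                    for name, expr in rule.assignments:
                        new = expr.evaluate(env)
                        states[(iid, name)] = new
                        env[name] = new
                    if rule.event_out is not None:
                        emitted.append((iid, rule.event_out))
                prev_tests[(iid, k)] = value
        for src, port in emitted:
            if src in spikes:
                spikes[src].append(t_ms)
            for tgt, in_port in system.event_routes.get((src, port), ()):
                tgt_inst = system.instances[tgt]
                env = envs[tgt]
                for handler in tgt_inst.ctype.on_events:
                    if handler.port == in_port:
                        for name, expr in handler.assignments:
                            new = expr.evaluate(env)
                            states[(tgt, name)] = new
                            env[name] = new

    def record(step: int, t_si: float) -> None:
        envs = evaluator.algebra(states, t_si)
        for (iid, var) in recorded:
            env = envs.get(iid)
            if env is None or var not in env:
                raise SimulationError(f"recorded variable {var!r} of {iid!r} does not exist")
            buffers[(iid, var)][step] = env[var]

    # conditions already true at t=0 fire before the first step
    apply_events_and_conditions(0.0, 0.0)
    record(0, 0.0)

    for step in range(1, n_steps + 1):
        t0_si = (step - 1) * dt_si
        t1_si = step * dt_si
        if spec.method == "euler":
            deriv = evaluator.derivatives(states, t0_si)
            for key, d in deriv.items():
                states[key] += dt_si * d
        else:  # rk4
            k1 = evaluator.derivatives(states, t0_si)
            mid = {k: states[k] + 0.5 * dt_si * k1[k] for k in states}
            k2 = evaluator.derivatives(mid, t0_si + 0.5 * dt_si)
            mid = {k: states[k] + 0.5 * dt_si * k2[k] for k in states}
            k3 = evaluator.derivatives(mid, t0_si + 0.5 * dt_si)
            end = {k: states[k] + dt_si * k3[k] for k in states}
            k4 = evaluator.derivatives(end, t1_si)
            for k in states:
                states[k] += dt_si / 6.0 * (k1[k] + 2 * k2[k] + 2 * k3[k] + k4[k])
        for key, value in states.items():
            if not np.isfinite(value):
                iid, var = key
                raise SimulationError(
                    f"numerical overflow in {var!r} of {iid!r} at t={step * spec.dt:.6g} ms"
                )
        apply_events_and_conditions(t1_si, step * spec.dt)
        record(step, t1_si)

    result.traces = buffers
    result.spikes = spikes
    return result
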