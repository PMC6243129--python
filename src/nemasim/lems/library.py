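"""Core library of point-neuron building blocks.

A pragmatic subset of the standard LEMS/NeuroML2 core types: leaky
integrate-and-fire and Izhikevich cells, a two-rate Hodgkin–Huxley-style
gating particle, current generators, a single-exponential chemical synapse
and a linear gap junction.  Every type passes the full structural and
dimensional invariant checks at load time.

The Izhikevich cell uses the dimensional (2007) formulation::

    C dv/dt = k (v - vr)(v - vt) - u + iSyn
    du/dt   = a (b (v - vr) - u)

with a peak-and-reset rule at ``vpeak``, so one set of dynamics covers the
regular-spiking/bursting/chattering regimes purely through parameterization.
"""

from __future__ import annotations

from functools import lru_cache

from ..expressions import parse_expression as e
from ..units import DIMENSIONS as D
from .types import ComponentType, OnCondition, OnEvent

__all__ = ["load_core_library", "core_type"]


def _iaf_cell() -> ComponentType:
    return ComponentType(
        name="iafCell",
        parameters={
            "C": D["capacitance"],
            "gLeak": D["conductance"],
            "eLeak": D["voltage"],
            "thresh": D["voltage"],
            "reset": D["voltage"],
        },
        state_variables={"v": D["voltage"]},
        time_derivatives={"v": e("(gLeak * (eLeak - v) + iSyn) / C")},
        on_start=(("v", e("reset")),),
        on_conditions=(
            OnCondition.parse("v >= thresh", {"v": "reset"}, event_out="spike"),
        ),
        event_ports={"spike": "out"},
        exposures={"v": "v"},
        requirements={"iSyn": D["current"]},
    )


def _izhikevich_cell() -> ComponentType:
    return ComponentType(
        name="izhikevichCell",
        parameters={
            "C": D["capacitance"],
            "k": D["conductance_per_voltage"],
            "vr": D["voltage"],
            "vt": D["voltage"],
            "vpeak": D["voltage"],
            "c": D["voltage"],
            "a": D["per_time"],
            "b": D["conductance"],
            "d": D["current"],
        },
        state_variables={"v": D["voltage"], "u": D["current"]},
        time_derivatives={
            "v": e("(k * (v - vr) * (v - vt) - u + iSyn) / C"),
            "u": e("a * (b * (v - vr) - u)"),
        },
        on_start=(("v", e("vr")), ("u", e("0 * b * vr"))),
        on_conditions=(
            OnCondition.parse("v >= vpeak", {"v": "c", "u": "u + d"}, event_out="spike"),
        ),
        event_ports={"spike": "out"},
        exposures={"v": "v", "u": "u"},
        requirements={"iSyn": D["current"]},
    )


def _hh_rate_gate() -> ComponentType:
    # Two-rate gating particle with exponential voltage-dependent rates:
    # alpha(v) = aRate exp((v-aMid)/aScale), beta(v) = bRate exp(-(v-bMid)/bScale)
    # so the steady state at clamped v is q_inf = alpha/(alpha+beta).
    return ComponentType(
        name="hhRateGate",
        parameters={
            "aRate": D["per_time"],
            "aMid": D["voltage"],
            "aScale": D["voltage"],
            "bRate": D["per_time"],
            "bMid": D["voltage"],
            "bScale": D["voltage"],
        },
        state_variables={"q": D["none"]},
        derived_variables={
            "alpha": e("aRate * exp((v - aMid) / aScale)"),
            "beta": e("bRate * exp(-(v - bMid) / bScale)"),
        },
        time_derivatives={"q": e("alpha * (1 - q) - beta * q")},
        on_start=(("q", e("0")),),
        exposures={"q": "q", "rateForward": "alpha", "rateReverse": "beta"},
        requirements={"v": D["voltage"]},
    )


def _hh_channel() -> ComponentType:
    # Single-gate ohmic channel: i = gMax * q^p * (erev - v); the gate
    # occupancy q is supplied by a linked hhRateGate.
    return ComponentType(
        name="hhChannel",
        parameters={"gMax": D["conductance"], "erev": D["voltage"]},
        derived_variables={"i": e("gMax * q * (erev - v)")},
        exposures={"i": "i"},
        requirements={"v": D["voltage"], "q": D["none"]},
    )


def _pulse_generator() -> ComponentType:
    return ComponentType(
        name="pulseGenerator",
        parameters={
            "delay": D["time"],
            "duration": D["time"],
            "amplitude": D["current"],
        },
        state_variables={"i": D["current"]},
        on_start=(("i", e("0 * amplitude")),),
        on_conditions=(
            OnCondition.parse("t >= delay", {"i": "amplitude"}),
            OnCondition.parse("t >= delay + duration", {"i": "0 * amplitude"}),
        ),
        exposures={"i": "i"},
    )


def _constant_current() -> ComponentType:
    return ComponentType(
        name="constantCurrent",
        parameters={"amplitude": D["current"]},
        derived_variables={"i": e("amplitude")},
        exposures={"i": "i"},
    )


def _exp_one_synapse() -> ComponentType:
    return ComponentType(
        name="expOneSynapse",
        parameters={
            "gbase": D["conductance"],
            "erev": D["voltage"],
            "tauDecay": D["time"],
        },
        state_variables={"g": D["conductance"]},
        derived_variables={"i": e("g * (erev - v)")},
        time_derivatives={"g": e("-g / tauDecay")},
        on_start=(("g", e("0 * gbase")),),
        on_events=(OnEvent.parse("in", {"g": "g + gbase"}),),
        event_ports={"in": "in"},
        exposures={"i": "i", "g": "g"},
        requirements={"v": D["voltage"]},
    )


def _gap_junction() -> ComponentType:
    return ComponentType(
        name="gapJunction",
        parameters={"conductance": D["conductance"]},
        derived_variables={"i": e("conductance * (vpeer - v)")},
        exposures={"i": "i"},
        requirements={"v": D["voltage"], "vpeer": D["voltage"]},
    )


@lru_cache(maxsize=1)
def load_core_library() -> dict[str, ComponentType]:
    """The shipped ComponentType library, keyed by type name."""
    types = [
        _iaf_cell(),
        _izhikevich_cell(),
        _hh_rate_gate(),
        _hh_channel(),
        _pulse_generator(),
        _constant_current(),
        _exp_one_synapse(),
        _gap_junction(),
    ]
    library = {}
    for ct in types:
        problems = ct.validate()
        if problems:  # pragma: no cover - library is static
            raise AssertionError(f"core library type invalid: {problems}")
        library[ct.name] = ct
    return library


def core_type(name: str) -> ComponentType:
    lib = load_core_library()
    try:
        return lib[name]
    except KeyError:
        raise KeyError(f"no core type {name!r}; available: {sorted(lib)}") from None
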