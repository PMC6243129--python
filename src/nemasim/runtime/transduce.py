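"""Stimulus transduction: behavioral events to neuron-level current input.

Real sensory transduction in the worm involves mechanically- and chemically-
gated channels far beyond this package's scope; this module is the pluggable
seam where experiment-timeline events become current injections.  The
default map converts mechanosensory stimuli into constant current pulses
into the six classical touch receptor neurons (ALML/R, AVM, PLML/R, PVM) —
anterior touch onto the anterior receptors, posterior touch onto the
posterior ones — with a linear, *placeholder* gain.  All other modalities
default to labelled no-ops until configured by the user.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from ..experiment.types import (
    DirectTouch,
    EventCategory,
    ExperimentDefinition,
    Modality,
    PlateTap,
    TimelineEvent,
)
from ..experiment.validate import validate_experiment
from .waveform import Waveform

__all__ = [
    "TransductionRule",
    "TransductionMap",
    "TransductionError",
    "default_transduction_map",
    "transduce",
    "ANTERIOR_TOUCH_NEURONS",
    "POSTERIOR_TOUCH_NEURONS",
]

ANTERIOR_TOUCH_NEURONS = ("ALML", "ALMR", "AVM")
POSTERIOR_TOUCH_NEURONS = ("PLML", "PLMR", "PVM")


class TransductionError(ValueError):
    pass


@dataclass(frozen=True)
class TransductionRule:
    """Map one (modality, stimulus variant) to target neurons and a gain.

    ``gain`` scales the stimulus magnitude linearly into nA.  ``targets``
    may be a callable ``stimulus -> tuple of neuron names`` for
    stimulus-dependent routing (e.g. touch location).
    """

    modality: Modality
    stimulus_type: type
    targets: tuple[str, ...] | object  # tuple or callable(stimulus) -> tuple
    gain: float  # nA per magnitude unit
    magnitude: object = None  # callable(stimulus) -> float; default: .force/.intensity

    def target_neurons(self, stimulus) -> tuple[str, ...]:
        if callable(self.targets):
            return tuple(self.targets(stimulus))
        return tuple(self.targets)

    def stimulus_magnitude(self, stimulus) -> float:
        if callable(self.magnitude):
            return float(self.magnitude(stimulus))
        for attr in ("force", "intensity", "amplitude", "concentration"):
            if hasattr(stimulus, attr):
                return float(getattr(stimulus, attr))
        raise TransductionError(f"no magnitude attribute on {type(stimulus).__name__}")


@dataclass(frozen=True)
class TransductionMap:
    rules: tuple[TransductionRule, ...] = ()
    known_neurons: tuple[str, ...] | None = None  # validate targets if given

    def rule_for(self, event: TimelineEvent) -> TransductionRule | None:
        for rule in self.rules:
            if rule.modality is event.modality and isinstance(event.stimulus, rule.stimulus_type):
                return rule
        return None


def _touch_targets(stimulus: DirectTouch) -> tuple[str, ...]:
    # receptive fields split roughly at mid-body
    return ANTERIOR_TOUCH_NEURONS if stimulus.body_position < 0.5 else POSTERIOR_TOUCH_NEURONS


#: Placeholder gain: nA of receptor current per μN of applied force.
DEFAULT_TOUCH_GAIN_NA_PER_UN = 0.1
#: Placeholder gain: nA per arbitrary tap-intensity unit (taps hit all six).
DEFAULT_TAP_GAIN_NA = 0.5


def default_transduction_map(known_neurons=None) -> TransductionMap:
    return TransductionMap(
        rules=(
            TransductionRule(Modality.MECHANOTAXIS, DirectTouch,
                             _touch_targets, DEFAULT_TOUCH_GAIN_NA_PER_UN),
            TransductionRule(Modality.MECHANOTAXIS, PlateTap,
                             ANTERIOR_TOUCH_NEURONS + POSTERIOR_TOUCH_NEURONS,
                             DEFAULT_TAP_GAIN_NA),
        ),
        known_neurons=tuple(known_neurons) if known_neurons is not None else None,
    )


def _event_window(event: TimelineEvent, duration: float) -> tuple[float, float] | None:
    """Active time span [t0, t1) of an event, clipped to the experiment."""
    if event.category is EventCategory.EXPERIMENT_WIDE:
        return (0.0, duration)
    if event.category is EventCategory.INTERVAL:
        return (event.event_start_time, event.event_stop_time)
    # instant events: a touch lasts its contact duration; other instant
    # stimuli act for a single-point window and inject nothing
    if isinstance(event.stimulus, DirectTouch) and event.stimulus.contact_duration > 0:
        t1 = min(event.event_time + event.stimulus.contact_duration, duration)
        if t1 > event.event_time:
            return (event.event_time, t1)
        return None
    return None


def transduce(
    experiment: ExperimentDefinition,
    transduction_map: TransductionMap | None = None,
) -> list[tuple[str, Waveform]]:
    """One constant-current pulse per (matched event, target neuron).

    Pulse support equals the event's active time span; amplitude is
    ``gain * stimulus magnitude``.  Unmatched events (no rule — the labelled
    no-ops) contribute nothing.
    """
    problems = validate_experiment(experiment)
    if problems:
        raise TransductionError(
            "invalid experiment: " + "; ".join(str(p) for p in problems)
        )
    tmap = transduction_map if transduction_map is not None else default_transduction_map()
    injections: list[tuple[str, Waveform]] = []
    for event in experiment.sorted_events():
        rule = tmap.rule_for(event)
        if rule is None:
            continue
        window = _event_window(event, experiment.experiment_duration)
        if window is None:
            continue
        amplitude = rule.gain * rule.stimulus_magnitude(event.stimulus)
        for neuron in rule.target_neurons(event.stimulus):
            if tmap.known_neurons is not None and neuron not in tmap.known_neurons:
                raise TransductionError(f"transduction rule targets unknown neuron {neuron!r}")
            injections.append((neuron, Waveform.pulse(window[0], window[1], amplitude)))
    return injections
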