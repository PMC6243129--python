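"""Timeline algebra: which stimuli act on the worm at a given instant.

Experiment-wide stimuli are active throughout; interval stimuli are active on
the half-open window [t0, t1) so abutting intervals never overlap; instant
stimuli are active when the query time is within a configurable tolerance
(default 0 ms: strict equality).
"""

from __future__ import annotations

from .types import EventCategory, ExperimentDefinition, TimelineEvent

__all__ = ["active_stimuli", "event_active_at"]


def event_active_at(event: TimelineEvent, t: float, tolerance: float = 0.0) -> bool:
    """Whether a single event is active at time ``t`` (ms)."""
    if event.category is EventCategory.EXPERIMENT_WIDE:
        return True
    if event.category is EventCategory.INTERVAL:
        return event.event_start_time <= t < event.event_stop_time
    return abs(t - event.event_time) <= tolerance


def active_stimuli(
    definition: ExperimentDefinition, t: float, tolerance: float = 0.0
) -> set[TimelineEvent]:
    """All events active at time ``t`` within the experiment.

    Raises ``ValueError`` if ``t`` is outside [0, experiment_duration].
    """
    if not 0.0 <= t <= definition.experiment_duration:
        raise ValueError(
            f"query time {t} outside experiment duration [0, {definition.experiment_duration}]"
        )
    return {e for e in definition.events if event_active_at(e, t, tolerance)}
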