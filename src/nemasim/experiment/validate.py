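"""Invariant checking for experiment definitions.

Violations are data, not exceptions: :func:`validate_experiment` is total and
returns an empty list exactly when every type invariant holds and every event
time lies within the experiment duration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .types import (
    ChemicalDrop,
    DirectTouch,
    ElectricShock,
    EventCategory,
    ExperimentDefinition,
    Light,
    MODALITY_OF_STIMULUS,
    Obstacle,
    OsmoticRing,
    PlateCoordinate,
    PlateTap,
    TemperatureChange,
    TimelineEvent,
)

__all__ = ["Violation", "validate_experiment"]


@dataclass(frozen=True)
class Violation:
    path: str  # e.g. "events[3]" or "environment.plate"
    message: str

    def __str__(self) -> str:
        return f"{self.path}: {self.message}"


def _check_nonneg(out, path, **named):
    for name, value in named.items():
        if value < 0:
            out.append(Violation(path, f"{name} must be >= 0, got {value}"))


def _check_stimulus(out: list[Violation], path: str, event: TimelineEvent) -> None:
    s = event.stimulus
    expected = MODALITY_OF_STIMULUS.get(type(s))
    if expected is None:
        out.append(Violation(path, f"unknown stimulus type {type(s).__name__}"))
        return
    if expected is not event.modality:
        out.append(
            Violation(
                path,
                f"stimulus {type(s).__name__} belongs to {expected.value}, "
                f"not {event.modality.value}",
            )
        )
    if isinstance(s, DirectTouch):
        _check_nonneg(out, path, force=s.force, contact_duration=s.contact_duration)
        if not 0.0 <= s.body_position <= 1.0:
            out.append(Violation(path, f"body_position must be in [0, 1], got {s.body_position}"))
    elif isinstance(s, PlateTap):
        _check_nonneg(out, path, intensity=s.intensity)
    elif isinstance(s, ChemicalDrop):
        _check_nonneg(out, path, concentration=s.concentration)
    elif isinstance(s, OsmoticRing):
        _check_nonneg(
            out, path, concentration=s.concentration,
            inner_radius=s.inner_radius, outer_radius=s.outer_radius,
        )
        if not s.inner_radius < s.outer_radius:
            out.append(
                Violation(path, f"ring inner_radius {s.inner_radius} must be < outer_radius {s.outer_radius}")
            )
    elif isinstance(s, TemperatureChange):
        if s.profile not in ("linear", "step"):
            out.append(Violation(path, f"profile must be linear or step, got {s.profile!r}"))
    elif isinstance(s, ElectricShock):
        _check_nonneg(out, path, amplitude=s.amplitude, duration=s.duration, frequency=s.frequency)
    elif isinstance(s, Light):
        _check_nonneg(out, path, intensity=s.intensity, wavelength=s.wavelength)


def _check_event(out: list[Violation], path: str, event: TimelineEvent, duration: float) -> None:
    cat = event.category
    if cat is EventCategory.INSTANT:
        if event.event_time is None:
            out.append(Violation(path, "instant event requires event_time"))
        elif not 0.0 <= event.event_time <= duration:
            out.append(
                Violation(path, f"event_time {event.event_time} outside [0, {duration}]")
            )
        if event.event_start_time is not None or event.event_stop_time is not None:
            out.append(Violation(path, "instant event must not carry interval times"))
    elif cat is EventCategory.INTERVAL:
        t0, t1 = event.event_start_time, event.event_stop_time
        if t0 is None or t1 is None:
            out.append(Violation(path, "interval event requires event_start_time and event_stop_time"))
        else:
            if not t0 < t1:
                out.append(Violation(path, "interval start must precede stop"))
            if not 0.0 <= t0 <= duration:
                out.append(Violation(path, f"event_start_time {t0} outside [0, {duration}]"))
            if not 0.0 <= t1 <= duration:
                out.append(Violation(path, f"event_stop_time {t1} outside [0, {duration}]"))
        if event.event_time is not None:
            out.append(Violation(path, "interval event must not carry event_time"))
    elif cat is EventCategory.EXPERIMENT_WIDE:
        if any(t is not None for t in (event.event_time, event.event_start_time, event.event_stop_time)):
            out.append(Violation(path, "experiment-wide event carries no times"))
    else:
        out.append(Violation(path, f"unknown event category {cat!r}"))
    _check_stimulus(out, path, event)


def _inside_plate(coord: PlateCoordinate, radius: float) -> bool:
    return math.hypot(coord.x, coord.y) <= radius + 1e-9


def _check_environment(out: list[Violation], env) -> None:
    _check_nonneg(out, "environment.worm", age=env.worm.age,
                  hours_without_food=env.worm.hours_without_food)
    if env.worm.sex not in ("hermaphrodite", "male"):
        out.append(Violation("environment.worm", f"unknown sex {env.worm.sex!r}"))
    if env.worm.stage not in ("L1", "L2", "L3", "L4", "adult"):
        out.append(Violation("environment.worm", f"unknown stage {env.worm.stage!r}"))
    plate = env.plate
    if plate.radius <= 0:
        out.append(Violation("environment.plate", f"radius must be > 0, got {plate.radius}"))
    if plate.border_height < 0:
        out.append(Violation("environment.plate", f"border_height must be >= 0, got {plate.border_height}"))
    if plate.shape != "cylindrical":
        out.append(Violation("environment.plate", f"unsupported plate shape {plate.shape!r}"))
    if plate.radius > 0 and not _inside_plate(env.worm_location, plate.radius):
        out.append(
            Violation("environment.worm_location",
                      f"worm at ({env.worm_location.x}, {env.worm_location.y}) "
                      f"lies outside plate radius {plate.radius}")
        )
    for i, ob in enumerate(env.obstacles):
        path = f"environment.obstacles[{i}]"
        if ob.stiffness <= 0:
            out.append(Violation(path, f"stiffness must be > 0, got {ob.stiffness}"))
        if ob.height <= 0 or ob.radius <= 0:
            out.append(Violation(path, "obstacle dimensions must be > 0"))
        if ob.shape != "cylinder":
            out.append(Violation(path, f"unsupported obstacle shape {ob.shape!r}"))
        if plate.radius > 0 and not _inside_plate(ob.placement, plate.radius):
            out.append(Violation(path, "obstacle placement lies outside the plate footprint"))
    if env.crowding.worm_count < 1:
        out.append(Violation("environment.crowding",
                             f"worm_count must be >= 1, got {env.crowding.worm_count}"))
    if env.crowding.distribution_index < 0:
        out.append(Violation("environment.crowding",
                             f"distribution_index must be >= 0, got {env.crowding.distribution_index}"))


def validate_experiment(definition: ExperimentDefinition) -> list[Violation]:
    """Check every invariant; returns an empty list iff the definition is valid."""
    out: list[Violation] = []
    duration = definition.experiment_duration
    if not duration > 0:
        out.append(Violation("experiment_duration", f"must be > 0, got {duration}"))
    for i, event in enumerate(definition.events):
        _check_event(out, f"events[{i}]", event, duration if duration > 0 else float("inf"))
    _check_environment(out, definition.environment)
    return out
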