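"""Domain types for duration-based behavioral experiment definitions.

A behavioral assay is a timeline of stimulus events plus a description of the
worm's environment.  Events fall into exactly one of three duration-based
categories — at a specific time, over an interval [t0, t1), or experiment-wide
— and one of five sensory (taxis) modalities: mechanotaxis, chemotaxis,
thermotaxis, galvanotaxis and phototaxis.  Non-sensory behaviors (feeding,
egg-laying, mating, defecation) are deliberately outside this format.

Units: all times in milliseconds, geometry in millimetres, angles in degrees,
touch force in micronewtons, currents in nanoamperes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Optional, Union

__all__ = [
    "EventCategory",
    "Modality",
    "DirectTouch",
    "PlateTap",
    "ChemicalDrop",
    "OsmoticRing",
    "TemperatureChange",
    "ElectricShock",
    "Light",
    "StimulusSpec",
    "PlateCoordinate",
    "TimelineEvent",
    "WormData",
    "PlateConfig",
    "Obstacle",
    "Crowding",
    "EnvironmentConfig",
    "ExperimentDefinition",
    "MODALITY_OF_STIMULUS",
]


class EventCategory(str, Enum):
    INSTANT = "instant"
    INTERVAL = "interval"
    EXPERIMENT_WIDE = "experiment_wide"


class Modality(str, Enum):
    MECHANOTAXIS = "mechanotaxis"
    CHEMOTAXIS = "chemotaxis"
    THERMOTAXIS = "thermotaxis"
    GALVANOTAXIS = "galvanotaxis"
    PHOTOTAXIS = "phototaxis"


@dataclass(frozen=True)
class PlateCoordinate:
    """Position in the plate-centered frame, millimetres."""

    x: float
    y: float


@dataclass(frozen=True)
class DirectTouch:
    body_position: float  # fraction 0-1 along the body, head = 0
    circumferential_angle: float  # degrees
    force: float  # μN
    contact_duration: float  # ms


@dataclass(frozen=True)
class PlateTap:
    intensity: float  # arbitrary units


@dataclass(frozen=True)
class ChemicalDrop:
    substance_id: str
    concentration: float  # mM
    location: PlateCoordinate


@dataclass(frozen=True)
class OsmoticRing:
    substance_id: str
    concentration: float  # mM
    center: PlateCoordinate
    inner_radius: float  # mm
    outer_radius: float  # mm


@dataclass(frozen=True)
class TemperatureChange:
    start_temp: float  # °C
    end_temp: float  # °C
    profile: str = "linear"  # linear | step


@dataclass(frozen=True)
class ElectricShock:
    amplitude: float  # nA
    duration: float  # ms
    frequency: float  # Hz


@dataclass(frozen=True)
class Light:
    intensity: float  # arbitrary units
    wavelength: float  # nm
    location: PlateCoordinate


StimulusSpec = Union[
    DirectTouch, PlateTap, ChemicalDrop, OsmoticRing, TemperatureChange, ElectricShock, Light
]

#: Each stimulus variant belongs to exactly one taxis modality.
MODALITY_OF_STIMULUS: dict[type, Modality] = {
    DirectTouch: Modality.MECHANOTAXIS,
    PlateTap: Modality.MECHANOTAXIS,
    ChemicalDrop: Modality.CHEMOTAXIS,
    OsmoticRing: Modality.CHEMOTAXIS,
    TemperatureChange: Modality.THERMOTAXIS,
    ElectricShock: Modality.GALVANOTAXIS,
    Light: Modality.PHOTOTAXIS,
}


@dataclass(frozen=True)
class TimelineEvent:
    """One stimulus occurrence on the experiment timeline.

    Exactly one of the time fields is populated, matching the category:
    ``event_time`` for instant events, ``(event_start_time, event_stop_time)``
    for interval events, and neither for experiment-wide events.
    """

    category: EventCategory
    modality: Modality
    stimulus: StimulusSpec
    event_time: Optional[float] = None  # ms, instant only
    event_start_time: Optional[float] = None  # ms, interval only
    event_stop_time: Optional[float] = None  # ms, interval only

    def sort_time(self) -> float:
        if self.category is EventCategory.INSTANT:
            return self.event_time if self.event_time is not None else 0.0
        if self.category is EventCategory.INTERVAL:
            return self.event_start_time if self.event_start_time is not None else 0.0
        return 0.0  # experiment-wide events start at t=0


@dataclass(frozen=True)
class WormData:
    mutation_id: str = "N2"
    age: float = 1.0  # days
    sex: str = "hermaphrodite"  # hermaphrodite | male
    stage: str = "L1"  # L1..L4 | adult
    hours_without_food: float = 0.0
    body_length: float = 1.0  # mm; adult is ~1 mm long
    body_diameter: float = 80.0  # μm


@dataclass(frozen=True)
class PlateConfig:
    shape: str = "cylindrical"
    border_height: float = 15.0  # mm
    radius: float = 50.0  # mm
    substrate_code: str = "A"  # agar
    dryness: float = 1.0  # mg over dry weight
    lid: bool = False


@dataclass(frozen=True)
class Obstacle:
    shape: str  # cylinder
    height: float  # mm
    radius: float  # mm
    stiffness: float  # N/m
    distance_x: float  # mm, distance to the central X axis
    distance_y: float  # mm, distance to the central Y axis
    angle: float  # deg

    @property
    def placement(self) -> PlateCoordinate:
        # the (distance to X axis, distance to Y axis) pair stored in the
        # document maps to a plate-centered coordinate as (x, y) = (dy, dx)
        return PlateCoordinate(self.distance_y, self.distance_x)


@dataclass(frozen=True)
class Crowding:
    worm_count: int = 1
    distribution_index: int = 0  # key into predefined placement formulae; opaque


@dataclass(frozen=True)
class EnvironmentConfig:
    worm: WormData = field(default_factory=WormData)
    worm_location: PlateCoordinate = field(default_factory=lambda: PlateCoordinate(0.0, 0.0))
    worm_orientation: float = 0.0  # deg
    plate: PlateConfig = field(default_factory=PlateConfig)
    obstacles: tuple[Obstacle, ...] = ()
    crowding: Crowding = field(default_factory=Crowding)


@dataclass(frozen=True)
class ExperimentDefinition:
    """A complete behavioral experiment: duration, event timeline, environment."""

    experiment_duration: float  # ms
    events: tuple[TimelineEvent, ...] = ()
    environment: EnvironmentConfig = field(default_factory=EnvironmentConfig)

    def with_events(self, events) -> "ExperimentDefinition":
        return replace(self, events=tuple(events))

    def sorted_events(self) -> tuple[TimelineEvent, ...]:
        """Events totally ordered by (start time, insertion order)."""
        return tuple(
            e for _, _, e in sorted(
                (ev.sort_time(), i, ev) for i, ev in enumerate(self.events)
            )
        )
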