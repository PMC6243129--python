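"""Seeded generator of valid experiment definitions (test/demo fixtures)."""

from __future__ import annotations

import math
import random

from .types import (
    ChemicalDrop,
    Crowding,
    DirectTouch,
    ElectricShock,
    EnvironmentConfig,
    EventCategory,
    ExperimentDefinition,
    Light,
    Modality,
    Obstacle,
    OsmoticRing,
    PlateConfig,
    PlateCoordinate,
    PlateTap,
    TemperatureChange,
    TimelineEvent,
    WormData,
)

__all__ = ["generate_fixture_experiment"]

# every (category, modality-variant) combination, cycled so coverage grows
# with n_events
_VARIANTS = [
    ("direct_touch", Modality.MECHANOTAXIS),
    ("electric_shock", Modality.GALVANOTAXIS),
    ("chemical_drop", Modality.CHEMOTAXIS),
    ("temperature", Modality.THERMOTAXIS),
    ("light", Modality.PHOTOTAXIS),
    ("plate_tap", Modality.MECHANOTAXIS),
    ("osmotic_ring", Modality.CHEMOTAXIS),
]
_CATEGORIES = [EventCategory.INSTANT, EventCategory.INTERVAL, EventCategory.EXPERIMENT_WIDE]


def _coordinate(rng: random.Random, plate_radius: float) -> PlateCoordinate:
    r = plate_radius * math.sqrt(rng.random()) * 0.9
    theta = rng.uniform(0.0, 2.0 * math.pi)
    return PlateCoordinate(round(r * math.cos(theta), 3), round(r * math.sin(theta), 3))


def _stimulus(kind: str, rng: random.Random, plate_radius: float):
    if kind == "direct_touch":
        return DirectTouch(
            body_position=round(rng.random(), 3),
            circumferential_angle=round(rng.uniform(0, 360), 1),
            force=round(rng.uniform(0.5, 20.0), 3),
            contact_duration=round(rng.uniform(10, 500), 1),
        )
    if kind == "plate_tap":
        return PlateTap(intensity=round(rng.uniform(0.1, 10.0), 3))
    if kind == "chemical_drop":
        return ChemicalDrop(
            substance_id=rng.choice(["NaCl", "quinine", "biotin", "CuSO4"]),
            concentration=round(rng.uniform(0.1, 100.0), 3),
            location=_coordinate(rng, plate_radius),
        )
    if kind == "osmotic_ring":
        inner = round(rng.uniform(1.0, plate_radius / 2), 3)
        return OsmoticRing(
            substance_id=rng.choice(["fructose", "glycerol"]),
            concentration=round(rng.uniform(100.0, 4000.0), 1),
            center=PlateCoordinate(0.0, 0.0),
            inner_radius=inner,
            outer_radius=round(inner + rng.uniform(0.5, 5.0), 3),
        )
    if kind == "temperature":
        start = round(rng.uniform(15.0, 25.0), 2)
        return TemperatureChange(
            start_temp=start,
            end_temp=round(start + rng.uniform(-5.0, 5.0), 2),
            profile=rng.choice(["linear", "step"]),
        )
    if kind == "electric_shock":
        return ElectricShock(
            amplitude=round(rng.uniform(0.1, 10.0), 3),
            duration=round(rng.uniform(1.0, 100.0), 1),
            frequency=round(rng.uniform(0.5, 50.0), 2),
        )
    if kind == "light":
        return Light(
            intensity=round(rng.uniform(0.1, 5.0), 3),
            wavelength=round(rng.uniform(350.0, 650.0), 1),
            location=_coordinate(rng, plate_radius),
        )
    raise AssertionError(kind)


def generate_fixture_experiment(
    seed: int, n_events: int, duration: float = 10000.0
) -> ExperimentDefinition:
    """Deterministically generate a valid experiment with ``n_events`` events.

    Category and modality coverage grows with ``n_events``: the generator
    cycles through every (category, stimulus-variant) combination before
    repeating.
    """
    if n_events < 0:
        raise ValueError("n_events must be >= 0")
    rng = random.Random(seed)
    plate = PlateConfig()
    events = []
    for i in range(n_events):
        category = _CATEGORIES[i % len(_CATEGORIES)]
        kind, modality = _VARIANTS[(i // len(_CATEGORIES)) % len(_VARIANTS)]
        stimulus = _stimulus(kind, rng, plate.radius)
        if category is EventCategory.INSTANT:
            ev = TimelineEvent(category, modality, stimulus,
                               event_time=round(rng.uniform(0.0, duration), 1))
        elif category is EventCategory.INTERVAL:
            t0 = round(rng.uniform(0.0, duration - 1.0), 1)
            t1 = round(rng.uniform(t0 + 0.5, duration), 1)
            ev = TimelineEvent(category, modality, stimulus,
                               event_start_time=t0, event_stop_time=t1)
        else:
            ev = TimelineEvent(category, modality, stimulus)
        events.append(ev)
    n_obstacles = rng.randint(0, 2)
    obstacles = tuple(
        Obstacle(
            shape="cylinder",
            height=round(rng.uniform(1.0, 10.0), 2),
            radius=round(rng.uniform(1.0, 8.0), 2),
            stiffness=round(rng.uniform(5.0, 100.0), 2),
            distance_x=round(rng.uniform(-20.0, 20.0), 2),
            distance_y=round(rng.uniform(-20.0, 20.0), 2),
            angle=round(rng.uniform(0.0, 360.0), 1),
        )
        for _ in range(n_obstacles)
    )
    environment = EnvironmentConfig(
        worm=WormData(
            mutation_id=rng.choice(["N2", "mec-4", "tax-4", "osm-9"]),
            age=rng.choice([1.0, 2.0, 3.0]),
            sex="hermaphrodite",
            stage=rng.choice(["L1", "L4", "adult"]),
            hours_without_food=float(rng.randint(0, 12)),
        ),
        worm_location=_coordinate(rng, plate.radius),
        worm_orientation=round(rng.uniform(0.0, 360.0), 1),
        plate=plate,
        obstacles=obstacles,
        crowding=Crowding(worm_count=rng.randint(1, 5), distribution_index=rng.randint(0, 3)),
    )
    return ExperimentDefinition(
        experiment_duration=duration, events=tuple(events), environment=environment
    )
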