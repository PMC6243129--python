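"""Reader/writer for the behavioral-experiment XML dialect.

The writer is canonical: events are emitted sorted by (start time, insertion
order), numbers are printed with ``%.12g``, and two writes of the same
definition are byte-identical.  The reader is strict — any element outside
the dialect raises :class:`UnknownElementError` — and inverts the writer.
"""

from __future__ import annotations

import importlib.resources
from typing import Iterator

from lxml import etree

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
    StimulusSpec,
    TemperatureChange,
    TimelineEvent,
    WormData,
)

__all__ = [
    "ExperimentXMLError",
    "UnknownElementError",
    "read_experiment",
    "write_experiment",
    "schema_path",
    "validate_against_schema",
]


class ExperimentXMLError(ValueError):
    """Malformed or out-of-dialect experiment document."""


class UnknownElementError(ExperimentXMLError):
    """An element outside the frozen dialect was encountered."""


_CATEGORY_TAGS = {
    "interactionAtSpecificTime": EventCategory.INSTANT,
    "interactionFromt0tot1": EventCategory.INTERVAL,
    "experimentWideConf": EventCategory.EXPERIMENT_WIDE,
}

_MODALITY_TAGS = {m.value: m for m in Modality}

_STIMULUS_TAGS = {
    "directTouchConf": DirectTouch,
    "plateTapConf": PlateTap,
    "chemicalDropConf": ChemicalDrop,
    "osmoticRingConf": OsmoticRing,
    "temperatureChangeConf": TemperatureChange,
    "electricShockConf": ElectricShock,
    "lightConf": Light,
}
_TAG_OF_STIMULUS = {v: k for k, v in _STIMULUS_TAGS.items()}


def _fmt(value: float) -> str:
    return format(float(value), ".12g")


# ------------------------------------------------------------------ writing


def _sub(parent, tag: str, text: str | None = None):
    el = etree.SubElement(parent, tag)
    if text is not None:
        el.text = text
    return el


def _write_coordinate(parent, tag: str, coord: PlateCoordinate) -> None:
    el = _sub(parent, tag)
    _sub(el, "x", _fmt(coord.x))
    _sub(el, "y", _fmt(coord.y))


def _write_stimulus(parent, stimulus: StimulusSpec) -> None:
    tag = _TAG_OF_STIMULUS[type(stimulus)]
    el = _sub(parent, tag)
    if isinstance(stimulus, DirectTouch):
        _sub(el, "bodyPosition", _fmt(stimulus.body_position))
        _sub(el, "circumferentialAngle", _fmt(stimulus.circumferential_angle))
        _sub(el, "force", _fmt(stimulus.force))
        _sub(el, "contactDuration", _fmt(stimulus.contact_duration))
    elif isinstance(stimulus, PlateTap):
        _sub(el, "intensity", _fmt(stimulus.intensity))
    elif isinstance(stimulus, ChemicalDrop):
        _sub(el, "substanceId", stimulus.substance_id)
        _sub(el, "concentration", _fmt(stimulus.concentration))
        _write_coordinate(el, "location", stimulus.location)
    elif isinstance(stimulus, OsmoticRing):
        _sub(el, "substanceId", stimulus.substance_id)
        _sub(el, "concentration", _fmt(stimulus.concentration))
        _write_coordinate(el, "center", stimulus.center)
        _sub(el, "innerRadius", _fmt(stimulus.inner_radius))
        _sub(el, "outerRadius", _fmt(stimulus.outer_radius))
    elif isinstance(stimulus, TemperatureChange):
        _sub(el, "startTemp", _fmt(stimulus.start_temp))
        _sub(el, "endTemp", _fmt(stimulus.end_temp))
        _sub(el, "profile", stimulus.profile)
    elif isinstance(stimulus, ElectricShock):
        _sub(el, "amplitude", _fmt(stimulus.amplitude))
        _sub(el, "duration", _fmt(stimulus.duration))
        _sub(el, "frequency", _fmt(stimulus.frequency))
    elif isinstance(stimulus, Light):
        _sub(el, "intensity", _fmt(stimulus.intensity))
        _sub(el, "wavelength", _fmt(stimulus.wavelength))
        _write_coordinate(el, "location", stimulus.location)
    else:  # pragma: no cover - closed set
        raise ExperimentXMLError(f"unknown stimulus type {type(stimulus).__name__}")


def _write_event(parent, event: TimelineEvent) -> None:
    tag = {v: k for k, v in _CATEGORY_TAGS.items()}[event.category]
    el = _sub(parent, tag)
    if event.category is EventCategory.INSTANT:
        _sub(el, "eventTime", _fmt(event.event_time))
    elif event.category is EventCategory.INTERVAL:
        _sub(el, "eventStartTime", _fmt(event.event_start_time))
        _sub(el, "eventStopTime", _fmt(event.event_stop_time))
    modality_el = _sub(el, event.modality.value)
    _write_stimulus(modality_el, event.stimulus)


def _write_environment(parent, env: EnvironmentConfig) -> None:
    el = _sub(parent, "environment")
    wd = _sub(el, "wormData")
    _sub(wd, "mutationId", env.worm.mutation_id)
    _sub(wd, "age", _fmt(env.worm.age))
    _sub(wd, "sex", env.worm.sex)
    _sub(wd, "stage", env.worm.stage)
    _sub(wd, "hoursWithoutFood", _fmt(env.worm.hours_without_food))
    _sub(wd, "bodyLength", _fmt(env.worm.body_length))
    _sub(wd, "bodyDiameter", _fmt(env.worm.body_diameter))
    loc = _sub(el, "wormLocation")
    _sub(loc, "x", _fmt(env.worm_location.x))
    _sub(loc, "y", _fmt(env.worm_location.y))
    _sub(loc, "orientation", _fmt(env.worm_orientation))
    plate = _sub(el, "plateConf")
    _sub(plate, "shape", env.plate.shape)
    _sub(plate, "borderHeight", _fmt(env.plate.border_height))
    _sub(plate, "radius", _fmt(env.plate.radius))
    _sub(plate, "substrate", env.plate.substrate_code)
    _sub(plate, "dryness", _fmt(env.plate.dryness))
    _sub(plate, "lid", "true" if env.plate.lid else "false")
    obstacles = _sub(el, "obstacles")
    for ob in env.obstacles:
        oel = _sub(obstacles, "obstacle")
        _sub(oel, "shape", ob.shape)
        _sub(oel, "height", _fmt(ob.height))
        _sub(oel, "radius", _fmt(ob.radius))
        _sub(oel, "stiffness", _fmt(ob.stiffness))
        pl = _sub(oel, "placement")
        _sub(pl, "distanceX", _fmt(ob.distance_x))
        _sub(pl, "distanceY", _fmt(ob.distance_y))
        _sub(pl, "angle", _fmt(ob.angle))
    crowd = _sub(el, "crowding")
    _sub(crowd, "wormCount", str(env.crowding.worm_count))
    _sub(crowd, "distributionIndex", str(env.crowding.distribution_index))


def write_experiment(definition: ExperimentDefinition) -> str:
    """Serialize a validated definition to canonical XML text."""
    from .validate import validate_experiment

    violations = validate_experiment(definition)
    if violations:
        raise ExperimentXMLError(
            "refusing to write invalid definition: " + "; ".join(v.message for v in violations)
        )
    root = etree.Element("behavioralExperiment")
    _sub(root, "experimentDuration", _fmt(definition.experiment_duration))
    interactions = _sub(root, "interactions")
    for event in definition.sorted_events():
        _write_event(interactions, event)
    _write_environment(root, definition.environment)
    return etree.tostring(root, pretty_print=True, encoding="unicode")


# ------------------------------------------------------------------ reading


def _children(el) -> Iterator:
    for child in el:
        if isinstance(child.tag, str):  # skip comments / PIs
            yield child


def _text(el, parent_tag: str) -> str:
    if len(list(_children(el))) != 0:
        raise ExperimentXMLError(f"element {el.tag!r} in {parent_tag!r} must be a leaf")
    return (el.text or "").strip()


def _number(el, parent_tag: str) -> float:
    text = _text(el, parent_tag)
    try:
        return float(text)
    except ValueError:
        raise ExperimentXMLError(
            f"non-numeric value {text!r} for {parent_tag}/{el.tag}"
        ) from None


def _fields(el) -> dict:
    """Map child tags to elements, rejecting duplicates."""
    out: dict = {}
    for child in _children(el):
        if child.tag in out:
            raise ExperimentXMLError(f"duplicate element {child.tag!r} in {el.tag!r}")
        out[child.tag] = child
    return out


def _take(fields: dict, tag: str, parent: str):
    try:
        return fields.pop(tag)
    except KeyError:
        raise ExperimentXMLError(f"missing element {tag!r} in {parent!r}") from None


def _no_extras(fields: dict, parent: str) -> None:
    if fields:
        raise UnknownElementError(
            f"unknown element(s) {sorted(fields)} in {parent!r}"
        )


def _read_coordinate(el) -> PlateCoordinate:
    f = _fields(el)
    coord = PlateCoordinate(
        x=_number(_take(f, "x", el.tag), el.tag),
        y=_number(_take(f, "y", el.tag), el.tag),
    )
    _no_extras(f, el.tag)
    return coord


def _read_stimulus(el) -> StimulusSpec:
    tag = el.tag
    f = _fields(el)
    if tag == "directTouchConf":
        out = DirectTouch(
            body_position=_number(_take(f, "bodyPosition", tag), tag),
            circumferential_angle=_number(_take(f, "circumferentialAngle", tag), tag),
            force=_number(_take(f, "force", tag), tag),
            contact_duration=_number(_take(f, "contactDuration", tag), tag),
        )
    elif tag == "plateTapConf":
        out = PlateTap(intensity=_number(_take(f, "intensity", tag), tag))
    elif tag == "chemicalDropConf":
        out = ChemicalDrop(
            substance_id=_text(_take(f, "substanceId", tag), tag),
            concentration=_number(_take(f, "concentration", tag), tag),
            location=_read_coordinate(_take(f, "location", tag)),
        )
    elif tag == "osmoticRingConf":
        out = OsmoticRing(
            substance_id=_text(_take(f, "substanceId", tag), tag),
            concentration=_number(_take(f, "concentration", tag), tag),
            center=_read_coordinate(_take(f, "center", tag)),
            inner_radius=_number(_take(f, "innerRadius", tag), tag),
            outer_radius=_number(_take(f, "outerRadius", tag), tag),
        )
    elif tag == "temperatureChangeConf":
        out = TemperatureChange(
            start_temp=_number(_take(f, "startTemp", tag), tag),
            end_temp=_number(_take(f, "endTemp", tag), tag),
            profile=_text(_take(f, "profile", tag), tag),
        )
    elif tag == "electricShockConf":
        out = ElectricShock(
            amplitude=_number(_take(f, "amplitude", tag), tag),
            duration=_number(_take(f, "duration", tag), tag),
            frequency=_number(_take(f, "frequency", tag), tag),
        )
    elif tag == "lightConf":
        out = Light(
            intensity=_number(_take(f, "intensity", tag), tag),
            wavelength=_number(_take(f, "wavelength", tag), tag),
            location=_read_coordinate(_take(f, "location", tag)),
        )
    else:
        raise UnknownElementError(f"unknown stimulus element {tag!r}")
    _no_extras(f, tag)
    return out


def _read_modality(el) -> tuple[Modality, StimulusSpec]:
    modality = _MODALITY_TAGS.get(el.tag)
    if modality is None:
        raise UnknownElementError(f"unknown modality element {el.tag!r}")
    kids = list(_children(el))
    if len(kids) != 1:
        raise ExperimentXMLError(f"modality {el.tag!r} must contain exactly one stimulus")
    stimulus = _read_stimulus(kids[0])
    if _STIMULUS_TAGS[kids[0].tag] not in _stimuli_of_modality(modality):
        raise ExperimentXMLError(
            f"stimulus {kids[0].tag!r} is not a {modality.value} stimulus"
        )
    return modality, stimulus


def _stimuli_of_modality(modality: Modality) -> tuple[type, ...]:
    from .types import MODALITY_OF_STIMULUS

    return tuple(t for t, m in MODALITY_OF_STIMULUS.items() if m is modality)


def _read_event(el) -> TimelineEvent:
    category = _CATEGORY_TAGS.get(el.tag)
    if category is None:
        raise UnknownElementError(f"unknown interaction element {el.tag!r}")
    f = _fields(el)
    event_time = start = stop = None
    if category is EventCategory.INSTANT:
        event_time = _number(_take(f, "eventTime", el.tag), el.tag)
    elif category is EventCategory.INTERVAL:
        start = _number(_take(f, "eventStartTime", el.tag), el.tag)
        stop = _number(_take(f, "eventStopTime", el.tag), el.tag)
    if len(f) != 1:
        raise ExperimentXMLError(
            f"{el.tag!r} must contain exactly one modality element, got {sorted(f)}"
        )
    modality, stimulus = _read_modality(f.popitem()[1])
    return TimelineEvent(
        category=category,
        modality=modality,
        stimulus=stimulus,
        event_time=event_time,
        event_start_time=start,
        event_stop_time=stop,
    )


def _read_environment(el) -> EnvironmentConfig:
    f = _fields(el)
    wd = _fields(_take(f, "wormData", "environment"))
    worm = WormData(
        mutation_id=_text(_take(wd, "mutationId", "wormData"), "wormData"),
        age=_number(_take(wd, "age", "wormData"), "wormData"),
        sex=_text(_take(wd, "sex", "wormData"), "wormData"),
        stage=_text(_take(wd, "stage", "wormData"), "wormData"),
        hours_without_food=_number(_take(wd, "hoursWithoutFood", "wormData"), "wormData"),
        body_length=_number(_take(wd, "bodyLength", "wormData"), "wormData"),
        body_diameter=_number(_take(wd, "bodyDiameter", "wormData"), "wormData"),
    )
    _no_extras(wd, "wormData")
    loc = _fields(_take(f, "wormLocation", "environment"))
    worm_location = PlateCoordinate(
        x=_number(_take(loc, "x", "wormLocation"), "wormLocation"),
        y=_number(_take(loc, "y", "wormLocation"), "wormLocation"),
    )
    orientation = _number(_take(loc, "orientation", "wormLocation"), "wormLocation")
    _no_extras(loc, "wormLocation")
    pc = _fields(_take(f, "plateConf", "environment"))
    lid_text = _text(_take(pc, "lid", "plateConf"), "plateConf")
    if lid_text not in ("true", "false"):
        raise ExperimentXMLError(f"lid must be 'true' or 'false', got {lid_text!r}")
    plate = PlateConfig(
        shape=_text(_take(pc, "shape", "plateConf"), "plateConf"),
        border_height=_number(_take(pc, "borderHeight", "plateConf"), "plateConf"),
        radius=_number(_take(pc, "radius", "plateConf"), "plateConf"),
        substrate_code=_text(_take(pc, "substrate", "plateConf"), "plateConf"),
        dryness=_number(_take(pc, "dryness", "plateConf"), "plateConf"),
        lid=lid_text == "true",
    )
    _no_extras(pc, "plateConf")
    obstacles = []
    obs_el = _take(f, "obstacles", "environment")
    for child in _children(obs_el):
        if child.tag != "obstacle":
            raise UnknownElementError(f"unknown element {child.tag!r} in 'obstacles'")
        of = _fields(child)
        placement = _fields(_take(of, "placement", "obstacle"))
        obstacles.append(
            Obstacle(
                shape=_text(_take(of, "shape", "obstacle"), "obstacle"),
                height=_number(_take(of, "height", "obstacle"), "obstacle"),
                radius=_number(_take(of, "radius", "obstacle"), "obstacle"),
                stiffness=_number(_take(of, "stiffness", "obstacle"), "obstacle"),
                distance_x=_number(_take(placement, "distanceX", "placement"), "placement"),
                distance_y=_number(_take(placement, "distanceY", "placement"), "placement"),
                angle=_number(_take(placement, "angle", "placement"), "placement"),
            )
        )
        _no_extras(placement, "placement")
        _no_extras(of, "obstacle")
    cr = _fields(_take(f, "crowding", "environment"))
    crowding = Crowding(
        worm_count=int(_number(_take(cr, "wormCount", "crowding"), "crowding")),
        distribution_index=int(_number(_take(cr, "distributionIndex", "crowding"), "crowding")),
    )
    _no_extras(cr, "crowding")
    _no_extras(f, "environment")
    return EnvironmentConfig(
        worm=worm,
        worm_location=worm_location,
        worm_orientation=orientation,
        plate=plate,
        obstacles=tuple(obstacles),
        crowding=crowding,
    )


def read_experiment(document: str) -> ExperimentDefinition:
    """Parse behavioral-experiment XML text into an :class:`ExperimentDefinition`."""
    try:
        root = etree.fromstring(document.encode() if isinstance(document, str) else document)
    except etree.XMLSyntaxError as exc:
        raise ExperimentXMLError(f"malformed XML: {exc}") from exc
    if root.tag != "behavioralExperiment":
        raise UnknownElementError(f"unexpected root element {root.tag!r}")
    f = _fields(root)
    duration = _number(_take(f, "experimentDuration", root.tag), root.tag)
    events = tuple(_read_event(el) for el in _children(_take(f, "interactions", root.tag)))
    environment = _read_environment(_take(f, "environment", root.tag))
    _no_extras(f, root.tag)
    return ExperimentDefinition(
        experiment_duration=duration, events=events, environment=environment
    )


# ------------------------------------------------------------------ schema


def schema_path() -> str:
    """Filesystem path of the shipped XSD."""
    ref = importlib.resources.files("nemasim.experiment") / "schema" / "behavioral_experiment.xsd"
    return str(ref)


def validate_against_schema(document: str) -> list[str]:
    """Validate raw XML text against the shipped XSD; returns error strings."""
    schema = etree.XMLSchema(etree.parse(schema_path()))
    try:
        tree = etree.fromstring(document.encode() if isinstance(document, str) else document)
    except etree.XMLSyntaxError as exc:
        return [f"malformed XML: {exc}"]
    if schema.validate(tree):
        return []
    return [str(e) for e in schema.error_log]
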