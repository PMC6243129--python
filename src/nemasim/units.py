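"""Dimensional analysis for model parameters.

A :class:`Dimension` is a vector of integer exponents over the seven SI base
quantities (m, kg, s, A, K, mol, cd).  Units are named scale factors on a
dimension: every unit in the table maps to SI by a power of ten, which is all
the neuron-model unit set (ms, mV, nA, nS, uF, ...) requires.
"""

from __future__ import annotations

from dataclasses import dataclass

_BASE = ("m", "kg", "s", "A", "K", "mol", "cd")


@dataclass(frozen=True)
class Dimension:
    """Exponent vector over the SI base quantities."""

    exponents: tuple[int, int, int, int, int, int, int] = (0, 0, 0, 0, 0, 0, 0)

    def __mul__(self, other: "Dimension") -> "Dimension":
        return Dimension(tuple(a + b for a, b in zip(self.exponents, other.exponents)))

    def __truediv__(self, other: "Dimension") -> "Dimension":
        return Dimension(tuple(a - b for a, b in zip(self.exponents, other.exponents)))

    def __pow__(self, n: int) -> "Dimension":
        if not isinstance(n, int):
            raise TypeError("dimension exponents must be integers")
        return Dimension(tuple(a * n for a in self.exponents))

    @property
    def is_dimensionless(self) -> bool:
        return all(e == 0 for e in self.exponents)

    def __str__(self) -> str:
        name = _DIMENSION_NAMES.get(self)
        if name is not None:
            return name
        parts = [f"{b}^{e}" for b, e in zip(_BASE, self.exponents) if e != 0]
        return "*".join(parts) if parts else "none"


def _dim(**kw: int) -> Dimension:
    exps = tuple(kw.get(b, 0) for b in _BASE)
    return Dimension(exps)


DIMENSIONLESS = _dim()
TIME = _dim(s=1)
PER_TIME = _dim(s=-1)
LENGTH = _dim(m=1)
VOLTAGE = _dim(m=2, kg=1, s=-3, A=-1)
CURRENT = _dim(A=1)
CONDUCTANCE = _dim(m=-2, kg=-1, s=3, A=2)
CAPACITANCE = _dim(m=-2, kg=-1, s=4, A=2)
CONDUCTANCE_PER_VOLTAGE = CONDUCTANCE / VOLTAGE
CURRENT_PER_TIME = CURRENT / TIME
TEMPERATURE = _dim(K=1)

#: Named dimensions usable in LEMS-style documents.
DIMENSIONS: dict[str, Dimension] = {
    "none": DIMENSIONLESS,
    "time": TIME,
    "per_time": PER_TIME,
    "length": LENGTH,
    "voltage": VOLTAGE,
    "current": CURRENT,
    "conductance": CONDUCTANCE,
    "capacitance": CAPACITANCE,
    "conductance_per_voltage": CONDUCTANCE_PER_VOLTAGE,
    "current_per_time": CURRENT_PER_TIME,
    "temperature": TEMPERATURE,
}

_DIMENSION_NAMES: dict[Dimension, str] = {v: k for k, v in DIMENSIONS.items()}


@dataclass(frozen=True)
class Unit:
    """A named unit: a dimension scaled by a power of ten to SI."""

    name: str
    dimension: Dimension
    power: int  # value_in_SI = value * 10**power

    def to_si(self, value: float) -> float:
        return value * 10.0 ** self.power

    def from_si(self, value: float) -> float:
        return value * 10.0 ** (-self.power)


#: Fixed unit table; sufficient for the shipped model library.
UNITS: dict[str, Unit] = {
    u.name: u
    for u in [
        Unit("s", TIME, 0),
        Unit("ms", TIME, -3),
        Unit("per_s", PER_TIME, 0),
        Unit("per_ms", PER_TIME, 3),
        Unit("V", VOLTAGE, 0),
        Unit("mV", VOLTAGE, -3),
        Unit("A", CURRENT, 0),
        Unit("nA", CURRENT, -9),
        Unit("pA", CURRENT, -12),
        Unit("S", CONDUCTANCE, 0),
        Unit("uS", CONDUCTANCE, -6),
        Unit("nS", CONDUCTANCE, -9),
        Unit("F", CAPACITANCE, 0),
        Unit("uF", CAPACITANCE, -6),
        Unit("nF", CAPACITANCE, -9),
        Unit("pF", CAPACITANCE, -12),
        Unit("nS_per_mV", CONDUCTANCE_PER_VOLTAGE, -6),
        Unit("pA_per_ms", CURRENT_PER_TIME, -9),
        Unit("degC", TEMPERATURE, 0),  # offset ignored; used as a label only
        Unit("none", DIMENSIONLESS, 0),
    ]
}


class UnknownUnitError(ValueError):
    pass


def get_unit(name: str) -> Unit:
    try:
        return UNITS[name]
    except KeyError:
        raise UnknownUnitError(f"unknown unit {name!r}") from None


def parse_quantity(text: str) -> tuple[float, Unit]:
    """Parse ``"5 mV"`` / ``"-70mV"`` / ``"3"`` into (value, Unit)."""
    s = text.strip()
    idx = len(s)
    for i, ch in enumerate(s):
        if ch.isalpha() and not (ch in "eE" and i > 0 and (s[i - 1].isdigit() or s[i - 1] == ".")):
            idx = i
            break
    value = float(s[:idx])
    unit_name = s[idx:].strip() or "none"
    return value, get_unit(unit_name)
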