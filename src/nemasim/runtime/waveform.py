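"""Injected current waveforms (piecewise-constant or piecewise-linear, nA)."""

from __future__ import annotations

import math
from bisect import bisect_right
from dataclasses import dataclass

__all__ = ["Waveform"]


@dataclass(frozen=True)
class Waveform:
    """Current vs time on [0, duration], milliseconds and nanoamperes.

    ``points`` is a sorted sequence of (t_ms, value_nA) breakpoints.  With
    ``interpolation="constant"`` the waveform holds each value on the
    half-open window up to the next breakpoint; with ``"linear"`` it ramps
    between breakpoints.  Before the first breakpoint the value is 0.
    """

    points: tuple[tuple[float, float], ...]
    interpolation: str = "constant"  # constant | linear

    def __post_init__(self):
        if self.interpolation not in ("constant", "linear"):
            raise ValueError(f"unknown interpolation {self.interpolation!r}")
        ts = [t for t, _ in self.points]
        if ts != sorted(ts):
            raise ValueError("waveform breakpoints must be time-sorted")
        for t, v in self.points:
            if not (math.isfinite(t) and math.isfinite(v)):
                raise ValueError("waveform breakpoints must be finite")

    @classmethod
    def pulse(cls, t0: float, t1: float, amplitude: float) -> "Waveform":
        """Constant ``amplitude`` nA on [t0, t1), zero elsewhere."""
        if not t0 < t1:
            raise ValueError(f"pulse needs t0 < t1, got [{t0}, {t1})")
        return cls(points=((t0, amplitude), (t1, 0.0)), interpolation="constant")

    def value(self, t: float) -> float:
        if not self.points or t < self.points[0][0]:
            return 0.0
        idx = bisect_right([p[0] for p in self.points], t) - 1
        t0, v0 = self.points[idx]
        if self.interpolation == "constant" or idx == len(self.points) - 1:
            return v0
        t1, v1 = self.points[idx + 1]
        if t1 == t0:
            return v1
        return v0 + (v1 - v0) * (t - t0) / (t1 - t0)

    def integral(self, t0: float, t1: float, n: int = 200_000) -> float:
        """Injected charge on [t0, t1) in nA·ms (midpoint quadrature)."""
        if not t0 < t1:
            return 0.0
        h = (t1 - t0) / n
        return h * sum(self.value(t0 + (i + 0.5) * h) for i in range(n))
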