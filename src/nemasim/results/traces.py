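"""Spreadsheet (CSV) export of simulation readback traces.

Layout: an optional ``# {json}`` metadata comment line, a header row with a
time column followed by one ``NEURON.variable`` column per trace, then one
row per grid point.  Values are printed with 12 significant digits, which
makes write→read→write byte-stable and value round-trips exact to printed
precision.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from ..runtime.engine import SimulationResultSet

__all__ = ["NeuralTraceSet", "write_traces_csv", "read_traces_csv"]


@dataclass
class NeuralTraceSet:
    """Simulation traces plus provenance metadata."""

    times: np.ndarray  # ms, uniform grid
    dt: float  # ms
    traces: dict[tuple[str, str], np.ndarray]
    spikes: dict[str, list[float]] = field(default_factory=dict)
    experiment_id: str = ""
    network_config_id: str = ""

    @classmethod
    def from_result(cls, result: SimulationResultSet, experiment_id: str = "",
                    network_config_id: str = "") -> "NeuralTraceSet":
        return cls(times=result.times, dt=result.dt, traces=dict(result.traces),
                   spikes=dict(result.spikes), experiment_id=experiment_id,
                   network_config_id=network_config_id)

    def n_samples(self) -> int:
        return len(self.times)

    def check(self) -> None:
        if len(self.times) == 0:
            raise ValueError("empty time grid")
        for key, arr in self.traces.items():
            if len(arr) != len(self.times):
                raise ValueError(f"trace {key} length {len(arr)} != grid {len(self.times)}")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"trace {key} contains non-finite values")

    def slice(self, t0: float, t1: float) -> "NeuralTraceSet":
        """Restrict to grid points with t0 <= t < t1 (times re-zeroed to t0)."""
        if not 0 <= t0 < t1 <= self.times[-1] + self.dt:
            raise ValueError(f"slice bounds [{t0}, {t1}) outside recording")
        mask = (self.times >= t0 - 1e-9) & (self.times < t1 - 1e-9)
        return replace(
            self,
            times=self.times[mask] - t0,
            traces={k: v[mask] for k, v in self.traces.items()},
            spikes={k: [t - t0 for t in v if t0 <= t < t1] for k, v in self.spikes.items()},
        )


def _fmt(x: float) -> str:
    return format(float(x), ".12g")


def write_traces_csv(traces: NeuralTraceSet, path) -> None:
    """One time column plus one column per (neuron, variable)."""
    traces.check()
    keys = sorted(traces.traces)
    meta = {
        "experiment_id": traces.experiment_id,
        "network_config_id": traces.network_config_id,
        "dt_ms": traces.dt,
        "spikes": {k: [round(t, 9) for t in v] for k, v in sorted(traces.spikes.items())},
    }
    with open(path, "w") as fh:
        fh.write("# " + json.dumps(meta, sort_keys=True) + "\n")
        fh.write(",".join(["time_ms"] + [f"{n}.{v}" for n, v in keys]) + "\n")
        columns = [traces.times] + [traces.traces[k] for k in keys]
        for row in zip(*columns):
            fh.write(",".join(_fmt(x) for x in row) + "\n")


def read_traces_csv(path) -> NeuralTraceSet:
    """Inverse of :func:`write_traces_csv`."""
    text = Path(path).read_text().splitlines()
    meta = {}
    if text and text[0].startswith("# "):
        meta = json.loads(text[0][2:])
        text = text[1:]
    if not text:
        raise ValueError(f"{path}: empty trace file")
    header = text[0].split(",")
    if header[0] != "time_ms":
        raise ValueError(f"{path}: first column must be time_ms")
    keys = []
    for column in header[1:]:
        neuron, _, variable = column.rpartition(".")
        if not neuron:
            raise ValueError(f"{path}: bad column name {column!r}")
        keys.append((neuron, variable))
    rows = [list(map(float, line.split(","))) for line in text[1:] if line]
    data = np.array(rows, dtype=float)
    times = data[:, 0]
    dt = float(meta.get("dt_ms", times[1] - times[0] if len(times) > 1 else 1.0))
    return NeuralTraceSet(
        times=times,
        dt=dt,
        traces={k: data[:, i + 1].copy() for i, k in enumerate(keys)},
        spikes={k: list(map(float, v)) for k, v in meta.get("spikes", {}).items()},
        experiment_id=meta.get("experiment_id", ""),
        network_config_id=meta.get("network_config_id", ""),
    )
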