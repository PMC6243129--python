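"""Result manifest: one JSON file tying traces, locomotion, and the
originating experiment/network documents to a common clock."""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

from .locomotion import LocomotionRecording, read_locomotion_jsonl
from .traces import NeuralTraceSet, read_traces_csv

__all__ = ["ResultManifest", "write_manifest", "load_manifest", "check_clock_reconciliation"]


@dataclass(frozen=True)
class ResultManifest:
    trace_file: str
    locomotion_file: str
    experiment_file: str | None = None
    network_file: str | None = None
    clock_offset_ms: float = 0.0  # added to locomotion timestamps to land on the trace clock

    def resolve(self, base: Path) -> tuple[NeuralTraceSet, LocomotionRecording]:
        """Load and parse both referenced result files (they must exist)."""
        traces = read_traces_csv(base / self.trace_file)
        recording = read_locomotion_jsonl(base / self.locomotion_file)
        return traces, recording


def write_manifest(manifest: ResultManifest, path) -> None:
    payload = {
        "trace_file": manifest.trace_file,
        "locomotion_file": manifest.locomotion_file,
        "experiment_file": manifest.experiment_file,
        "network_file": manifest.network_file,
        "clock_offset_ms": manifest.clock_offset_ms,
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def load_manifest(path) -> ResultManifest:
    obj = json.loads(Path(path).read_text())
    manifest = ResultManifest(
        trace_file=obj["trace_file"],
        locomotion_file=obj["locomotion_file"],
        experiment_file=obj.get("experiment_file"),
        network_file=obj.get("network_file"),
        clock_offset_ms=float(obj.get("clock_offset_ms", 0.0)),
    )
    base = Path(path).parent
    for ref in (manifest.trace_file, manifest.locomotion_file):
        if not (base / ref).exists():
            raise FileNotFoundError(f"manifest references missing file {ref!r}")
    return manifest


def check_clock_reconciliation(
    traces: NeuralTraceSet, recording: LocomotionRecording, clock_offset_ms: float = 0.0
) -> None:
    """Every frame timestamp (offset-corrected) must land within dt/2 of a
    trace grid point; raises ``ValueError`` otherwise."""
    dt = traces.dt
    for i, frame in enumerate(recording.frames):
        t = frame.timestamp + clock_offset_ms
        nearest = round(t / dt) * dt
        if abs(t - nearest) > dt / 2 + 1e-9 or not (
            traces.times[0] - dt / 2 <= t <= traces.times[-1] + dt / 2 + 1e-9
        ):
            raise ValueError(
                f"frame {i} at {frame.timestamp} ms does not reconcile with the trace clock"
            )
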