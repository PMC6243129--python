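"""Timeline slicing over a manifest-referenced results bundle.

Slicing is half-open [t0, t1) and re-zeroes the clock, so it acts as a
monoid: ``slice(slice(x, a, b), c, d) == slice(x, a+c, a+d)``, and two
abutting slices concatenate back to the original.
"""

from __future__ import annotations

from dataclasses import replace
from pathlib import Path

from .locomotion import LocomotionRecording
from .manifest import ResultManifest
from .traces import NeuralTraceSet

__all__ = ["slice_results", "concat_traces", "concat_recordings"]


def slice_results(
    manifest: ResultManifest, t0: float, t1: float, base_dir="."
) -> tuple[NeuralTraceSet, LocomotionRecording]:
    """Load the bundle behind ``manifest`` and restrict both result streams
    to [t0, t1) on the common (offset-reconciled) clock."""
    traces, recording = manifest.resolve(Path(base_dir))
    duration = traces.times[-1] + traces.dt
    if not 0 <= t0 < t1 <= duration + 1e-9:
        raise ValueError(f"slice bounds [{t0}, {t1}) outside [0, {duration}]")
    if manifest.clock_offset_ms:
        recording = LocomotionRecording(frames=tuple(
            replace(f, timestamp=f.timestamp + manifest.clock_offset_ms)
            for f in recording.frames
        ))
    return traces.slice(t0, t1), recording.slice(t0, t1)


def concat_traces(first: NeuralTraceSet, second: NeuralTraceSet) -> NeuralTraceSet:
    """Concatenate an abutting pair produced by slicing at one cut point."""
    import numpy as np

    if set(first.traces) != set(second.traces):
        raise ValueError("trace sets carry different columns")
    offset = first.times[-1] + first.dt
    return replace(
        first,
        times=np.concatenate([first.times, second.times + offset]),
        traces={k: np.concatenate([first.traces[k], second.traces[k]]) for k in first.traces},
        spikes={k: first.spikes.get(k, []) + [t + offset for t in second.spikes.get(k, [])]
                for k in set(first.spikes) | set(second.spikes)},
    )


def concat_recordings(first: LocomotionRecording, second: LocomotionRecording,
                      offset: float) -> LocomotionRecording:
    return LocomotionRecording(frames=first.frames + tuple(
        replace(f, timestamp=f.timestamp + offset) for f in second.frames
    ))
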