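"""Worm locomotion recordings: timestamped midline + muscle-activation frames.

Format: JSON-lines, one frame per line, keys sorted — the physics-engine
payload stand-in.  Each frame carries the worm's midline as N ordered 3D
points (mm) and the activation of the 95 body-wall muscle cells in [0, 1].

Muscle channel order (anatomical, fixed): the four quadrants interleaved
head-to-tail as ``DL1, DR1, VL1, VR1, DL2, ...`` — dorsal-left, dorsal-right,
ventral-left, ventral-right — for 24 rows, minus the absent 24th ventral-left
cell, giving 95 channels.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

__all__ = ["N_BODY_WALL_MUSCLES", "LocomotionFrame", "LocomotionRecording",
           "write_locomotion_jsonl", "read_locomotion_jsonl", "muscle_channel_names"]

N_BODY_WALL_MUSCLES = 95


def muscle_channel_names() -> list[str]:
    names = []
    for row in range(1, 25):
        for quadrant in ("DL", "DR", "VL", "VR"):
            if quadrant == "VL" and row == 24:
                continue  # the ventral-left column has 23 cells
            names.append(f"M{quadrant}{row:02d}")
    assert len(names) == N_BODY_WALL_MUSCLES
    return names


@dataclass(frozen=True)
class LocomotionFrame:
    timestamp: float  # ms
    midline: tuple[tuple[float, float, float], ...]  # N ordered 3D points, mm
    muscle_activations: tuple[float, ...]  # 95 values in [0, 1]


@dataclass(frozen=True)
class LocomotionRecording:
    frames: tuple[LocomotionFrame, ...]

    def check(self) -> None:
        if not self.frames:
            raise ValueError("empty recording")
        n_points = len(self.frames[0].midline)
        prev = -math.inf
        for i, frame in enumerate(self.frames):
            if frame.timestamp <= prev:
                raise ValueError(f"frame {i}: timestamps must be strictly increasing")
            prev = frame.timestamp
            if len(frame.midline) != n_points:
                raise ValueError(f"frame {i}: midline point count changed")
            if len(frame.muscle_activations) != N_BODY_WALL_MUSCLES:
                raise ValueError(
                    f"frame {i}: expected {N_BODY_WALL_MUSCLES} muscle activations, "
                    f"got {len(frame.muscle_activations)}"
                )
            for a in frame.muscle_activations:
                if not 0.0 <= a <= 1.0:
                    raise ValueError(f"frame {i}: muscle activation {a} outside [0, 1]")

    def n_frames(self) -> int:
        return len(self.frames)

    def timestamps(self) -> np.ndarray:
        return np.array([f.timestamp for f in self.frames])

    def slice(self, t0: float, t1: float) -> "LocomotionRecording":
        """Frames with t0 <= timestamp < t1, re-zeroed to t0."""
        if not t0 < t1:
            raise ValueError(f"need t0 < t1, got [{t0}, {t1})")
        kept = tuple(
            replace(f, timestamp=f.timestamp - t0)
            for f in self.frames
            if t0 - 1e-9 <= f.timestamp < t1 - 1e-9
        )
        return LocomotionRecording(frames=kept)


def _frame_to_json(frame: LocomotionFrame) -> str:
    return json.dumps(
        {
            "t_ms": round(frame.timestamp, 9),
            "midline_mm": [[round(c, 9) for c in p] for p in frame.midline],
            "muscles": [round(a, 9) for a in frame.muscle_activations],
        },
        sort_keys=True,
    )


def write_locomotion_jsonl(recording: LocomotionRecording, path) -> None:
    recording.check()
    with open(path, "w") as fh:
        for frame in recording.frames:
            fh.write(_frame_to_json(frame) + "\n")


def read_locomotion_jsonl(path) -> LocomotionRecording:
    frames = []
    for i, line in enumerate(Path(path).read_text().splitlines()):
        if not line.strip():
            continue
        try:
            obj = json.loads(line)
        except json.JSONDecodeError as exc:
            raise ValueError(f"{path}:{i + 1}: bad JSON frame: {exc}") from exc
        frames.append(
            LocomotionFrame(
                timestamp=float(obj["t_ms"]),
                midline=tuple(tuple(float(c) for c in p) for p in obj["midline_mm"]),
                muscle_activations=tuple(float(a) for a in obj["muscles"]),
            )
        )
    recording = LocomotionRecording(frames=tuple(frames))
    recording.check()
    return recording
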