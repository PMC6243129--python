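"""Synthetic results generator: the physics-engine stand-in.

Produces, deterministically per seed, a results bundle with the shape and
statistics of a real run: per-neuron membrane-potential traces with
spiking-like structure (noisy leaky integration with threshold resets) and a
locomotion recording whose midline undulates as a traveling dorsoventral
wave — the worm's crawling gait — with matching rhythmic muscle
activations.  It exists so the whole results pipeline (files, manifest,
slicing, visualization consumers) is exercisable without a body simulation.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from ..network.connectome import Connectome
from .locomotion import (
    N_BODY_WALL_MUSCLES,
    LocomotionFrame,
    LocomotionRecording,
)
from .manifest import ResultManifest, write_manifest
from .traces import NeuralTraceSet, write_traces_csv

__all__ = ["generate_synthetic_results", "write_synthetic_bundle"]

# crawling gait parameters (typical values for agar crawling)
_WAVELENGTH_FRACTION = 1.5  # body lengths per undulation wavelength
_WAVE_PERIOD_MS = 1600.0  # one undulation cycle
_AMPLITUDE_MM = 0.12  # peak lateral excursion
_BODY_LENGTH_MM = 1.0


def _synthetic_traces(
    seed: int, duration: float, dt: float, neurons: list[str]
) -> NeuralTraceSet:
    gen = np.random.default_rng(seed)
    n = int(np.floor(duration / dt + 1e-9)) + 1
    times = np.arange(n) * dt
    v_rest, v_thresh, v_reset, v_peak = -65.0e-3, -50.0e-3, -65.0e-3, 30.0e-3
    tau = 10.0  # ms
    traces: dict[tuple[str, str], np.ndarray] = {}
    spikes: dict[str, list[float]] = {}
    for neuron in neurons:
        drive = gen.uniform(0.5, 2.0) * (v_thresh - v_rest) / tau  # V per ms
        noise = gen.normal(0.0, 0.3e-3, size=n)
        v = np.empty(n)
        v[0] = v_rest
        neuron_spikes = []
        for i in range(1, n):
            dv = (v_rest - v[i - 1]) / tau + drive
            v[i] = v[i - 1] + dt * dv + noise[i]
            if v[i] >= v_thresh:
                v[i - 1] = v_peak  # draw the spike overshoot
                v[i] = v_reset
                neuron_spikes.append(times[i])
        traces[(neuron, "v")] = v
        spikes[neuron] = neuron_spikes
    return NeuralTraceSet(times=times, dt=dt, traces=traces, spikes=spikes,
                          experiment_id=f"synthetic-{seed}",
                          network_config_id=f"synthetic-{seed}")


def _synthetic_locomotion(
    seed: int, duration: float, dt: float, n_midline_points: int
) -> LocomotionRecording:
    gen = np.random.default_rng(seed + 1)
    n = int(np.floor(duration / dt + 1e-9)) + 1
    phase0 = gen.uniform(0.0, 2.0 * np.pi)
    s = np.linspace(0.0, 1.0, n_midline_points)  # fraction along the body
    k = 2.0 * np.pi * _WAVELENGTH_FRACTION
    omega = 2.0 * np.pi / _WAVE_PERIOD_MS
    frames = []
    for i in range(n):
        t = i * dt
        # traveling wave moves tail-ward; worm advances slowly along +x
        lateral = _AMPLITUDE_MM * np.sin(k * s - omega * t + phase0)
        x = s * _BODY_LENGTH_MM + 0.05 * (t / _WAVE_PERIOD_MS)
        midline = tuple(
            (float(xi), float(yi), 0.0) for xi, yi in zip(x, lateral)
        )
        # muscles: dorsal and ventral rows in antiphase along the same wave
        rows = np.linspace(0.0, 1.0, 24)
        dorsal = 0.5 + 0.5 * np.sin(k * rows - omega * t + phase0)
        ventral = 1.0 - dorsal
        activations = []
        for row in range(24):
            for quadrant in ("DL", "DR", "VL", "VR"):
                if quadrant == "VL" and row == 23:
                    continue
                level = dorsal[row] if quadrant.startswith("D") else ventral[row]
                activations.append(float(np.clip(level, 0.0, 1.0)))
        assert len(activations) == N_BODY_WALL_MUSCLES
        frames.append(LocomotionFrame(timestamp=t, midline=midline,
                                      muscle_activations=tuple(activations)))
    return LocomotionRecording(frames=tuple(frames))


def generate_synthetic_results(
    seed: int,
    duration: float,
    dt: float,
    connectome: Connectome,
    n_midline_points: int = 33,
    max_neurons: int | None = 12,
) -> tuple[NeuralTraceSet, LocomotionRecording, ResultManifest]:
    """Deterministic synthetic results bundle sharing one clock.

    Traces are generated for the first ``max_neurons`` neurons of the
    connectome (all of them if ``max_neurons`` is None).  Frame count is
    ``floor(duration/dt) + 1``; each frame carries the full 95 body-wall
    muscle channels.
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    names = connectome.names()
    if max_neurons is not None:
        names = names[:max_neurons]
    traces = _synthetic_traces(seed, duration, dt, names)
    recording = _synthetic_locomotion(seed, duration, dt, n_midline_points)
    manifest = ResultManifest(
        trace_file="traces.csv",
        locomotion_file="locomotion.jsonl",
        clock_offset_ms=0.0,
    )
    return traces, recording, manifest


def write_synthetic_bundle(out_dir, seed: int, duration: float, dt: float,
                           connectome: Connectome, n_midline_points: int = 33) -> ResultManifest:
    """Generate and write the full bundle (CSV + JSONL + manifest) to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    traces, recording, manifest = generate_synthetic_results(
        seed, duration, dt, connectome, n_midline_points
    )
    write_traces_csv(traces, out / manifest.trace_file)
    from .locomotion import write_locomotion_jsonl

    write_locomotion_jsonl(recording, out / manifest.locomotion_file)
    write_manifest(manifest, out / "manifest.json")
    return manifest
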