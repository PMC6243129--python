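"""Results I/O: CSV/JSONL round-trips, synthetic bundle invariants, slicing
algebra, clock reconciliation, and viewer highlight sets."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nemasim.results import (
    N_BODY_WALL_MUSCLES,
    check_clock_reconciliation,
    concat_traces,
    generate_synthetic_results,
    highlight_sets,
    load_manifest,
    muscle_channel_names,
    read_locomotion_jsonl,
    read_traces_csv,
    slice_results,
    write_locomotion_jsonl,
    write_synthetic_bundle,
    write_traces_csv,
)
from nemasim.network import load_connectome, packaged_connectome


@pytest.fixture(scope="module")
def connectome():
    return packaged_connectome()


@pytest.fixture
def bundle(tmp_path, connectome):
    manifest = write_synthetic_bundle(tmp_path, seed=11, duration=300.0, dt=1.0,
                                      connectome=connectome)
    return tmp_path, manifest


class TestTraceCsv:
    def test_column_count_is_traces_plus_time(self, tmp_path, connectome):
        traces, _, _ = generate_synthetic_results(1, 50.0, 1.0, connectome, max_neurons=4)
        # keep two variables per neuron to check the 2x2 -> 5 column layout
        two_var = {k: v for k, v in list(traces.traces.items())[:2]}
        for (n, _), arr in list(two_var.items()):
            traces.traces[(n, "u")] = arr * 0.5
        traces.traces = {k: traces.traces[k] for k in list(two_var) +
                         [(n, "u") for n, _ in two_var]}
        path = tmp_path / "t.csv"
        write_traces_csv(traces, path)
        header = path.read_text().splitlines()[1].split(",")
        assert len(header) == 5
        assert header[0] == "time_ms"

    def test_write_read_write_byte_stable(self, bundle):
        base, manifest = bundle
        first = (base / manifest.trace_file).read_bytes()
        again = read_traces_csv(base / manifest.trace_file)
        write_traces_csv(again, base / "copy.csv")
        assert (base / "copy.csv").read_bytes() == first

    def test_values_round_trip_to_printed_precision(self, bundle):
        base, manifest = bundle
        traces = read_traces_csv(base / manifest.trace_file)
        write_traces_csv(traces, base / "again.csv")
        again = read_traces_csv(base / "again.csv")
        for key in traces.traces:
            np.testing.assert_allclose(again.traces[key], traces.traces[key],
                                       rtol=1e-11, atol=0)


class TestSyntheticGenerator:
    def test_frame_and_sample_counts(self, connectome):
        traces, recording, _ = generate_synthetic_results(5, 123.0, 0.5, connectome,
                                                          max_neurons=3)
        expected = int(np.floor(123.0 / 0.5)) + 1
        assert traces.n_samples() == expected
        assert recording.n_frames() == expected

    def test_each_frame_carries_95_muscle_activations(self, connectome):
        _, recording, _ = generate_synthetic_results(5, 40.0, 2.0, connectome,
                                                     max_neurons=2)
        assert all(len(f.muscle_activations) == N_BODY_WALL_MUSCLES
                   for f in recording.frames)
        assert len(muscle_channel_names()) == N_BODY_WALL_MUSCLES

    def test_same_seed_twice_gives_identical_files(self, tmp_path, connectome):
        write_synthetic_bundle(tmp_path / "a", 9, 100.0, 1.0, connectome)
        write_synthetic_bundle(tmp_path / "b", 9, 100.0, 1.0, connectome)
        for name in ("traces.csv", "locomotion.jsonl", "manifest.json"):
            assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()

    def test_different_seeds_differ(self, tmp_path, connectome):
        write_synthetic_bundle(tmp_path / "a", 1, 100.0, 1.0, connectome)
        write_synthetic_bundle(tmp_path / "b", 2, 100.0, 1.0, connectome)
        assert (tmp_path / "a/traces.csv").read_bytes() != (tmp_path / "b/traces.csv").read_bytes()

    def test_traces_exhibit_spiking_structure(self, connectome):
        traces, _, _ = generate_synthetic_results(3, 500.0, 0.5, connectome,
                                                  max_neurons=6)
        assert any(len(s) > 0 for s in traces.spikes.values())

    def test_midline_is_a_traveling_wave(self, connectome):
        _, recording, _ = generate_synthetic_results(3, 400.0, 10.0, connectome,
                                                     max_neurons=1)
        first = np.array([p[1] for p in recording.frames[0].midline])
        later = np.array([p[1] for p in recording.frames[20].midline])
        # undulation present and phase-shifted over time
        assert first.std() > 0.01
        assert not np.allclose(first, later)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), duration=st.floats(10.0, 400.0),
           dt=st.sampled_from([0.5, 1.0, 2.0]))
    def test_generator_output_always_satisfies_invariants(self, seed, duration, dt):
        connectome = load_connectome(
            "name\tclass\tcategory\tx\ty\tz\nX\tX\tinter\t0\t0\t0\n",
            "pre\tpost\tkind\n")
        traces, recording, _ = generate_synthetic_results(seed, duration, dt, connectome)
        traces.check()
        recording.check()
        assert np.all(np.diff(recording.timestamps()) > 0)


class TestManifestAndClock:
    def test_manifest_loads_and_resolves(self, bundle):
        base, _ = bundle
        manifest = load_manifest(base / "manifest.json")
        traces, recording = manifest.resolve(base)
        assert traces.n_samples() == recording.n_frames()

    def test_missing_referenced_file_rejected(self, bundle):
        base, _ = bundle
        (base / "locomotion.jsonl").rename(base / "gone.jsonl")
        with pytest.raises(FileNotFoundError):
            load_manifest(base / "manifest.json")

    def test_clock_reconciliation(self, bundle):
        base, manifest = bundle
        traces, recording = manifest.resolve(base)
        check_clock_reconciliation(traces, recording)  # within dt/2 everywhere

    def test_unreconcilable_clock_flagged(self, bundle):
        base, manifest = bundle
        traces, recording = manifest.resolve(base)
        with pytest.raises(ValueError, match="reconcile"):
            check_clock_reconciliation(traces, recording, clock_offset_ms=0.7)


class TestSlicing:
    def test_full_slice_is_identity(self, bundle):
        base, manifest = bundle
        traces, recording = manifest.resolve(base)
        duration = traces.times[-1] + traces.dt
        sliced_t, sliced_r = slice_results(manifest, 0.0, duration, base)
        assert np.array_equal(sliced_t.times, traces.times)
        assert sliced_r.n_frames() == recording.n_frames()

    def test_abutting_slices_concatenate_to_original(self, bundle):
        base, manifest = bundle
        traces, _ = manifest.resolve(base)
        duration = traces.times[-1] + traces.dt
        cut = 120.0
        left, _ = slice_results(manifest, 0.0, cut, base)
        right, _ = slice_results(manifest, cut, duration, base)
        rebuilt = concat_traces(left, right)
        assert np.array_equal(rebuilt.times, traces.times)
        for key in traces.traces:
            np.testing.assert_array_equal(rebuilt.traces[key], traces.traces[key])

    def test_slicing_is_a_monoid_action(self, bundle):
        base, manifest = bundle
        traces, _ = manifest.resolve(base)
        a, b = 50.0, 250.0
        c, d = 30.0, 120.0
        outer, _ = slice_results(manifest, a, b, base)
        inner = outer.slice(c, d)
        direct = traces.slice(a + c, a + d)
        assert np.array_equal(inner.times, direct.times)
        for key in traces.traces:
            np.testing.assert_array_equal(inner.traces[key], direct.traces[key])

    def test_random_slice_lengths_match_index_arithmetic(self, bundle):
        import random

        base, manifest = bundle
        traces, _ = manifest.resolve(base)
        rng = random.Random(5)
        for _ in range(50):
            t0 = rng.uniform(0.0, 250.0)
            t1 = rng.uniform(t0 + 1.0, 300.0)
            sliced = traces.slice(t0, t1)
            expected = sum(1 for t in traces.times if t0 - 1e-9 <= t < t1 - 1e-9)
            assert sliced.n_samples() == expected

    def test_out_of_range_bounds_rejected(self, bundle):
        base, manifest = bundle
        with pytest.raises(ValueError):
            slice_results(manifest, -10.0, 50.0, base)
        with pytest.raises(ValueError):
            slice_results(manifest, 200.0, 100.0, base)


class TestHighlightSets:
    def test_toy_selection(self):
        connectome = load_connectome(
            "name\tclass\tcategory\tx\ty\tz\nA\tA\tinter\t0\t0\t0\nB\tB\tinter\t0\t0\t1\n",
            "pre\tpost\tkind\nA\tB\tchemical\n")
        sets = highlight_sets(connectome, "A")
        assert sets == {"selected": {"A"}, "postsynaptic": {"B"}}

    def test_isolated_neuron_has_empty_postsynaptic_set(self):
        connectome = load_connectome(
            "name\tclass\tcategory\tx\ty\tz\nA\tA\tinter\t0\t0\t0\n",
            "pre\tpost\tkind\n")
        assert highlight_sets(connectome, "A")["postsynaptic"] == set()

    def test_fixture_spot_check_equals_adjacency_scan(self, connectome):
        for name in ("AVAL", "AVM", "PLML"):
            expected = {c.post for c in connectome.connections
                        if c.kind == "chemical" and c.pre == name}
            assert highlight_sets(connectome, name)["postsynaptic"] == expected

    def test_locomotion_write_read_write_byte_stable(self, tmp_path, connectome):
        _, recording, _ = generate_synthetic_results(2, 60.0, 2.0, connectome,
                                                     max_neurons=1)
        write_locomotion_jsonl(recording, tmp_path / "l.jsonl")
        again = read_locomotion_jsonl(tmp_path / "l.jsonl")
        write_locomotion_jsonl(again, tmp_path / "l2.jsonl")
        assert (tmp_path / "l.jsonl").read_bytes() == (tmp_path / "l2.jsonl").read_bytes()
        # values preserved to the printed (9-decimal) precision
        for f1, f2 in zip(recording.frames, again.frames):
            assert f2.timestamp == pytest.approx(f1.timestamp, abs=1e-9)
            np.testing.assert_allclose(f2.muscle_activations, f1.muscle_activations,
                                       atol=1e-9)
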