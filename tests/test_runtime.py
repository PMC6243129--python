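"""Reference interpreter: flattening structure, closed-form spike timing,
dt-convergence, symmetry, determinism, and stimulus transduction."""

import math

import numpy as np
import pytest

from nemasim.experiment import (
    DirectTouch,
    EventCategory,
    Modality,
    TimelineEvent,
    generate_fixture_experiment,
)
from nemasim.lems import (
    Link,
    compose_model,
    core_type,
    export_lems,
    import_lems,
    instantiate,
)
from nemasim.network import (
    NetworkConfiguration,
    NeuronSelector,
    SynapseSelector,
    assign_models,
    assign_synapses,
    auto_select_recorded_variables,
    export_network,
    import_network,
    load_connectome,
)
from nemasim.runtime import (
    FlattenError,
    SimulationError,
    SimulationSpec,
    Waveform,
    default_transduction_map,
    flatten,
    run,
    transduce,
)

from conftest import IAF_BINDINGS, driven_iaf

# closed-form inter-spike interval of the leaky integrate-and-fire cell:
# T = tau * ln(R I / (R I - V_theta)), tau = C/gL, R = 1/gL, V_theta = thresh - reset
C_SI, GL_SI = 1e-9, 50e-9
V_THETA = 15e-3  # thresh -50 mV, reset -65 mV


def iaf_isi_closed_form(current_a: float) -> float:
    tau = C_SI / GL_SI
    ri = current_a / GL_SI
    return tau * math.log(ri / (ri - V_THETA)) * 1e3  # ms


def mean_isi(spikes: list[float]) -> float:
    return float(np.mean(np.diff(spikes)))


class TestFlatten:
    def test_single_iaf_structure(self):
        system = flatten(driven_iaf(2.0))
        cell = system.instances["cell"]
        assert list(cell.ctype.state_variables) == ["v"]
        assert len(cell.ctype.on_conditions) == 1

    def test_izhikevich_structure(self, izh_cell):
        gen = instantiate(core_type("constantCurrent"), {"amplitude": "0.1 nA"}, id="gen")
        model = compose_model([izh_cell, gen], [Link("gen", "i", "izh", "iSyn")])
        system = flatten(model)
        izh = system.instances["izh"]
        assert sorted(izh.ctype.state_variables) == ["u", "v"]
        assert len(izh.ctype.on_conditions) == 1  # the peak/reset rule

    def test_cyclic_cross_component_deriveds_rejected(self):
        from nemasim.expressions import parse_expression
        from nemasim.lems import ComponentType
        from nemasim.units import DIMENSIONS

        loop = ComponentType(
            name="loop",
            derived_variables={"out": parse_expression("inp * 2")},
            exposures={"out": "out"},
            requirements={"inp": DIMENSIONS["none"]},
        )
        a = instantiate(loop, {}, id="a")
        b = instantiate(loop, {}, id="b")
        model = compose_model([a, b], [Link("a", "out", "b", "inp"),
                                       Link("b", "out", "a", "inp")])
        with pytest.raises(FlattenError, match="cyclic"):
            flatten(model)


class TestIafAgainstClosedForm:
    def test_zero_current_decays_monotonically_with_no_spikes(self):
        bindings = dict(IAF_BINDINGS, reset="-60 mV")  # start above rest
        model = driven_iaf(0.0, bindings)
        result = run(SimulationSpec(model=model, duration=100.0, dt=0.05))
        v = result.trace("cell", "v")
        assert np.all(np.diff(v) <= 1e-15)
        assert v[-1] == pytest.approx(-65e-3, abs=1e-4)
        assert result.spikes["cell"] == []

    def test_isi_matches_closed_form_within_2_percent(self):
        result = run(SimulationSpec(model=driven_iaf(2.0), duration=100.0, dt=0.01))
        spikes = result.spikes["cell"]
        assert len(spikes) >= 5
        assert mean_isi(spikes) == pytest.approx(iaf_isi_closed_form(2e-9), rel=0.02)

    def test_dt_refinement_moves_spike_times_by_order_dt(self):
        """Halving dt changes the first spike time by at most O(dt), and the
        subthreshold trajectory error shrinks linearly (forward Euler)."""
        first_spikes = {}
        for dt in (0.08, 0.04, 0.02, 0.01):
            result = run(SimulationSpec(model=driven_iaf(2.0), duration=50.0, dt=dt))
            first_spikes[dt] = result.spikes["cell"][0]
        for dt in (0.08, 0.04, 0.02):
            assert abs(first_spikes[dt] - first_spikes[dt / 2]) <= 2 * dt
        # continuous observable: subthreshold charging curve vs analytic
        tau_ms = (C_SI / GL_SI) * 1e3
        ri = 2e-9 / GL_SI
        t = 5.0  # ms, before the first spike
        exact_v = -65e-3 + ri * (1 - math.exp(-t / tau_ms))
        errors = []
        for dt in (0.1, 0.05, 0.025):
            result = run(SimulationSpec(model=driven_iaf(2.0), duration=t, dt=dt))
            errors.append(abs(result.trace("cell", "v")[-1] - exact_v))
        assert errors[0] > errors[1] > errors[2]
        assert errors[2] == pytest.approx(errors[0] / 4, rel=0.3)


class TestNetworkDynamics:
    def _two_cell_gap_network(self, conductance="1 nS"):
        neurons = ("name\tclass\tcategory\tx\ty\tz\n"
                   "A\tA\tinter\t0\t0\t0\nB\tB\tinter\t0\t0\t1\n")
        conns = "pre\tpost\tkind\nA\tB\tgap_junction\n"
        connectome = load_connectome(neurons, conns)
        cell = instantiate(core_type("iafCell"), IAF_BINDINGS, id="iaf")
        gap = instantiate(core_type("gapJunction"), {"conductance": conductance}, id="gj")
        config = NetworkConfiguration(connectome=connectome)
        config = assign_models(config, NeuronSelector(), cell)
        config = assign_synapses(config, SynapseSelector(kind="gap_junction"), gap)
        return import_network(export_network(auto_select_recorded_variables(config)))

    def test_gap_junction_symmetry(self):
        """Identical coupled cells from identical states stay identical."""
        network = self._two_cell_gap_network()
        inj = Waveform.pulse(0.0, 80.0, 1.2)
        result = run(SimulationSpec(model=network, duration=80.0, dt=0.05,
                                    injections=(("A", inj), ("B", inj))))
        assert np.array_equal(result.trace("A", "v"), result.trace("B", "v"))
        assert result.spikes["A"] == result.spikes["B"]

    def test_zero_conductance_synapses_preserve_isolated_trajectory(self):
        """With no injections and zero-conductance coupling, each cell's
        trajectory equals its isolated-cell trajectory."""
        network = self._two_cell_gap_network(conductance="0 nS")
        coupled = run(SimulationSpec(model=network, duration=50.0, dt=0.05))
        isolated = run(SimulationSpec(model=driven_iaf(0.0), duration=50.0, dt=0.05))
        assert np.array_equal(coupled.trace("A", "v"), isolated.trace("cell", "v"))

    def test_chemical_synapse_propagates_spikes(self, toy_connectome, exc_synapse):
        cell = instantiate(core_type("iafCell"), IAF_BINDINGS, id="iaf")
        gap = instantiate(core_type("gapJunction"), {"conductance": "0.2 nS"}, id="gj")
        strong = instantiate(core_type("expOneSynapse"),
                             {"gbase": "20 nS", "erev": "0 mV", "tauDecay": "10 ms"},
                             id="strong")
        config = NetworkConfiguration(connectome=toy_connectome)
        config = assign_models(config, NeuronSelector(), cell)
        config = assign_synapses(config, SynapseSelector(kind="chemical"), strong)
        config = assign_synapses(config, SynapseSelector(kind="gap_junction"), gap)
        network = import_network(export_network(auto_select_recorded_variables(config)))
        result = run(SimulationSpec(model=network, duration=120.0, dt=0.05,
                                    injections=(("ALML", Waveform.pulse(0.0, 120.0, 2.0)),)))
        assert result.spikes["ALML"]
        assert result.spikes["AVDL"]  # driven only through the synapse

    def test_determinism(self):
        network = self._two_cell_gap_network()
        spec = SimulationSpec(model=network, duration=60.0, dt=0.05,
                              injections=(("A", Waveform.pulse(5.0, 50.0, 1.5)),))
        first, second = run(spec), run(spec)
        assert all(np.array_equal(first.traces[k], second.traces[k]) for k in first.traces)
        assert first.spikes == second.spikes

    def test_trace_length_is_floor_duration_over_dt_plus_one(self):
        network = self._two_cell_gap_network()
        result = run(SimulationSpec(model=network, duration=10.0, dt=0.3))
        assert len(result.times) == math.floor(10.0 / 0.3) + 1
        assert all(len(tr) == len(result.times) for tr in result.traces.values())


class TestRoundTripBehavioralEquivalence:
    def test_exported_model_runs_identically_after_round_trip(self):
        model = driven_iaf(2.0)
        direct = run(SimulationSpec(model=model, duration=100.0, dt=0.02))
        reimported = import_lems(export_lems(model))
        again = run(SimulationSpec(model=reimported, duration=100.0, dt=0.02))
        assert direct.spikes["cell"] == again.spikes["cell"]
        assert np.array_equal(direct.trace("cell", "v"), again.trace("cell", "v"))


class TestRk4CrossCheck:
    def test_passive_decay_matches_analytic_solution_better_than_euler(self):
        bindings = dict(IAF_BINDINGS, reset="-55 mV")  # start above rest, subthreshold
        model = driven_iaf(0.0, bindings)
        tau_ms = (C_SI / GL_SI) * 1e3
        t = 20.0
        exact = -65e-3 + 10e-3 * math.exp(-t / tau_ms)
        euler = run(SimulationSpec(model=model, duration=t, dt=0.1))
        rk4 = run(SimulationSpec(model=model, duration=t, dt=0.1, method="rk4"))
        err_euler = abs(euler.trace("cell", "v")[-1] - exact)
        err_rk4 = abs(rk4.trace("cell", "v")[-1] - exact)
        assert err_rk4 < err_euler / 100
        assert err_rk4 < 1e-9


class TestErrors:
    def test_overflow_reported_with_time_and_instance(self):
        # dq/dt = q^2 / tau blows up in finite time; no reset rule exists
        from nemasim.expressions import parse_expression
        from nemasim.lems import ComponentType
        from nemasim.units import DIMENSIONS

        explosive = ComponentType(
            name="explosive",
            parameters={"tau": DIMENSIONS["time"]},
            state_variables={"q": DIMENSIONS["none"]},
            time_derivatives={"q": parse_expression("q * q / tau")},
            on_start=(("q", parse_expression("2")),),
        )
        assert explosive.validate() == []
        model = compose_model([instantiate(explosive, {"tau": "1 ms"}, id="boom")])
        with pytest.raises(SimulationError, match="overflow.*'boom' at t="):
            run(SimulationSpec(model=model, duration=100.0, dt=0.5,
                               recorded=(("boom", "q"),)))

    def test_unknown_injection_target_rejected(self):
        with pytest.raises(ValueError, match="unknown instance"):
            run(SimulationSpec(model=driven_iaf(0.0), duration=10.0, dt=0.1,
                               injections=(("ghost", Waveform.pulse(0, 5, 1.0)),)))

    def test_bad_dt_rejected(self):
        with pytest.raises(ValueError, match="dt"):
            run(SimulationSpec(model=driven_iaf(0.0), duration=10.0, dt=0.0))


class TestTransduction:
    def test_no_events_gives_no_injections(self):
        experiment = generate_fixture_experiment(0, 0)
        assert transduce(experiment) == []

    def test_interval_touch_pulses_exactly_on_window(self):
        touch = TimelineEvent(
            EventCategory.INTERVAL, Modality.MECHANOTAXIS,
            DirectTouch(body_position=0.2, circumferential_angle=0.0,
                        force=10.0, contact_duration=0.0),
            event_start_time=100.0, event_stop_time=400.0,
        )
        experiment = generate_fixture_experiment(0, 0).with_events([touch])
        injections = transduce(experiment)
        targets = {n for n, _ in injections}
        assert targets == {"ALML", "ALMR", "AVM"}  # anterior receptive field
        for _, wf in injections:
            assert wf.value(99.9) == 0.0
            assert wf.value(100.0) == pytest.approx(1.0)  # 0.1 nA/μN * 10 μN
            assert wf.value(399.9) == pytest.approx(1.0)
            assert wf.value(400.0) == 0.0

    def test_posterior_touch_targets_posterior_neurons(self):
        touch = TimelineEvent(
            EventCategory.INSTANT, Modality.MECHANOTAXIS,
            DirectTouch(body_position=0.9, circumferential_angle=0.0,
                        force=5.0, contact_duration=250.0),
            event_time=1000.0,
        )
        experiment = generate_fixture_experiment(0, 0).with_events([touch])
        injections = transduce(experiment)
        assert {n for n, _ in injections} == {"PLML", "PLMR", "PVM"}
        # instant touch injects over its contact duration
        for _, wf in injections:
            assert wf.value(1100.0) > 0.0
            assert wf.value(1251.0) == 0.0

    def test_injected_charge_equals_amplitude_times_window(self):
        wf = Waveform.pulse(100.0, 400.0, 1.0)
        assert wf.integral(0.0, 500.0) == pytest.approx(1.0 * 300.0, rel=1e-6)

    def test_magnitude_scales_linearly(self):
        def single_amplitude(force):
            touch = TimelineEvent(
                EventCategory.INTERVAL, Modality.MECHANOTAXIS,
                DirectTouch(0.2, 0.0, force, 0.0),
                event_start_time=0.0, event_stop_time=100.0,
            )
            experiment = generate_fixture_experiment(0, 0).with_events([touch])
            (_, wf), *_ = transduce(experiment)
            return wf.value(50.0)

        assert single_amplitude(8.0) == pytest.approx(2 * single_amplitude(4.0))

    def test_unmapped_modalities_are_no_ops(self):
        experiment = generate_fixture_experiment(3, 12)
        injections = transduce(experiment)
        touch_targets = {"ALML", "ALMR", "AVM", "PLML", "PLMR", "PVM"}
        assert {n for n, _ in injections} <= touch_targets

    def test_rule_targeting_unknown_neuron_rejected(self):
        touch = TimelineEvent(
            EventCategory.INTERVAL, Modality.MECHANOTAXIS,
            DirectTouch(0.2, 0.0, 1.0, 0.0),
            event_start_time=0.0, event_stop_time=10.0,
        )
        experiment = generate_fixture_experiment(0, 0).with_events([touch])
        restricted = default_transduction_map(known_neurons=("PLML",))
        from nemasim.runtime import TransductionError

        with pytest.raises(TransductionError, match="unknown neuron"):
            transduce(experiment, restricted)
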