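"""Network configuration: connectome loading, model/synapse assignment
precedence, recorded-variable auto-selection, export round-trips, and the
postsynaptic-partner oracle."""

import random

import pytest

from nemasim.lems import core_type, instantiate
from nemasim.network import (
    ConfigError,
    ConnectomeError,
    NetworkConfiguration,
    NeuronSelector,
    SelectionMode,
    SelectionSession,
    SynapseSelector,
    assign_models,
    assign_synapses,
    auto_select_recorded_variables,
    export_network,
    gap_junction_neighbors,
    import_network,
    load_connectome,
    override_parameters,
    packaged_connectome,
    postsynaptic_partners,
)

from conftest import TOY_CONNECTIONS, TOY_NEURONS


class TestConnectome:
    def test_packaged_fixture_has_302_neurons(self):
        connectome = packaged_connectome()
        assert len(connectome.neurons) == 302
        assert len({n.name for n in connectome.neurons}) == 302
        assert connectome.connections  # wiring present

    def test_toy_table_loads(self, toy_connectome):
        assert len(toy_connectome.neurons) == 6
        assert len(toy_connectome.connections) == 6
        graph = toy_connectome.graph()
        assert graph.number_of_nodes() == 6
        # gap junction expands to two directed edges in the graph view
        assert graph.number_of_edges() == 7

    def test_dangling_endpoint_rejected(self):
        bad = TOY_CONNECTIONS + "GHOST\tAVAL\tchemical\t1\tunknown\n"
        with pytest.raises(ConnectomeError, match="dangling endpoint 'GHOST'"):
            load_connectome(TOY_NEURONS, bad)

    def test_duplicate_neuron_rejected(self):
        bad = TOY_NEURONS + "ALML\tALM\tsensory\t0\t0\t9\n"
        with pytest.raises(ConnectomeError, match="duplicate neuron"):
            load_connectome(bad, TOY_CONNECTIONS)

    def test_unknown_kind_rejected(self):
        bad = TOY_CONNECTIONS + "ALML\tAVAL\twireless\t1\tunknown\n"
        with pytest.raises(ConnectomeError, match="unknown connection kind"):
            load_connectome(TOY_NEURONS, bad)

    def test_gap_junctions_stored_once_per_pair(self):
        bad = TOY_CONNECTIONS + "AVDR\tAVDL\tgap_junction\t1\tnone\n"
        with pytest.raises(ConnectomeError, match="listed more than once"):
            load_connectome(TOY_NEURONS, bad)


class TestAssignment:
    def test_default_plus_single_override_counts(self, iaf_cell, izh_cell):
        connectome = packaged_connectome()
        config = NetworkConfiguration(connectome=connectome)
        config = assign_models(config, NeuronSelector(), iaf_cell)
        config = assign_models(config, NeuronSelector(names=("AVAL",)), izh_cell)
        resolved = [config.resolve_model(n).type.name for n in connectome.names()]
        assert resolved.count("izhikevichCell") == 1
        assert resolved.count("iafCell") == 301

    def test_category_selector(self, toy_connectome, iaf_cell, izh_cell):
        config = NetworkConfiguration(connectome=toy_connectome)
        config = assign_models(config, NeuronSelector(), iaf_cell)
        config = assign_models(config, NeuronSelector(category="sensory"), izh_cell)
        overridden = [n.name for n in toy_connectome.neurons
                      if config.resolve_model(n.name).type.name == "izhikevichCell"]
        assert overridden == ["ALML", "ALMR"]

    def test_later_assignment_wins(self, toy_connectome, iaf_cell, izh_cell):
        config = NetworkConfiguration(connectome=toy_connectome)
        config = assign_models(config, NeuronSelector(names=("AVAL",)), iaf_cell)
        config = assign_models(config, NeuronSelector(names=("AVAL",)), izh_cell)
        assert config.resolve_model("AVAL").type.name == "izhikevichCell"

    def test_empty_selector_match_warns(self, toy_connectome, iaf_cell):
        config = NetworkConfiguration(connectome=toy_connectome, default_model=iaf_cell)
        with pytest.warns(UserWarning, match="matches no neuron"):
            assign_models(config, NeuronSelector(names=("NOPE",)), iaf_cell)

    def test_non_cell_component_rejected_as_model(self, toy_connectome, exc_synapse):
        config = NetworkConfiguration(connectome=toy_connectome)
        with pytest.raises(ConfigError, match="not a cell model"):
            assign_models(config, NeuronSelector(), exc_synapse)

    def test_parameter_override_rebinds(self, toy_connectome, iaf_cell):
        config = NetworkConfiguration(connectome=toy_connectome, default_model=iaf_cell)
        config = override_parameters(config, "AVAL", {"thresh": (-45.0, "mV")})
        assert config.resolve_model("AVAL").bindings["thresh"][0] == -45.0
        assert config.resolve_model("AVDL").bindings["thresh"][0] == -50.0


class TestSynapseAssignment:
    def test_neurotransmitter_selector(self, toy_connectome, exc_synapse, gap_junction):
        config = NetworkConfiguration(connectome=toy_connectome)
        config = assign_synapses(config, SynapseSelector(kind="chemical"), exc_synapse)
        inh = instantiate(core_type("expOneSynapse"),
                          {"gbase": "2 nS", "erev": "-80 mV", "tauDecay": "20 ms"},
                          id="inh")
        config = assign_synapses(config, SynapseSelector(neurotransmitter="GABA"), inh)
        config = assign_synapses(config, SynapseSelector(kind="gap_junction"), gap_junction)
        mapped = [config.resolve_synapse(c).id for c in toy_connectome.connections]
        assert mapped.count("inh") == 1  # the single GABA edge
        assert mapped.count("exc") == 4
        assert mapped.count("gj") == 1

    def test_kind_mismatch_rejected(self, toy_connectome, exc_synapse, gap_junction):
        config = NetworkConfiguration(connectome=toy_connectome)
        with pytest.raises(ConfigError, match="not a gap junction"):
            assign_synapses(config, SynapseSelector(kind="gap_junction"), exc_synapse)
        with pytest.raises(ConfigError, match="not a chemical synapse"):
            assign_synapses(config, SynapseSelector(kind="chemical"), gap_junction)

    def test_export_blocked_while_any_connection_unmatched(
        self, toy_connectome, iaf_cell, exc_synapse
    ):
        config = NetworkConfiguration(connectome=toy_connectome, default_model=iaf_cell)
        config = assign_synapses(config, SynapseSelector(kind="chemical"), exc_synapse)
        with pytest.raises(ConfigError, match="AVDL->AVDR"):
            export_network(config)


class TestRecordedVariables:
    def _configured(self, connectome, cell, exc_synapse, gap_junction):
        config = NetworkConfiguration(connectome=connectome, default_model=cell)
        config = assign_synapses(config, SynapseSelector(kind="chemical"), exc_synapse)
        config = assign_synapses(config, SynapseSelector(kind="gap_junction"), gap_junction)
        return config

    def test_izhikevich_default_records_two_variables_per_neuron(
        self, toy_connectome, izh_cell, exc_synapse, gap_junction
    ):
        config = self._configured(toy_connectome, izh_cell, exc_synapse, gap_junction)
        config = auto_select_recorded_variables(config)
        assert len(config.recorded_variables) == 2 * len(toy_connectome.neurons)
        per_neuron = {v for n, v in config.recorded_variables if n == "AVAL"}
        assert per_neuron == {"v", "u"}

    def test_auto_selection_is_idempotent(
        self, toy_connectome, izh_cell, exc_synapse, gap_junction
    ):
        config = self._configured(toy_connectome, izh_cell, exc_synapse, gap_junction)
        once = auto_select_recorded_variables(config)
        assert auto_select_recorded_variables(once).recorded_variables == once.recorded_variables

    def test_unresolved_model_is_an_error(self, toy_connectome):
        config = NetworkConfiguration(connectome=toy_connectome)
        with pytest.raises(ConfigError, match="resolves to no model"):
            auto_select_recorded_variables(config)

    def test_empty_network_gives_empty_recording_set(self, iaf_cell):
        empty = load_connectome("name\tclass\tcategory\tx\ty\tz\n",
                                "pre\tpost\tkind\n")
        config = NetworkConfiguration(connectome=empty, default_model=iaf_cell)
        assert auto_select_recorded_variables(config).recorded_variables == ()


class TestNetworkExport:
    def test_round_trip_preserves_edges_and_overrides(
        self, toy_connectome, iaf_cell, exc_synapse, gap_junction
    ):
        config = NetworkConfiguration(connectome=toy_connectome, default_model=iaf_cell)
        config = override_parameters(config, "AVAL", {"thresh": (-42.0, "mV")})
        config = assign_synapses(config, SynapseSelector(kind="chemical"), exc_synapse)
        config = assign_synapses(config, SynapseSelector(kind="gap_junction"), gap_junction)
        config = auto_select_recorded_variables(config)
        text = export_network(config)
        model = import_network(text)
        assert set(model.cell_of) == set(toy_connectome.names())
        expected_edges = sorted(
            (c.pre, c.post, c.kind, c.multiplicity if c.kind == "chemical" else 1)
            for c in toy_connectome.connections
        )
        assert sorted(model.edge_multiset()) == expected_edges
        aval = model.components[model.cell_of["AVAL"]]
        assert aval.bindings["thresh"][0] == -42.0

    def test_export_is_deterministic(self, toy_connectome, iaf_cell, exc_synapse, gap_junction):
        def build():
            config = NetworkConfiguration(connectome=toy_connectome, default_model=iaf_cell)
            config = assign_synapses(config, SynapseSelector(kind="chemical"), exc_synapse)
            config = assign_synapses(config, SynapseSelector(kind="gap_junction"), gap_junction)
            return export_network(auto_select_recorded_variables(config))

        assert build() == build()

    def test_topology_is_never_mutated(self, toy_connectome, iaf_cell):
        before = (toy_connectome.neurons, toy_connectome.connections)
        config = NetworkConfiguration(connectome=toy_connectome, default_model=iaf_cell)
        override_parameters(config, "AVAL", {"thresh": (-40.0, "mV")})
        assert (toy_connectome.neurons, toy_connectome.connections) == before


class TestPostsynapticPartners:
    def test_toy_fan_out(self):
        neurons = "name\tclass\tcategory\tx\ty\tz\n" + "".join(
            f"{n}\t{n}\tinter\t0\t0\t0\n" for n in "ABC")
        conns = ("pre\tpost\tkind\nA\tB\tchemical\nA\tC\tchemical\n")
        connectome = load_connectome(neurons, conns)
        assert postsynaptic_partners(connectome, "A") == {"B", "C"}
        assert postsynaptic_partners(connectome, "B") == set()

    def test_gap_junction_neighbors_reported_separately(self, toy_connectome):
        assert postsynaptic_partners(toy_connectome, "AVDL") == {"AVAL"}
        assert gap_junction_neighbors(toy_connectome, "AVDL") == {"AVDR"}
        assert gap_junction_neighbors(toy_connectome, "AVDR") == {"AVDL"}

    def test_unknown_neuron_raises(self, toy_connectome):
        with pytest.raises(ConnectomeError, match="unknown neuron"):
            postsynaptic_partners(toy_connectome, "NOPE")

    def test_matches_brute_force_adjacency_scan_on_random_graphs(self):
        rng = random.Random(777)
        for _ in range(30):
            n = rng.randint(3, 15)
            names = [f"N{i}" for i in range(n)]
            neurons = "name\tclass\tcategory\tx\ty\tz\n" + "".join(
                f"{name}\t{name}\tinter\t0\t0\t0\n" for name in names)
            edges = set()
            while len(edges) < rng.randint(0, 3 * n):
                edges.add((rng.choice(names), rng.choice(names), rng.random() < 0.25))
            lines = ["pre\tpost\tkind"]
            seen_pairs = set()
            adjacency: dict[str, set] = {name: set() for name in names}
            for pre, post, is_gap in edges:
                if is_gap:
                    pair = frozenset((pre, post))
                    if pre == post or pair in seen_pairs:
                        continue
                    seen_pairs.add(pair)
                    lines.append(f"{pre}\t{post}\tgap_junction")
                else:
                    lines.append(f"{pre}\t{post}\tchemical")
                    adjacency[pre].add(post)
            connectome = load_connectome(neurons, "\n".join(lines) + "\n")
            for name in names:
                assert postsynaptic_partners(connectome, name) == adjacency[name]


class TestSelectionModes:
    def test_operations_rejected_outside_their_mode(self, toy_connectome, iaf_cell, exc_synapse):
        session = SelectionSession(NetworkConfiguration(connectome=toy_connectome))
        session.assign_models(NeuronSelector(), iaf_cell)  # allowed in default mode
        with pytest.raises(ConfigError, match="synapse_selection"):
            session.assign_synapses(SynapseSelector(kind="chemical"), exc_synapse)
        session.set_mode(SelectionMode.SYNAPSE_SELECTION)
        session.assign_synapses(SynapseSelector(kind="chemical"), exc_synapse)
        with pytest.raises(ConfigError, match="neuron_parameter"):
            session.override_parameters("AVAL", {"thresh": (-45.0, "mV")})
        session.set_mode(SelectionMode.NEURON_PARAMETER)
        session.override_parameters("AVAL", {"thresh": (-45.0, "mV")})
        assert session.config.resolve_model("AVAL").bindings["thresh"][0] == -45.0
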