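import pytest

from nemasim.lems import Link, compose_model, core_type, instantiate
from nemasim.network import load_connectome

TOY_NEURONS = """\
name	class	category	x	y	z
ALML	ALM	sensory	0	0	0
ALMR	ALM	sensory	0	1	0
AVDL	AVD	inter	0	2	0
AVDR	AVD	inter	0	3	0
AVAL	AVA	inter	0	4	0
DA1	DA	motor	0	5	0
"""

TOY_CONNECTIONS = """\
pre	post	kind	multiplicity	neurotransmitter
ALML	AVDL	chemical	3	glutamate
ALMR	AVDR	chemical	3	glutamate
AVDL	AVAL	chemical	2	GABA
AVDR	AVAL	chemical	2	glutamate
AVAL	DA1	chemical	4	acetylcholine
AVDL	AVDR	gap_junction	1	none
"""

IAF_BINDINGS = {
    "C": "1 nF", "gLeak": "50 nS", "eLeak": "-65 mV",
    "thresh": "-50 mV", "reset": "-65 mV",
}

IZH_BINDINGS = {
    "C": "100 pF", "k": "0.7 nS_per_mV", "vr": "-60 mV", "vt": "-40 mV",
    "vpeak": "35 mV", "c": "-50 mV", "a": "0.03 per_ms", "b": "-2 nS",
    "d": "100 pA",
}


@pytest.fixture
def toy_connectome():
    return load_connectome(TOY_NEURONS, TOY_CONNECTIONS)


@pytest.fixture
def iaf_cell():
    return instantiate(core_type("iafCell"), IAF_BINDINGS, id="cell")


@pytest.fixture
def izh_cell():
    return instantiate(core_type("izhikevichCell"), IZH_BINDINGS, id="izh")


@pytest.fixture
def exc_synapse():
    return instantiate(
        core_type("expOneSynapse"),
        {"gbase": "1 nS", "erev": "0 mV", "tauDecay": "10 ms"},
        id="exc",
    )


@pytest.fixture
def gap_junction():
    return instantiate(core_type("gapJunction"), {"conductance": "0.5 nS"}, id="gj")


def driven_iaf(amplitude_na: float, iaf_bindings=None):
    """A leaky integrate-and-fire cell with a constant current source."""
    cell = instantiate(core_type("iafCell"), iaf_bindings or IAF_BINDINGS, id="cell")
    gen = instantiate(core_type("constantCurrent"),
                      {"amplitude": f"{amplitude_na} nA"}, id="gen")
    return compose_model([cell, gen], [Link("gen", "i", "cell", "iSyn")], root="cell")
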