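"""Viewer highlight sets: selected neuron (green) and its postsynaptic
partners (yellow)."""

from __future__ import annotations

from ..network.connectome import Connectome, postsynaptic_partners

__all__ = ["highlight_sets"]


def highlight_sets(connectome: Connectome, selected: str) -> dict[str, set[str]]:
    """``{"selected": {...}, "postsynaptic": {...}}`` for one chosen neuron.

    The selected neuron appears in the postsynaptic set only if it synapses
    onto itself (an autapse).
    """
    partners = postsynaptic_partners(connectome, selected)
    return {"selected": {selected}, "postsynaptic": partners}
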