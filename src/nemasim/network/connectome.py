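"""Fixed-topology connectome: neuron roster plus chemical/electrical wiring.

The topology is immutable by design — configuration only annotates it with
model assignments.  The packaged fixture carries the canonical 302 neuron
names of the adult hermaphrodite; its connection table is synthetic wiring
(see the table headers and the methods note) sufficient for exercising every
pipeline stage.  Gap junctions are stored once per unordered pair.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from io import StringIO
from pathlib import Path

import networkx as nx
import pandas as pd

__all__ = [
    "ConnectomeError",
    "Neuron",
    "Connection",
    "Connectome",
    "load_connectome",
    "packaged_connectome",
    "postsynaptic_partners",
    "gap_junction_neighbors",
]

CATEGORIES = ("sensory", "inter", "motor")
KINDS = ("chemical", "gap_junction")


class ConnectomeError(ValueError):
    pass


@dataclass(frozen=True)
class Neuron:
    name: str
    neuron_class: str
    category: str  # sensory | inter | motor
    position: tuple[float, float, float]  # soma x,y,z in μm; annotation only
    wormbase_url: str | None = None  # opaque cross-reference


@dataclass(frozen=True)
class Connection:
    pre: str
    post: str
    kind: str  # chemical | gap_junction
    multiplicity: int = 1
    neurotransmitter: str = "unknown"


@dataclass(frozen=True)
class Connectome:
    neurons: tuple[Neuron, ...]
    connections: tuple[Connection, ...]

    def __post_init__(self):
        names = [n.name for n in self.neurons]
        if len(names) != len(set(names)):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise ConnectomeError(f"duplicate neuron name(s): {dup}")
        known = set(names)
        for c in self.connections:
            for endpoint in (c.pre, c.post):
                if endpoint not in known:
                    raise ConnectomeError(
                        f"dangling endpoint {endpoint!r} in connection {c.pre}->{c.post}"
                    )
            if c.kind not in KINDS:
                raise ConnectomeError(f"unknown connection kind {c.kind!r}")

    def neuron(self, name: str) -> Neuron:
        for n in self.neurons:
            if n.name == name:
                return n
        raise ConnectomeError(f"unknown neuron {name!r}")

    def names(self) -> list[str]:
        return [n.name for n in self.neurons]

    def graph(self) -> nx.MultiDiGraph:
        """Directed multigraph: chemical edges directed, gap junctions as two
        directed edges (one symmetric record expands on traversal)."""
        g = nx.MultiDiGraph()
        for n in self.neurons:
            g.add_node(n.name, category=n.category, neuron_class=n.neuron_class)
        for c in self.connections:
            g.add_edge(c.pre, c.post, kind=c.kind,
                       multiplicity=c.multiplicity, neurotransmitter=c.neurotransmitter)
            if c.kind == "gap_junction":
                g.add_edge(c.post, c.pre, kind=c.kind,
                           multiplicity=c.multiplicity, neurotransmitter=c.neurotransmitter)
        return g


def _read_table(source) -> pd.DataFrame:
    if isinstance(source, (str, Path)) and "\t" not in str(source) and "\n" not in str(source):
        return pd.read_csv(source, sep="\t", comment="#")
    return pd.read_csv(StringIO(str(source)), sep="\t", comment="#")


def load_connectome(neuron_table, connection_table) -> Connectome:
    """Build a validated Connectome from two delimited tables.

    Each argument is a path or raw TSV text.  The neuron table needs columns
    ``name, class, category, x, y, z``; the connection table needs
    ``pre, post, kind, multiplicity, neurotransmitter``.
    """
    ndf = _read_table(neuron_table)
    required = {"name", "class", "category", "x", "y", "z"}
    if not required <= set(ndf.columns):
        raise ConnectomeError(f"neuron table missing columns {sorted(required - set(ndf.columns))}")
    neurons = []
    for row in ndf.to_dict("records"):
        if row["category"] not in CATEGORIES:
            raise ConnectomeError(
                f"neuron {row['name']!r}: unknown category {row['category']!r}"
            )
        neurons.append(
            Neuron(
                name=str(row["name"]),
                neuron_class=str(row["class"]),
                category=str(row["category"]),
                position=(float(row["x"]), float(row["y"]), float(row["z"])),
            )
        )
    cdf = _read_table(connection_table)
    required = {"pre", "post", "kind"}
    if not required <= set(cdf.columns):
        raise ConnectomeError(f"connection table missing columns {sorted(required - set(cdf.columns))}")
    seen_gap_pairs: set[frozenset] = set()
    connections = []
    for row in cdf.to_dict("records"):
        kind = str(row["kind"])
        if kind == "gap_junction":
            pair = frozenset((str(row["pre"]), str(row["post"])))
            if pair in seen_gap_pairs:
                raise ConnectomeError(
                    f"gap junction {set(pair)} listed more than once (store one record per pair)"
                )
            seen_gap_pairs.add(pair)
        connections.append(
            Connection(
                pre=str(row["pre"]),
                post=str(row["post"]),
                kind=kind,
                multiplicity=int(row.get("multiplicity", 1)),
                neurotransmitter=str(row.get("neurotransmitter", "unknown")),
            )
        )
    return Connectome(tuple(neurons), tuple(connections))


def packaged_connectome() -> Connectome:
    """Load the packaged 302-neuron fixture."""
    data = importlib.resources.files("nemasim.network") / "data"
    return load_connectome(
        str(data / "neurons.tsv"), str(data / "connections_synthetic.tsv")
    )


def postsynaptic_partners(connectome: Connectome, neuron: str) -> set[str]:
    """Post endpoints of chemical connections with ``pre == neuron``.

    This is the set a viewer highlights in yellow when the given neuron is
    selected (the selected neuron itself shown in green); electrical
    neighbors are reported separately by :func:`gap_junction_neighbors`.
    """
    connectome.neuron(neuron)  # raises on unknown name
    return {c.post for c in connectome.connections if c.kind == "chemical" and c.pre == neuron}


def gap_junction_neighbors(connectome: Connectome, neuron: str) -> set[str]:
    """Electrical-coupling partners of ``neuron`` (symmetric records)."""
    connectome.neuron(neuron)
    out = set()
    for c in connectome.connections:
        if c.kind != "gap_junction":
            continue
        if c.pre == neuron:
            out.add(c.post)
        elif c.post == neuron:
            out.add(c.pre)
    return out
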