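"""Regenerate the packaged connectome fixture tables.

``neurons.tsv`` carries the canonical 302 adult-hermaphrodite neuron names,
their class and sensory/inter/motor category (standard nomenclature from the
public wiring literature).  Soma positions are synthetic placeholders laid
out along the anterior-posterior axis; they are annotation only and never
enter any simulation.

``connections_synthetic.tsv`` is SYNTHETIC wiring: a deterministic, seeded
random graph over the real neuron names with a hardcoded mechanosensory core
(touch receptor neurons onto the forward/backward command interneurons).  It
stands in for the published wiring matrix, which is not redistributable from
memory; only the neuron count and the table schema are treated as ground
truth by the package.

Run from the repository root:  python scripts/make_connectome_fixture.py
"""

from __future__ import annotations

import random
from pathlib import Path

OUT = Path(__file__).resolve().parent.parent / "src" / "nemasim" / "network" / "data"

# class -> (members spec, category); "LR" expands to L/R pair, "1-n" to a range
PAIRS_SENSORY = [
    "ADE", "ADF", "ADL", "AFD", "ALM", "ALN", "ASE", "ASG", "ASH", "ASI",
    "ASJ", "ASK", "AWA", "AWB", "AWC", "BAG", "CEPD", "CEPV", "FLP", "IL2D",
    "IL2", "IL2V", "OLL", "OLQD", "OLQV", "PDE", "PHA", "PHB", "PHC", "PLM",
    "PLN", "PVD", "SDQ", "URB", "URX", "URYD", "URYV",
]
PAIRS_INTER = [
    "ADA", "AIA", "AIB", "AIM", "AIN", "AIY", "AIZ", "AUA", "AVA", "AVB",
    "AVD", "AVE", "AVF", "AVH", "AVJ", "AVK", "BDU", "CAN", "LUA", "PVC",
    "PVN", "PVP", "PVQ", "PVW", "RIA", "RIB", "RIC", "RIF", "RIG", "RIM",
    "RIP", "RIV", "SAAD", "SAAV", "SIAD", "SIAV", "SIBD", "SIBV",
]
PAIRS_MOTOR = [
    "HSN", "IL1D", "IL1", "IL1V", "RMD", "RMDD", "RMDV", "RME", "RMF", "RMG",
    "RMH", "SABV", "SMBD", "SMBV", "SMDD", "SMDV", "URAD", "URAV",
    # pharyngeal paired
    "I1", "I2", "M2", "M3", "MC", "NSM",
]
SINGLES = {
    # name: category
    "ALA": "inter", "AQR": "sensory", "AVG": "inter", "AVL": "motor",
    "AVM": "sensory", "DVA": "inter", "DVB": "motor", "DVC": "inter",
    "I3": "inter", "I4": "inter", "I5": "inter", "I6": "inter",
    "M1": "motor", "M4": "motor", "M5": "motor", "MI": "motor",
    "PDA": "motor", "PDB": "motor", "PQR": "sensory", "PVM": "sensory",
    "PVR": "inter", "PVT": "inter", "RID": "inter", "RIH": "inter",
    "RIR": "inter", "RIS": "inter", "RMED": "motor", "RMEV": "motor",
    "SABD": "motor",
}
VC_CLASSES = [  # ventral-cord motor neuron classes: (class, count)
    ("AS", 11), ("DA", 9), ("DB", 7), ("DD", 6),
    ("VA", 12), ("VB", 11), ("VC", 6), ("VD", 13),
]

# curated mechanosensory core: six touch receptor neurons onto the
# backward (AVA/AVD) and forward (AVB/PVC) command interneurons
TOUCH_CORE = [
    ("ALML", "AVDL"), ("ALML", "AVDR"), ("ALMR", "AVDR"), ("ALMR", "AVDL"),
    ("AVM", "AVDL"), ("AVM", "AVDR"), ("AVM", "AVBL"), ("AVM", "AVBR"),
    ("PLML", "PVCL"), ("PLML", "PVCR"), ("PLMR", "PVCR"), ("PLMR", "PVCL"),
    ("PVM", "AVAL"), ("PVM", "AVAR"),
    ("AVDL", "AVAL"), ("AVDR", "AVAR"), ("PVCL", "AVBL"), ("PVCR", "AVBR"),
]

NT = ["glutamate", "acetylcholine", "GABA", "dopamine", "serotonin", "unknown"]
NT_W = [0.30, 0.35, 0.12, 0.06, 0.05, 0.12]


def build_neurons() -> list[tuple[str, str, str]]:
    rows = []
    for cls_list, cat in ((PAIRS_SENSORY, "sensory"), (PAIRS_INTER, "inter"),
                          (PAIRS_MOTOR, "motor")):
        for cls in cls_list:
            rows.append((cls + "L", cls, cat))
            rows.append((cls + "R", cls, cat))
    for name, cat in SINGLES.items():
        rows.append((name, name, cat))
    for cls, count in VC_CLASSES:
        for i in range(1, count + 1):
            rows.append((f"{cls}{i:02d}" if False else f"{cls}{i}", cls, "motor"))
    rows.sort()
    assert len(rows) == 302, len(rows)
    assert len({r[0] for r in rows}) == 302
    return rows


def main() -> None:
    rng = random.Random(302302)
    neurons = build_neurons()
    OUT.mkdir(parents=True, exist_ok=True)

    with open(OUT / "neurons.tsv", "w") as fh:
        fh.write("# Adult hermaphrodite neuron roster (canonical 302 names);\n")
        fh.write("# soma positions are SYNTHETIC placeholders, micrometres.\n")
        fh.write("name\tclass\tcategory\tx\ty\tz\n")
        for i, (name, cls, cat) in enumerate(neurons):
            # synthetic layout: most somata packed anteriorly, tail cluster
            frac = i / len(neurons)
            x = round(rng.gauss(0.0, 12.0), 1)
            y = round(rng.gauss(0.0, 12.0), 1)
            z = round(1000.0 * (0.08 + 0.84 * frac) + rng.gauss(0.0, 20.0), 1)
            fh.write(f"{name}\t{cls}\t{cat}\t{x}\t{y}\t{z}\n")

    names = [n for n, _, _ in neurons]
    by_cat: dict[str, list[str]] = {"sensory": [], "inter": [], "motor": []}
    for name, _, cat in neurons:
        by_cat[cat].append(name)

    chem: dict[tuple[str, str], tuple[int, str]] = {}
    gaps: set[tuple[str, str]] = set()
    for pre, post in TOUCH_CORE:
        chem[(pre, post)] = (rng.randint(2, 8), "glutamate")
    for name, _, cat in neurons:
        # feed-forward bias: sensory -> inter, inter -> inter/motor, motor -> motor
        pools = {
            "sensory": by_cat["inter"] * 3 + by_cat["sensory"],
            "inter": by_cat["inter"] + by_cat["motor"] * 2,
            "motor": by_cat["motor"] * 3 + by_cat["inter"],
        }[cat]
        for _ in range(rng.randint(2, 5)):
            post = rng.choice(pools)
            if post == name or (name, post) in chem:
                continue
            chem[(name, post)] = (rng.randint(1, 6),
                                  rng.choices(NT, weights=NT_W, k=1)[0])
        if rng.random() < 0.6:  # gap junctions stored once per unordered pair
            peer = rng.choice(names)
            if peer != name:
                gaps.add(tuple(sorted((name, peer))))

    with open(OUT / "connections_synthetic.tsv", "w") as fh:
        fh.write("# SYNTHETIC wiring over the canonical neuron roster:\n")
        fh.write("# deterministic seeded graph + curated mechanosensory core.\n")
        fh.write("# gap junctions appear once per unordered pair.\n")
        fh.write("pre\tpost\tkind\tmultiplicity\tneurotransmitter\n")
        for (pre, post), (mult, nt) in sorted(chem.items()):
            fh.write(f"{pre}\t{post}\tchemical\t{mult}\t{nt}\n")
        for a, b in sorted(gaps):
            fh.write(f"{a}\t{b}\tgap_junction\t1\tnone\n")
    print(f"wrote {len(neurons)} neurons, {len(chem)} chemical, {len(gaps)} gap junctions")


if __name__ == "__main__":
    main()
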