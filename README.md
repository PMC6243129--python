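# nemasim

A headless Python toolkit for defining, encoding and executing *C. elegans*
behavioral-experiment simulations. It covers the full desk-scale pipeline
that a web-based worm-simulation platform needs behind its GUIs:

1. **Behavioral experiment encoding** — an XML dialect for duration-based
   stimulus timelines. Every event is one of three categories
   (`interactionAtSpecificTime`, `interactionFromt0tot1`,
   `experimentWideConf`) and one of five taxis modalities (mechanotaxis,
   chemotaxis, thermotaxis, galvanotaxis, phototaxis), plus a full
   environment block (worm data, plate, obstacles, crowding). A shipped XSD
   freezes the dialect.
2. **LEMS-style model building** — `ComponentType` dynamics templates
   (state variables, derived variables, time derivatives, event rules) kept
   strictly separate from parameterized `Component` instances, with
   dimensional checking over the seven SI base quantities, a core library
   (leaky integrate-and-fire, Izhikevich, HH-style rate gates, synapses,
   gap junctions, current generators), and LEMS XML export/import.
3. **Connectome network configuration** — the fixed 302-neuron
   adult-hermaphrodite topology with ordered selector rules for assigning
   cell and synapse models (later assignments win), per-neuron parameter
   overrides, automatic recorded-variable selection, and self-contained
   NeuroML/LEMS-style network export.
4. **Reference interpreter** — flattens exported models/networks into an
   ordered update system and integrates them (forward Euler by default,
   RK4 as a cross-check), with deterministic event semantics and a
   pluggable transduction map turning timeline stimuli into current
   injections (default: touch onto the six classical touch receptor
   neurons).
5. **Results I/O** — spreadsheet (CSV) trace export, JSON-lines locomotion
   recordings (midline + the 95 body-wall muscle activations), a manifest
   tying both to one clock, timeline slicing, viewer highlight sets, and a
   seeded synthetic-results generator standing in for a body-physics
   engine.

The core closed form used to validate the interpreter is the leaky
integrate-and-fire inter-spike interval under constant drive *I*:

    T = τ ln( RI / (RI − V_θ) ),   τ = C/g_L,  R = 1/g_L,  V_θ = V_thresh − V_reset

## Worked example

The packaged document `fixtures/worked_example.xml` encodes a 60 s assay on
a 1-day-old L1 hermaphrodite, 1 h without food, on a cylindrical plate
(radius 50 mm, border height 15 mm, agar substrate, no lid) with one
cylindrical obstacle (height 5 mm, radius 5 mm, stiffness 43.2 N/m), a
galvanotaxis interval, an instant touch and an experiment-wide osmotic
ring:

```sh
$ nemasim validate-experiment fixtures/worked_example.xml
fixtures/worked_example.xml: valid (3 events)
```

A complete demo pipeline on the full packaged connectome (integrate-and-fire
cells everywhere, excitatory exponential synapses, 0.5 nS gap junctions):

```sh
$ nemasim new-experiment --seed 1 --events 6 --duration 300 --out exp.xml
$ nemasim configure-network --preset iaf --out cfg.json
$ nemasim export-network --config cfg.json --out net.xml
$ nemasim simulate --network net.xml --experiment exp.xml \
      --dt 0.5 --duration 100 --out results/
simulated 100.0 ms at dt=0.5 ms: 302 traces, 21 spikes -> results/
```

The generated experiment contains a direct-touch event; its transduced
current pulse drives the touch receptor neurons, whose spikes propagate
through the synaptic graph — hence the nonzero spike count.

`results/` then holds `traces.csv` (one column per recorded neuron
variable), `locomotion.jsonl` (one frame per line: timestamp, 33-point
midline, 95 muscle activations) and `manifest.json` binding them to a
common clock. `nemasim slice-results --manifest results/manifest.json
--t0 0 --t1 100 --out sliced/` extracts a window; `nemasim neuron-info
AVAL` prints a neuron's class, category, soma position and postsynaptic
partners.

In the Python API the same pipeline is ~15 lines; see the test suite for
executable examples of every operation.

## Repository layout

```
src/nemasim/
  experiment/   XML dialect, XSD, validation, timeline algebra, generator
  lems/         ComponentType/Component system, core library, LEMS XML
  network/      connectome tables, configuration, network export
  runtime/      flattening, Euler/RK4 integration, transduction
  results/      CSV/JSONL/manifest I/O, slicing, synthetic generator
  cli.py        the `nemasim` command
fixtures/       worked-example XML, hand-written Izhikevich LEMS model
docs/methods.md model and design notes
```

The packaged connectome neuron roster uses the canonical 302 neuron names;
its wiring table is synthetic (see `docs/methods.md` for provenance and
what that does and does not validate).
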