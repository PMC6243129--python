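# Methods and design notes

## Scope and model

`nemasim` implements the experiment-definition half of a worm-simulation
platform as a headless library: encoding behavioral assays, assembling
declarative point-neuron models, configuring the fixed *C. elegans*
connectome, executing the result with a reference interpreter, and handling
the produced data. Body physics, sensory biophysics, GUI rendering and
hardware backends are explicitly out of scope; where the pipeline needs
their outputs (locomotion, transduced receptor currents) it uses documented
stand-ins.

## Behavioral experiment encoding

Every stimulus event belongs to exactly one duration-based category —
instant (`interactionAtSpecificTime`), interval (`interactionFromt0tot1`),
or experiment-wide (`experimentWideConf`) — and one of five taxis
modalities. Units are fixed: times in ms, geometry in mm, angles in
degrees, touch force in μN (no established unit exists for eyelash-touch
force at this abstraction level; μN is the natural scale), currents in nA.
Decisions where the format was genuinely open:

- **Interval activity is half-open [t0, t1)** so abutting intervals never
  overlap and slice concatenation is exact.
- **Instant-event tolerance defaults to 0 ms** (strict equality) and is a
  query parameter, since nothing in the format itself fixes a sampling
  tolerance.
- **Instant touch duration**: a `DirectTouch` carries its own
  `contact_duration`; an instant touch event is transduced over
  [t, t + contact_duration).
- **Obstacle placement** is stored as the (distance-to-X-axis,
  distance-to-Y-axis, angle) triple of the document format and converted to
  a plate-centered coordinate on access.
- **Crowding distribution indices are opaque**: the predefined placement
  formulae they name are a simulator concern, so the index is carried and
  range-checked only.
- Phototaxis intensity and plate-tap intensity have no standard unit; both
  are "arbitrary units" by declaration.

Validation is total (violations are returned as data, never raised), and
the writer is canonical: events sorted by (start time, insertion order),
`%.12g` number formatting, byte-identical repeated writes.

## Model building blocks

A `ComponentType` holds dynamics (state variables, derived variables, time
derivatives, on-start assignments, edge-triggered conditions, event
handlers, event ports, exposures, requirements); a `Component` binds its
parameters once, with units. Dimensional analysis uses integer exponent
vectors over the seven SI base quantities; the unit table is a fixed set of
power-of-ten scalings (ms, mV, nA, nS, pF, …), which covers every unit a
point-neuron library needs. Dimension checking enforces d(state)/dt =
dim(state)/time and well-dimensioned assignments and predicates.

The expression language is intentionally small — arithmetic, `exp`, `log`,
`sqrt`, `abs`, and (in predicates only) comparisons joined by `and` —
which is sufficient for the threshold/reset rules of the shipped models.
Name resolution is lexical within a type; shadowing is an error.

The core library ships: leaky integrate-and-fire, the dimensional (2007)
Izhikevich formulation (`C dv/dt = k(v−vr)(v−vt) − u + i`,
`du/dt = a(b(v−vr) − u)`, peak-and-reset at `vpeak`), a two-rate HH-style
gating particle with exponential voltage-dependent rates (so the clamped
steady state is α/(α+β), used as a closed-form test), an ohmic single-gate
channel, pulse and constant current generators, a single-exponential
conductance synapse, and a linear gap junction. Kinetic schemes,
structure/for-each templates, and multi-compartment morphology are outside
the implemented LEMS subset and are rejected on import with an
unsupported-construct error rather than silently dropped.

## Connectome fixture and provenance

The packaged neuron table carries the canonical 302 adult-hermaphrodite
neuron names and classes with a sensory/inter/motor category per class
(standard nomenclature from the public wiring literature). Two caveats,
both marked in the files themselves:

- **Soma positions are synthetic placeholders.** Positions serve selection
  and reporting only and never enter simulation.
- **The connection table is synthetic wiring**
  (`connections_synthetic.tsv`): a deterministic seeded graph over the real
  neuron names with a curated mechanosensory core (touch receptors onto the
  AVA/AVB/AVD/PVC command interneurons), generated by
  `scripts/make_connectome_fixture.py`. The published wiring matrix is not
  redistributable from memory; consequently tests validate *pipeline
  behavior* (loading, selection, export, simulation) on this topology, not
  biological connectivity claims.

Gap junctions are stored once per unordered pair and expanded to two
directed conductance terms at flatten time. Topology is immutable;
configuration is an annotation layer (ordered last-wins selector rules,
matching a default-then-customize workflow). Recorded variables are
auto-selected as the membrane-potential exposure plus all state variables
of each neuron's resolved model — the natural "everything the model can
show" rule, chosen because no finer specification exists; users can edit
the list afterwards.

## Reference interpreter

Flattening produces per-instance SI parameter tables, a global
lexicographic topological order over derived variables (cross-component
requirement edges included; cycles are an error), and event routes.
Current-type requirements are *summing*: every attached synapse, junction
half and injection contributes, and an unattached current requirement
defaults to zero so isolated cells run. All other requirements must be
wired exactly.

Integration is forward Euler with dt defaulting to 0.05 ms — matching the
fixed-step update rules hardware implementations use — with classical RK4
available as a cross-check for smooth dynamics (it is not used when event
accuracy matters, since resets are discontinuous). Event semantics, chosen
for determinism:

- predicates are edge-triggered (fire on false→true) and tested after each
  state update, in instance-name order;
- a condition already true at t = 0 fires before the first step;
- reset assignments apply before event delivery within the same step;
- simultaneous events are delivered in name order.

Verified properties: the integrate-and-fire inter-spike interval matches
T = τ ln(RI/(RI−V_θ)) within 2 % at dt = 0.01 ms (measured ~0.001 %);
subthreshold trajectories converge at first order in dt; identically
driven gap-coupled twins stay bit-identical; an exported model re-imported
from XML reproduces identical spike times. Non-finite state aborts the run
with the offending instance and time.

## Transduction

The transduction map is the pluggable seam between behavioral events and
neuron input. The default map covers mechanosensation only: direct touch
injects a constant current pulse into the anterior (ALML/R, AVM) or
posterior (PLML/R, PVM) touch receptor triad according to body position
(split at mid-body), and plate tap into all six. Gains are **placeholders**
— 0.1 nA/μN for touch, 0.5 nA per tap-intensity unit — set to drive the
default cells near threshold at physiological-feeling forces; nothing at
this abstraction level fixes them, and quantitative work must calibrate
them. All other modalities are labelled no-ops until the user supplies
rules. Injection magnitude is linear in stimulus magnitude by construction.

## Results model and the synthetic generator

Traces are CSV (a JSON metadata comment line, then `time_ms` plus one
column per neuron-variable, `%.12g`), which makes write→read→write
byte-stable. Locomotion is JSON-lines, one frame per line: timestamp,
33-point midline (a point-set midline, not a mesh — skinning is a viewer
concern), and the 95 body-wall muscle activations in a fixed anatomical
channel order (four quadrants interleaved head-to-tail; the ventral-left
column has 23 cells). A JSON manifest ties both files to one clock; the
reconciliation invariant is that every frame timestamp lands within dt/2
of a trace grid point after offset correction.

The synthetic generator stands in for the body-physics engine so the
results pipeline is fully exercisable. Traces are noisy leaky integrators
with threshold resets (spiking-like structure, membrane-scale values);
locomotion is a traveling-wave undulation (wavelength 1.5 body lengths,
period 1.6 s, amplitude 0.12 mm — typical crawling-gait scales) with
dorsal/ventral muscle rows in antiphase along the same wave. Everything is
seeded and bit-deterministic. What passing tests show: format, clocking,
determinism, slicing algebra and invariant preservation. What they do not
show: anything about real neural dynamics or real locomotion — the
generator's statistics are plausible, not fitted.

Slicing is half-open and re-zeroes the clock, making it a monoid action
(`slice(slice(x, a, b), c, d) = slice(x, a+c, a+d)`); a recording's
duration is defined as `last_sample + dt` (exclusive end) so the full
slice is the identity and abutting slices concatenate exactly.

## Problem sizes in the shipped tests

The suites run the interpreter on single cells and 2–8-neuron networks at
dt = 0.01–0.1 ms over 50–300 ms, the oracles on 1000 randomized timelines
and 50 random graphs, and the generators at 20–500 ms — sizes chosen so
the whole suite completes in well under a minute while still hitting every
code path; the 302-neuron fixture is exercised for loading, configuration,
export and counting invariants rather than long simulations.

## Known limitations

- The LEMS subset is flat: no child component hierarchies, kinetic schemes
  or morphologies.
- The interpreter is a clarity-first reference (per-instance dict
  evaluation); it is not built for long full-connectome runs.
- Synaptic multiplicity scales the postsynaptic current linearly rather
  than instantiating independent release sites.
- `degC` is treated as a label (offsets ignored); temperature never enters
  the shipped dynamics.
- The synthetic wiring table means network-level emergent dynamics on the
  packaged fixture are illustrative only.
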