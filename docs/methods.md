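# Methods

## What the package computes

`nrnstim` turns a declarative description of synaptic stimulation — which
mechanisms, how strong, where on the dendritic tree, and when — into the
complete file set a NEURON simulation needs: a hoc morphology, hoc and
Python drivers, and per-module data tables. A small passive cable
simulator is bundled so that generated ensembles can be sanity-checked
against cable theory without installing NEURON.

## Morphology model

An SWC reconstruction is a list of points `(id, type, x, y, z, radius,
parent)` with type codes 1 = soma, 2 = axon, 3 = basal dendrite,
4 = apical dendrite. NEURON cells are built from line *sections*; here
each point together with its parent defines one section, and sections are
grouped into 0-based per-compartment arrays (`soma[0..]`, `apical[0..]`,
...) in file order. Points with a type code outside {1, 2, 3, 4} are kept
in the point list but flagged in `Morphology.warnings` and receive no
section; likewise non-positive radii are flagged. Structural defects
(duplicate ids, parents that do not precede their children) are hard
errors. No repair, resampling or smoothing of the reconstruction is
attempted.

Geometry conventions:

* **Section length** is the planar (x, y) Euclidean distance between the
  point and its parent by default; `use_3d=True` includes z. Both modes
  are exposed because point-based reconstructions are conventionally
  measured in the projection plane of the acquisition, while 3D length is
  the physically complete choice; neither is privileged, the default is
  the planar one.
* **Diameter** is twice the point's radius (SWC stores radius; NEURON
  sections need a diameter).
* **Root sections** (parent −1) have no chord to measure; they use the
  sphere-equivalent convention `L = diam = 2·radius`, which preserves the
  soma's membrane area scale.
* **Zero-length sections** (planar-coincident points) are emitted with an
  epsilon length of 0.01 µm and a warning, so the hoc output stays valid.
* **Distances between sections** (used for input placement) are always
  full 3D distances between the sections' own SWC coordinates — the
  point's coordinate, not the chord midpoint, is the representative point.
* **Branch points** are points whose parent id is non-sequential
  (`parent ≠ id − 1`), the standard property of depth-first-written SWC
  files; the root is excluded by definition.
* **Probe intersection** (`segments_intersecting_line`) tests each
  section's 2D chord against a finite probe segment. Collinear overlap
  counts as a hit; degenerate zero-length chords never hit. These
  tie-break conventions are arbitrary but deterministic.

## Stimulus model

A **module** is one input mechanism:

* `synaptic` — a two-state kinetic synapse whose conductance is a
  difference of exponentials with rise constant τ₁ and decay constant τ₂
  (ms) and reversal potential E (mV); requires 0 < τ₁ < τ₂.
* `istep` — a current step with an amplitude (nA) and duration (ms).
* `custom` — an opaque NMODL payload; the point-process class name is
  read from the `POINT_PROCESS` declaration and nothing else in the file
  is interpreted.

A **tag** groups modules that must share locations and activation times
(e.g. AMPA + NMDA receptors of the same synapse), and carries the input
count, the allowed compartments, the location rule (an anchor segment plus
a distance distribution), and the timing rule (onset plus inter-stimulus
interval distribution). A **session** is the whole experiment: morphology
path, modules, tags, number of runs, master seed.

### Distribution semantics

Each stochastic quantity (weight, anchor distance, inter-stimulus
interval) is governed by a `(kind, mean, sd)` spec:

* `single` — the constant `mean`.
* `multiple_uniform` — the unique symmetric uniform with the requested
  mean and sd, i.e. support `[mean − √3·sd, mean + √3·sd]`. Negative
  draws (possible when `mean < √3·sd`) are resampled rather than clamped,
  so the realized mean is not distorted by a point mass at zero; a hard
  cap of 1000 attempts guards against degenerate specs.
* `multiple_poisson` — the user supplies both a mean and an sd, which a
  plain Poisson cannot honor (its sd is √mean). The default reading is a
  *scaled* Poisson `c·K`, `K ~ Poisson(μ²/σ²)`, `c = σ²/μ`, which matches
  both requested moments and stays non-negative by construction. A
  `poisson_mode="natural"` option draws `Poisson(mean)` and ignores the
  sd, for users who intend the textbook distribution.

### Placement and timing

For a tag with a non-degenerate location rule, every candidate segment in
the allowed compartments is ranked by `|d(anchor, s) − d*|` where `d*` is
the drawn target distance; the argmin wins and ties break uniformly at
random. This nearest-distance selection always terminates (unlike
acceptance sampling on a discrete tree) and recovers the requested mean
distance up to the quantization error of the point spacing. Positions
along sections are fixed at 0.5; the intra-section position is not part
of the stimulus model. Activation times accumulate: `t₀ = onset`,
`tᵢ = tᵢ₋₁ + Δᵢ` with Δᵢ drawn from the interval spec, so `single` with
interval 0 means synchronous activation and interval draws being
non-negative makes time lists non-decreasing by construction.

### Randomness

One master seed per session. Every draw comes from a substream keyed by
`(seed, run_index, crc32(tag name), role, crc32(module name))` through
`numpy`'s `SeedSequence`/PCG64, where role is location, time, or weight.
Consequences: realizations are bit-reproducible; distinct runs are
independent; and editing one tag (or adding a module to it) never
perturbs the draws of any other tag — the stream-substitution property
the tests assert directly.

## Output tree

```
<out>/<YYYYMMDD-HHMMSS>/run-<k>/
    cell.nrn        hoc section arrays, L/diam per section, connect child(0)->parent(1)
    nrnez.hoc       hoc driver (xopen's cell.nrn, reads the .dat files)
    nrnez.py        Python driver (same contract via neuron.h)
    <name>.swc      verbatim copy of the input reconstruction
    <module>.mod    custom NMODL payloads, copied verbatim
    <module>/location.dat   rows: (compartment code 1-4, section index, position)
    <module>/time.dat       rows: (activation time, ms)
    <module>/weight.dat     rows: (weight, µS for synapses, nA for current steps)
```

Every `.dat` file starts with a "rows cols" header that must match the
body — checked on read and on every emitted file in the tests. The `.dat`
column schemas are original to this package. Weights convert from the
user-facing nS to NEURON's µS only at this boundary (1 nS = 10⁻³ µS).
Synapses are realized in the drivers as two-state kinetic point processes
receiving one event each through a `NetStim`/`NetCon` pair whose weight is
the peak conductance; current steps become current clamps with
`del`/`dur`/`amp`. All paths inside a run folder are relative, so folders
are relocatable and each run is self-sufficient. The timestamped root can
be pinned (`timestamp=`/`--pin-timestamp`) to make whole trees
byte-reproducible; name collisions get `-1`, `-2`, ... suffixes.
`nrnivmodl` is *not* invoked by default — the emitted files are the
product and compilation is host-dependent — but `compile_mods=True` /
`--compile` restores it when NEURON is installed.

## Passive cable simulator

`cablesim` discretizes the morphology at one compartment per section (no
sub-section discretization; adequate for the monotonicity and linearity
properties it exists to check). Per compartment, cylinder area
`π·d·L` gives capacitance `cm·area` and leak `area/Rm`; the axial
conductance to the parent is `1/r` with `r = 4·Ra·L/(π·d²)` from the
child section's own geometry. Defaults are conventional passive values —
`cm = 1 µF/cm²`, `Rm = 20 kΩ·cm²`, `Ra = 150 Ω·cm`, leak reversal and
rest −65 mV — all exposed in `PassiveParams` and not claimed to be any
particular published cell's.

The synaptic conductance is `g(t) = w·f·(e^{−t/τ₂} − e^{−t/τ₁})` with `f`
normalizing the peak to `w`; the peak occurs at
`t* = τ₁τ₂/(τ₂−τ₁)·ln(τ₂/τ₁)`.

Integration is backward Euler (unconditionally stable on the stiff tree)
with a direct sparse solve per step; the constant part of the system
matrix is factorized once and re-used whenever no synaptic conductance is
active. The state variable is the *deviation* from the leak reversal, so
the resting state is an exact fixed point of the scheme, not merely a
numerical one (the no-input trace is flat to < 10⁻¹² mV). Accuracy is
checked against the RC closed form (max error < 0.5 % of the step
amplitude at dt = 0.01 ms) and by step-halving convergence. Because
synapses are conductances, not currents, superposition is only
approximate; for subthreshold inputs the error is second-order small and
the tests bound it at 1 % of the response peak.

## Synthetic fixtures

The fixture generator emulates only what the tests need: a ball-and-stick
cable (soma plus a straight apical cable at uniform spacing, so distances
are closed-form), a Y-tree with exactly one non-sequential parent id, and
a seeded random branched tree for brute-force comparisons. None of these
reproduce the statistics of real reconstructions — no taper, no tortuosity,
no realistic branch-order distribution — so passing tests demonstrate the
correctness of the bookkeeping and the samplers, not biological realism.
The session presets encode the published single-input and 100-input test
configurations (AMPA τ₁ = 0.7 ms, τ₂ = 2 ms, E = 0 mV at 1 nS and 7.5 pS;
GABA_A τ₁ = 0.5 ms, τ₂ = 7 ms, E = −75 mV at 330 pS; onset 200 ms;
Poisson placement centered 200 µm from the soma with 50 µm sd, spanning
the 100–300 µm band) against a 300 µm cable at 1 µm spacing, sized so the
200 µm anchor exists and quantization error is below 1 µm.

## Problem sizes

The validation suite uses a 301-compartment cable, 10⁵-draw sampler
checks, and 40–100 ms simulations at dt = 0.01–0.05 ms; the full suite
runs in well under a minute on one CPU, and `scripts/acceptance.py` in a
few seconds. These sizes were chosen as the smallest at which the
statistical assertions (3 standard errors) and the discretization checks
are meaningful.

## Known limitations

* Active conductances, spikes, and firing-rate results are out of scope;
  the cable simulator is a validator for the generator, not a NEURON
  replacement.
* Output files are semantically equivalent to, not byte-compatible with,
  any other generator's; the `.dat` column layout and hoc template are
  original.
* Location distributions are over straight-line (Euclidean) distance, not
  path (geodesic) distance along the tree; there is no clustered or
  correlated placement model.
* Legacy pickle session files are not read; sessions and defaults are
  JSON with a versioned schema.
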