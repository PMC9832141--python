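# nrnstim

Compartmental models in NEURON are only as informative as the synaptic
input patterns driving them, and writing hoc or Python by hand to place
hundreds of stochastic inputs on a reconstructed dendritic tree is
error-prone boilerplate. `nrnstim` is a headless library and CLI that
takes an SWC morphology and a declarative *session* — which mechanisms,
how strong, where, and when — and emits the complete, self-sufficient
file tree a NEURON simulation needs: a hoc morphology (`cell.nrn`),
drivers for both interpreters (`nrnez.hoc`, `nrnez.py`), and per-module
data tables (`location.dat`, `time.dat`, `weight.dat`). It is aimed at
experimentalists and trainees who want stochastic synaptic ensembles
without writing simulator code.

The stochastic core: each quantity (synaptic weight, distance from an
anchor segment, inter-stimulus interval) follows a `(kind, mean μ, sd σ)`
spec — a constant, the symmetric uniform on `[μ − √3σ, μ + √3σ]`, or a
scaled Poisson `c·K`, `K ~ Poisson(μ²/σ²)`, `c = σ²/μ`, matching both
requested moments. Inputs are placed by drawing a target Euclidean
distance from the anchor and selecting the nearest allowed segment;
synapses are two-state kinetic mechanisms `g(t) ∝ e^{−t/τ₂} − e^{−t/τ₁}`
(rise τ₁, decay τ₂, reversal E), peak-normalized so the drawn weight is
the peak conductance. Tags force co-localization (AMPA + NMDA at the same
sites and times), and a per-(run, tag, role) seeded substream scheme makes
every ensemble bit-reproducible. A bundled passive cable simulator
(backward Euler on the section tree) validates generated ensembles
against cable theory — distance-dependent EPSP attenuation, driving-force
asymmetry, subthreshold linearity — without installing NEURON.

## Worked example

```sh
# a 300 µm ball-and-stick morphology, 1 µm point spacing
nrnstim fixture --kind ball_and_stick --n-points 300 --spacing 1 --out cell.swc
nrnstim inspect --swc cell.swc
```

```
soma: 1
axon: 0
basal: 0
apical: 300
branch points: 0
```

Create a session — one 1 nS AMPA synapse (τ₁ = 0.7 ms, τ₂ = 2 ms,
E = 0 mV) at 200 µm along the apical cable, activated at 200 ms — and
generate the NEURON file tree:

```python
from nrnstim import save_session
from nrnstim.fixtures import make_session
open("sess.json", "w").write(save_session(make_session("fig3_single", "cell.swc")))
```

```sh
nrnstim generate --swc cell.swc --session sess.json --out outdir --pin-timestamp demo
ls outdir/demo/run-0
```

```
AMPA  cell.nrn  cell.swc  nrnez.hoc  nrnez.py
```

`AMPA/weight.dat` contains `1 1` then `0.001` — the 1 nS weight in
NEURON's µS. Running the same session on the bundled passive cable:

```sh
nrnstim simulate --swc cell.swc --session sess.json --out trace.csv
```

the somatic trace rests at −65 mV and peaks at **−59.984 mV at
t = 206.68 ms**: a ~5 mV EPSP whose ~7 ms latency-to-peak reflects
passive cable filtering of a 200 µm-distal input. Moving the anchor
closer to the soma makes the EPSP larger and faster, as cable theory
requires.

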