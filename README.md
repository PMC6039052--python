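# spindlenet

A conductance-based network model of sleep-spindle generation in two
interacting thalamocortical systems, with the analysis pipeline needed to
measure spindle statistics from its output: estimated LFPs, an
analytic-signal spindle detector, and ensemble statistics (density, ISI
distributions, spatial correlation, core/matrix co-occurrence, onset
delays, spike phases).

## The scientific problem

Human sleep spindles (11–15 Hz bursts, 0.5–3 s) look different in MEG and
EEG: MEG spindles are frequent and local, EEG spindles rare and globally
synchronous, and EEG spindles almost always co-occur with MEG spindles but
not vice versa.  A proposed explanation is the anatomy of the two
thalamocortical pathways: the **core** system projects focally to middle
layers (L3/4), the **matrix** system diffusely to superficial layers
(apical dendrites of L5 cells), with roughly ten-fold wider fanout.

`spindlenet` implements that hypothesis as a simulatable model: three
cortical layers of two-compartment Hodgkin–Huxley pyramidal cells and
interneurons, plus two independent thalamic TC–RE populations wired into
a focal core loop (core TC → L3/4; L6 → core thalamus) and a diffuse
matrix loop (matrix TC → L5 dendrites; L5 → matrix thalamus).  Synaptic
totals are normalized by input count, so the matrix's broad projections
are individually weak.  Spindles arise spontaneously: Poisson miniature
EPSPs occasionally synchronize a local cortical patch, the corticothalamic
volley ignites a TC–RE spindle (post-inhibitory rebound via the
low-threshold Ca²⁺ current I_T), and Ca²⁺-dependent upregulation of the
h-current terminates it.  The model's claims: core spindles are frequent
and local, matrix spindles rare and global, matrix spindles usually
co-occur with core spindles (not conversely), the core leads in onset,
and the L3/4→L5 interlaminar strength — not the reverse — controls matrix
spindle density.

## Worked example

A desk-scale run (sizes ÷10, 45 s of model time — a few minutes on one
core):

```python
from spindlenet.network import NetworkSpec, build_network
from spindlenet.simulator import SimConfig, run_simulation
from spindlenet.experiments import analyze_result

net = build_network(NetworkSpec().scaled(10.0))
res = run_simulation(net, SimConfig(duration=45.0, transient_discard=5.0,
                                    seed=1, mini_amp=0.07))
out = analyze_result(res)
print(f"core density   {out['density_L34']:.1f} /min")
print(f"matrix density {out['density_L5']:.1f} /min")
print(f"P(core | matrix) = {out['p_core_given_matrix']:.2f}")
print(f"P(matrix | core) = {out['p_matrix_given_core']:.2f}")
```

prints (seed 1):

```
core density   3.1 /min
matrix density 1.4 /min
P(core | matrix) = 1.00
P(matrix | core) = 0.38
```

i.e. the core produced twice as many spindles per LFP channel, every
matrix spindle overlapped a core spindle, and only 38 % of core spindle
events reached the matrix — the co-occurrence asymmetry the model exists
to explain.  (Single short runs are noisy; the reproduction script below
aggregates longer runs over two seeds.)

The standalone detector works on any numeric matrix:

```bash
spindlenet fixtures make-bursts --channels 4 --duration 300 --out /tmp/fx
spindlenet detect --in /tmp/fx_series.tsv --rate 200 --mode empirical --out /tmp/events.csv
```

Other CLI entry points: `spindlenet simulate`, `spindlenet stats`,
`spindlenet sweep --kind fanout|interlaminar|onelayer`.

## Layout

| module | contents |
|---|---|
| `spindlenet.cells` | TC/RE and PY/IN single-cell models, rate functions in `_rates` |
| `spindlenet.synapses` | receptor kinetics, depression, GABA-B cascade, minis |
| `spindlenet.network` | populations, fanout geometry, input-normalized weights |
| `spindlenet.simulator` | packed numba integration, spike extraction |
| `spindlenet.lfp` | group-mean dendritic-current LFP, band-pass |
| `spindlenet.detect` | envelope spindle detector (model & empirical presets) |
| `spindlenet.stats` | density, ISI fits, correlation, co-occurrence, delays, phases |
| `spindlenet.experiments` | fanout / interlaminar / one-layer sweeps |
| `spindlenet.io` | config round-trip, reports, labeled burst fixtures |
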