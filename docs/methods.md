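# Methods

## Model overview

`spindlenet` simulates two interacting thalamocortical systems — *core* and
*matrix* — built from conductance-based neurons on a one-dimensional strip,
to study how projection fanout and interlaminar cortical connectivity shape
sleep-spindle statistics.

Cortex: three layers (L3/4, L5, L6), each with two-compartment pyramidal
cells (PY; regular spiking, dendrite/soma area ratio R = 165) and
interneurons (IN; fast spiking, R = 50), coupled by an axial conductance
g_c = 1/r, r = 10 MΩ.  Thalamus: single-compartment relay (TC) and
reticular (RE) cells, 200 of each per system at full scale, with no
synaptic contact between the two systems inside the thalamus.  Each
compartment obeys

    C_m dV/dt = −g_leak (V − E_leak) − I_int − I_syn

with I_int the sum of the intrinsic currents listed below and all currents
outward-positive.

The core loop is focal: core TC → {PY, IN} of L3/4 (radius 10 thalamic
index units), L6 PY → {core TC, RE} (radius 2 cortical units).  The matrix
loop is diffuse and direct: matrix TC → distal dendrites of L5 PY (radius
100), L5 PY → {matrix TC, RE} (radius 20); the baseline matrix/core fanout
ratio is therefore 10.  Within each layer, PY↔PY, PY→IN and IN→PY are
local; L3/4 ↔ L5 interlaminar excitation is set to half the intralaminar
strength at its 100 % reference point.

## Intrinsic currents and adopted kinetics

The published parameter set for this model family fixes the conductance
densities (all defaults in `cells.py` match it) but defers the rate
equations to earlier single-cell work.  The kinetics adopted here
(`_rates.py`) are the standard set of that lineage:

* **Thalamic I_Na, I_K** — Traub-type rates shifted by −63 mV (spike
  threshold near −50 mV).
* **I_T** — relay variant (activation mid −57 mV, slow deinactivation,
  Q10-scaled to 36 °C) for TC; reticular variant (mid −52 mV) for RE.
  E_Ca is computed from the Nernst equation with [Ca]_o = 2 mM.
* **I_h (TC only)** — voltage activation (mid −75 mV) plus
  activity-dependent upregulation: intracellular Ca binds a messenger
  (half-activation 1.5 µM, 4 Ca per site) that locks open channels in a
  state with twice the conductance.  The lock accumulates over a spindle
  and depolarizes the cell until rebound fails: this is the main
  termination mechanism, and its slow unbinding (~1 s) sets the
  refractory period between spindles.
* **Cortical I_Na, I_K** — the two-compartment regular/fast-spiking set:
  dense axo-somatic Na (3000 mS/cm²) with a **first-order** delayed
  rectifier (g·n, 200 mS/cm²).  The first-order form matters: with an
  n⁴ rectifier the axo-somatic Na window current stabilizes a depolarized
  fixed point near −24 mV and cells latch after one spike.
* **I_Na(p)** — activation 0.02/(1+exp(−(V+42)/5)), the family's
  functional form including its 0.02 open-fraction scale.  Without that
  scale the persistent current latches the dendrite near −15 mV.
* **I_Km, I_HVA, I_KCa** — standard rates, Q10 ≈ 2.95 to 36 °C; I_KCa is
  first order in [Ca] (rates 0.01·Ca / 0.02 ms⁻¹).
* **Ca pools** — influx 5.18·10⁻⁵·(−I_Ca) mM cm²/(ms µA) into a 1 µm
  shell (thalamus; decay 5 ms) or a 0.1 µm shell (cortex; decay 165 ms,
  ten-fold drive), relaxing to 0.24 µM.

Two deliberate parameter choices resolve printed ambiguities:

* **RE leak conductance** appears in print as both 0.05 and 0.005 mS/cm².
  The default is 0.05: single-cell integration shows 0.005 turns an
  isolated RE cell into a spontaneous burster (the network would spindle
  continuously), while 0.05 leaves it quiescent at −76 mV yet bursting on
  depolarization.  Both values are constructor arguments.
* **GABA-A reversal on TC cells** is −85 mV rather than the printed
  −80 mV.  With the adopted kinetics TC cells rest near −75 mV; a −80 mV
  reversal leaves an IPSP of less than 5 mV, which cannot deinactivate
  I_T (verified by pair-level integration over a wide conductance range:
  no rebound ever occurs).  −85 mV — the deeper chloride reversal used
  throughout the thalamic-relay literature — restores the
  rebound-burst mechanism that spindles require.  The value is a
  per-connection setting (`ConnectionRule.e_syn`).

## Synapses

First-order transmitter-gated kinetics (0.5 mM, 0.3 ms pulse while the
presynaptic soma is above 0 mV): AMPA (α = 1.1 /mM/ms, β = 0.67 /ms),
NMDA (0.072, 0.0066) with the voltage gate 1/(1+exp(−(V+25)/12.5)),
GABA-A (5.0, 0.18).  GABA-B uses the G-protein cascade
(K1 = 0.52 /mM/ms, K2 = 0.0013, K3 = 0.098, K4 = 0.033 /ms, K_d = 100,
n = 4), giving slow, burst-selective inhibition at −95 mV.

Short-term depression (U = 0.2, τ = 500 ms) applies to intracortical
excitatory connections only.  Synaptic strengths are totals per target;
per-synapse weights are total/(number of inputs received), so broader
projections have proportionally weaker synapses ("input normalization").
The printed µS values are treated as absolute conductances and divided by
the target compartment's area, the convention of the model family's code;
this interpretation was validated by requiring the TC–RE pair to produce
a self-terminating spindle-band oscillation (see below).

Miniature PSPs are delivered on excitatory cortical synapses (AMPA) and
IN→PY GABA-A synapses as open-fraction increments of 0.1 (roughly two
thirds of an evoked response), timed by an inhomogeneous Poisson process
with rate µ(Δ) = (2/(1+e^(−Δ/400)) − 1)/250 per ms after the last
presynaptic spike (saturation 4 Hz per synapse), sampled by thinning.
The default mini amplitude was chosen so that between-spindle PY firing
stays sparse (≲1 Hz); minis are the only noise source and the sole cause
of spontaneous spindle initiation.

## Integration

Fixed step, dt = 0.025 ms.  Voltages use exponential Euler with
conductances frozen over the step — for the stiff axo-somatic compartment
this relaxes V toward its conductance-weighted quasi-steady value, the
behavior the family's algebraic-soma formulation targets.  Gating
variables use Rush–Larsen updates with (x_∞, exp(−dt/τ)) interpolated
from precomputed 0.05 mV tables; the slow Ca-coupled I_h states, the Ca
pools, synaptic open fractions and the GABA-B cascade use forward Euler.
Spikes are upward crossings of −20 mV with a 2 ms refractory.  Identical
seeds give bit-identical rasters.  A fused numba kernel advances all
cells and synapses; idle synapses (closed, no transmitter) cost one
comparison per step.

Initial conditions: per-class resting states (found by 3 s relaxation of
the reference single-cell integrator) plus seeded ±2 mV jitter; the first
seconds (default 5 s) are discarded from every output.

## LFP, detection, statistics

The LFP proxy for each group of contiguous PY cells (100 at full scale)
is the arithmetic mean of the chemical synaptic currents entering their
dendritic compartments (inward negative); L3/4 stands for the core
("MEG-like"), L5 for the matrix ("EEG-like") signal.  Filtering is a
zero-phase 4th-order Butterworth band-pass (6–15 Hz for model LFP),
chosen zero-phase so onset-delay statistics are unbiased.

Detection: Hilbert envelope of the band-passed signal, Gaussian-smoothed
(±300 ms support, σ = 40 ms); events are regions above mean + 1 SD
containing at least one sample above mean + 2 SD, with gaps < 100 ms
merged (envelope-ripple guard, toggleable), then gated to 0.5–3 s in
model mode (0.5–2 s in empirical mode with a 10–16 Hz band).  Thresholds
are in SD units, so detection is exactly amplitude-scale invariant.
Inter-spindle intervals are center-to-center with intervals > 20 s
excluded.

Statistics follow the definitions in `stats.py`: density in spindles/min
per channel; ML lognormal/exponential ISI fits plus Lilliefors normality;
epoch-restricted Pearson spatial correlation by channel distance;
co-occurrence as span intersection of layer-level events (channel events
merged across gaps < 300 ms); onset delays from nearest-onset pairing
within 2.5 s, each matrix event used once, negative = core first;
spike phases from the analytic-signal angle at spike times inside events
(peak ≡ phase 0; add π for the trough-zero convention), 100-bin
normalized histograms.

## Desk-scale conditions

Full-scale statistics (3000 PY, 600 IN, 800 thalamic cells, minutes of
model time per condition) are beyond a single-core desk run, so the test
suite and the reproduction script use a reduced configuration chosen
once:

* sizes ÷10 (100 PY/layer, 20 IN/layer, 20 TC and 20 RE per system);
* thalamocortical (TC→cortex) radii ÷10, preserving the output
  fanout-to-size ratios (core local, matrix global);
* corticothalamic radii and the intracortical radii (PY→PY 5, PY→IN 1,
  IN→PY 5 — unprinted, adopted values) kept in absolute cell counts:
  they set how many locally summing inputs a cell integrates, i.e. the
  local-synchrony threshold for igniting a spindle (5 cortical inputs
  per core TC, 41 weak inputs per matrix TC — the full-scale counts).
  Scaling them down to ~1 input lets lone random spikes ignite spindles
  and collapses the core/matrix recruitment contrast;
* the intrathalamic radius scales but is floored at 2 cells (an
  unscaled radius lets every thalamic spindle span the strip and erases
  the core/matrix locality contrast);
* 60 s of analyzed model time per seed (after 5 s transient), 2–3 seeds
  per condition, 10 LFP groups per layer.

At this scale the model reproduces the mechanism *directionally*: higher
core than matrix density, P(core | matrix) > P(matrix | core), negative
mean onset delay (core leads), higher matrix spatial correlation, falling
matrix density with rising fanout ratio, and matrix density controlled by
L3/4→L5 but not L5→L3/4 strength.  Absolute densities sit somewhat below the full-scale values (typically
3–5 core spindles/min per channel vs ~6.5 at full scale), as expected
when each layer holds ten-fold fewer initiation sites; full-scale
numbers should be compared against full-scale runs (`scale=1`, cluster
or overnight).

Two fanout-sweep limitations of the reduced network are documented
rather than hidden: at ratio 1 the matrix loop (now focal, strong, and
relatively ten-fold broader than at full scale) locks into continuous
tonic reverberation instead of discrete waxing-and-waning events, so
detected density collapses even though firing rates triple; and at low
ratios the per-channel density metric conflates initiation rate with
spatial extent far more strongly than at full scale (a focal matrix
event lights 1 channel where a global one lights 10).  The full-scale
claim that matrix density falls as the fanout ratio rises from 1 to 10
is therefore *not* reproduced by the ÷10 network, and the corresponding
end-to-end check is expected to fail at desk scale.

What the synthetic burst fixtures (`io.generate_burst_series`) do and do
not show: they validate the detector and the statistics pipeline against
known ground truth (labels of onset/offset/frequency), with 1/f-like
background and Tukey-tapered bursts whose labeled duration matches their
suprathreshold extent.  They do not emulate volume conduction, artifacts,
non-stationary background, or spindle frequency drift, so detector scores
on them bound performance on clean signals only.

## Numerical and design notes

* dt = 0.025 ms default; halving dt changes single-cell voltage traces by
  < 1 mV RMS.  Coarser steps (≥ 0.04 ms) measurably change network event
  counts and are not used.
* The TC–RE pair reduction (one TC, one RE, printed conductances) shows a
  self-terminating oscillatory epoch after a brief RE depolarization, at
  ~7–14 Hz burst rate with Ih-upregulation termination.  Epoch length in
  this deterministic two-cell system is chaotic in the synaptic
  strengths (0.6–10 s within ±20 %), so tests assert the mechanism
  (≥ 4 rebound bursts, spindle-band rate, termination) rather than an
  exact epoch length.
* Events whose envelope gap is < 100 ms are merged before duration
  gating; without the merge, envelope ripple splits long simulated
  spindles and inflates short-duration counts.
* Degenerate inputs: empty event lists give NaN co-occurrence and empty
  delay samples (flagged, never silently zero); ISI fits require ≥ 20
  intervals; spatial correlation requires at least one spindle epoch.
* Spike-phase units with < 10 in-spindle spikes are excluded and counted.
* The "400 interneurons (200 in each population)" count is arithmetically
  inconsistent with three layers; the default is 200 IN per layer
  (600 total), configurable.
* Interlaminar NMDA is 0.03 µS (half the intralaminar 0.06), keeping the
  sweep's "100 % = half intralaminar" anchor self-consistent; the printed
  0.75 µS (12.5× the intralaminar value, presumably a misprint) is
  selectable via `NetworkSpec(interlaminar_nmda_printed=True)`.
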