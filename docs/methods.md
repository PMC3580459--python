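# Methods

`qspwm` couples two mechanistic levels: a receptor-competition model
of a single synapse, and a conductance-based prefrontal-cortex network
whose stimulus-evoked persistent firing is read out as a working-memory
span. Clinical dose information enters at the synapse level; its
consequences for cognition are read out at the network level and
compared against published ADAS-Cog outcomes.

## Receptor-competition synapse

Ligands (neurotransmitter, drug, metabolite, tracer) compete for shared
receptor pools. For ligand *i* with association rate `kon_i`
(nM⁻¹·ms⁻¹) and dissociation constant `Kd_i` (nM),

    d[R_i]/dt = kon_i [C_i] [R_f] − kon_i Kd_i [R_i],
    R_f = R_o − Σ_i R_i .

The dissociation rate is always the derived `kon·Kd`; because the
system is linear in the bound fractions, `R_o` cancels and fractions
are integrated directly (fixed-step RK4, default `dt = 0.01 ms`, with
automatic sub-stepping when `kon·C·dt` would exceed the stability
range, e.g. at very high drug concentrations).

Free transmitter decays exponentially with half-life τ½ and jumps by a
quantal increment at each presynaptic spike. Release is the product of
two regulators, both multiplying a base release `r0`:

* autoreceptor feedback `1 + rmax (1 − 2 A^S / (A^S + B0^S))`, where
  `A` is the autoreceptor occupancy 150 ms before the spike (before
  150 ms of history exists, `A = B0`, which makes the early gain
  exactly 1);
* spike-history facilitation/depression
  `1 + Σ_prev [wf e^(−kf Δt) − wd e^(−kd Δt)]` with rates derived from
  half-lives (`ln 2 / t½`); the factor is floored at 0 so release can
  never be negative.

The simulation protocol is: equilibration against a constant 500 nM
free transmitter (solved in closed form with the competitive-binding
isotherm — exact, and identical to integrating the ODE to steady
state), a 5 s transient at the tonic rate, then a 10 s averaging
window over which mean occupancies are accumulated (trapezoidal rule,
so halving `dt` moves the means by less than 1e−6 relative). Tonic
drive is a deterministic regular train: the physiological inputs are
specified as rates, not spike statistics, and a regular train makes
every synapse-level quantity reproducible without seed bookkeeping.

### Cholinergic preset

M2 is the autoreceptor; M1, α7 and α4β2 are postsynaptic pools. The
quantal increment derives from 70 molecules per quantum × 5.5 quanta
per action potential in a 1×10⁻¹⁶ L cleft (the mid-range of the
5–20×10⁻¹⁷ L anatomical estimate), i.e. ≈6.4 µM per release. Tonic
rate 7 Hz (mid 6–8 Hz band), free-ACh half-life 5 ms. The
acetylcholinesterase enzyme constants (pEC50 −6.6, Hill 0.9, turnover
25 000 s⁻¹, density 2 400 µm⁻²) are recorded as reference constants;
clearance itself is the first-order half-life law, because the whole
dose chain operates on the half-life.

The effective ACh affinity of the M1 pool (`Kd = 202 nM`) is the one
truly calibrated constant: it is fixed so that 8 mg galantamine —
through `l = D/(D+Ki)` with the clinical `Ki = 30 mg`, half-life
5 → 6.33 ms — raises mean M1 activation by 9.1 %, the value the
clinical calibration itself converges to. The remaining affinities
(M2 280 nM, α7 3 µM, α4β2 1 µM) are plausible rank-ordered values;
they only enter downstream as *relative* activation changes.

### Serotonergic preset and calibration loop

5-HT1B is the autoreceptor (agonist-state Kd 4.2 nM for endogenous
5-HT; the antagonist-state 23.4 nM applies to antagonist tracers;
functional EC50 8.5 nM), with 5-HT2A and 5-HT6 postsynaptic pools and
a 1 Hz tonic rate. The presynaptic physiology ships with the fitted
values (RelSens 7.75, facilitation/depression weights 1.1/0.42,
half-lives 90/120 ms) and the intra- over extrasynaptic free-5-HT
ratio of 2; the cleft transmitter scale is on the intrasynaptic side.

The fitting loop that produced such values is a first-class, testable
pipeline: a seeded generator simulates forced-firing
(voltammetry-style) peak-transmitter data under known presynaptic
parameters, optionally with Gaussian noise; `fit_presynaptic_params`
runs a coarse full-factorial search followed by steepest descent
(central-difference gradient, backtracking line search, stop on
<1e−8 improvement). The generator emulates peak free-transmitter
levels under driven trains only — it does not model electrode
kinetics, uptake-transporter saturation or tissue diffusion, so
passing recovery tests show the estimator is consistent, not that the
animal data themselves would be fitted this well.

Tracer displacement is simulated mechanistically: the synapse is run
with and without the drug and displacement is
`1 − occ_tracer(drug)/occ_tracer(baseline)`; the functional brain
concentration for an observed displacement is found by a bracketed
root search (Brent, bracket 10⁻³–10⁶ nM, displacement is monotone in
concentration).

## Cortical network

80 four-compartment pyramidal cells (apical-distal — proximal — soma —
basal chain; 40 stimulated, 40 unstimulated) and 40 two-compartment
fast-spiking interneurons. Compartment geometry and maximal
conductances follow the published per-compartment table; gating
follows the published rate functions with removable singularities
patched by their limits (a handful of signs lost in transcription were
restored to the standard forms of the underlying PFC cell models —
each gate is asserted to satisfy `x∞ ∈ [0,1]`, `τ > 0` over
[−120, 60] mV). The KCa gate operates on the calcium-shifted voltage
`Vs = V + 40 log10(1e4 [Ca])` with `[Ca]` (molar) floored at 1e−8;
calcium follows `d[Ca]/dt = −φ I_HVA − ([Ca]−Ca_rest)/τ_Ca`
(φ = 1e−9 M per µA·cm⁻²·ms, τ_Ca = 250 ms).

Connectivity: all pyramidal cells synapse onto the whole pyramidal
population (AMPA+NMDA, self-connections included) and onto every
interneuron; a seeded 60 % subset of interneurons projects GABA-A onto
all pyramidal cells; all interneurons inhibit each other. Excitation
lands on the proximal dendrite (pyramids) / dendrite (interneurons),
inhibition on the soma. A contacts-per-pair multiplier is exposed for
anatomically denser variants (default 1).

Synapses are difference-of-exponentials (AMPA 0.5/2 ms, NMDA
2.3/95 ms, GABA-A 0.5/8 ms; E_glu = 0 mV, E_GABA = −70 mV on pyramids,
−75 mV on interneurons) aggregated into two accumulator states per
compartment and class. The NMDA conductance passes the standard
voltage-dependent Mg²⁺ block `1/(1 + ([Mg]/3.57) e^(−0.062V))` at
1 mM, and — a deliberate model choice — a smooth receptor-saturation
ceiling `g_eff = C (1 − e^(−g/C))` with `C = 0.4 mS/cm²` on the summed
NMDA input per compartment. Without the ceiling the regenerative
interaction between the Mg block and recurrent NMDA drive produces an
uncontrollable high-rate state (the network escapes any plausible
inhibitory tone); with it the quiescent state is stable, ignition
requires the coherent stimulus, and the persistent state stays in an
inhibition-balanced regime.

The memory stimulus is a 200 ms, 20 µA/cm² somatic current into the 40
stimulated cells at t = 2 s. It also triggers the mGluR5-dependent
after-depolarization, an α-function current
`A (t/τ) e^(1−t/τ)` (A = 4 µA/cm², τ = 4 s) on the stimulated somata —
the ADP is gated on the stimulus because mGluR5 activation requires
the ignition input; a run without stimulus has neither. The decaying
ADP tail sets a deterministic ceiling on the attractor lifetime
(~10 s for the healthy network) while recurrent NMDA drive determines
how close to that ceiling the collapse happens; this hybrid keeps the
healthy span distribution inside the physiological 4–10 s envelope
while remaining sensitive to synaptic and excitability changes.

Background noise is an independent 500 Hz Poisson excitatory train per
neuron (weight 0.012 mS/cm²), giving ~1 Hz pyramidal baseline firing.
Unprinted membrane constants: C_m = 1 µF/cm², leak 7×10⁻⁵ S/cm² to
−70 mV, axial resistivity 150 Ω·cm, E_Na = 55, E_K = −80,
E_Ca = 120 mV.

Integration is fixed-step `dt = 0.025 ms`: exponential Euler on every
gate via voltage-indexed update tables (0.05 mV grid), exponential
Euler on V toward the frozen-conductance steady state with the axial
self-term treated implicitly, neighbor voltages explicit. A 1 s
unrecorded settle phase precedes t = 0 so the identical-initial-state
transient never reaches the raster. Spikes are upward crossings of
−20 mV at the soma with a 2 ms refractory and 1 ms conduction delay.
At this step size single-cell firing rates still carry a few-percent
step-size bias (halving `dt` moves rates by ~5 %); the step is part of
the model definition and all calibrated values refer to it.

## Span readout and conditions

The working-memory span divides time into 200 ms bins, counts distinct
stimulated neurons firing per bin, and takes the time between the
first and last bin whose count strictly exceeds M/2 (M = number of
stimulated cells, post-lesion). The alternative 80 % threshold is a
parameter.

A clinical condition composes: linear pathology progression
(baseline 5 %/5 % synapse/neuron loss at trial entry, slopes
0.04 %/week synapses and 0.25 %/week neurons; the MCI state is 3 %/4 %
with a 10 % cholinergic compensation), the cholinergic deficit
(17.5 % release reduction for calibration runs, 30 % in the validation
experiments), the dopaminergic placebo surge (+7.5 % DA tone from week
12 on), drug chains (AChE-I half-life scaling; SB742457 5-HT6
activation presets 40.6/12.9/5.1/3.1 % for placebo/5/15/35 mg, fed
through the 5-HT6 cascade with gain 0.025 under the
antagonism-raises-modulators sign convention), ApoE4 synapse-loss
increments (3 %/5 % per allele count, homozygotes additionally −10 %
ACh), and memantine (NMDA conductance ×0.995 on e-e, ×0.99 on e-i
synapses).

Lesioning deletes `round(loss × 80)` pyramidal cells balanced across
the stimulated/unstimulated halves (odd counts take the extra cell
from the unstimulated half so the stimulated population that carries
the metric is preserved; interneurons are spared), then removes the
synapse-loss fraction of surviving glutamatergic contacts, e-e and
e-i classes at the same rate, an AMPA/NMDA pair at one (pre, post)
counting as a single anatomical contact.

Receptor-activation changes reach the network through the coupling
rules: D1/α7 factors on excitatory synapses onto pyramids (+D4 on
AMPA onto interneurons), D1/α4β2 on GABA-A onto pyramids (+5-HT3 on
interneuron–interneuron GABA-A), and the muscarinic membrane rule
`ΔM = −4 + 6 A_M1 + 2(1 − A_M2)` scaling the pyramidal
delayed-rectifier conductance with P_M1 = 0.075 per mV. Two
normalizations keep the calibrated healthy network as the exact
reference state: the Kdr rule uses the ΔM *difference* from the
control condition, and a depolarizing ΔM *closes* K⁺ channels (the
literal printed sign would make cholinomimetics anti-cognitive; the
convention is config-switchable). The α7 coupling defaults to twice
the α4β2 coupling (the calibrated relative effectiveness of 2).

## Calibration machinery

`correlate_clinical` fits ADAS-Cog effects against mean spans (degree
1 or 2 least squares; r², F-test p, per-week sub-fits). Since the
ADAS-Cog effects in the table are changes from each trial's own
baseline, absolute spans are used as the regressor — any common
baseline shift is absorbed by the intercept, so slope and r² are
identical to a change-vs-baseline formulation. `doe_screen` evaluates
a response on a 2n-run two-level fold-over design (cyclic
quadratic-residue generator row) and ranks main effects by magnitude;
fold-over cancels even-order interactions but leaves an O(1/n)
cross-factor contamination, which matters only when effects differ by
less than that factor. `optimize_response_surface` is a greedy
per-coordinate local refinement with shrinking relative steps and a
hard evaluation budget; `sensitivity_scan` is one-at-a-time.

## Problem sizes in the shipped tests

The test suite runs everything at the sizes a single CPU handles
comfortably: the healthy-network check uses 10 seeded 15 s trials; the
clinical-correlation smoke check uses the eight 12-week conditions at
5 trials each; the validation experiments (memantine, ApoE4) use 14
paired seeds per arm with 9.5 s windows and the stimulus moved to
1 s (spans cap at 8.5 s there, which truncates the longest trials);
the presynaptic-recovery check fits four forced-firing stimuli at a
0.05 ms synapse step. The full 28-condition × 10-trial calibration is
reachable through the `qspwm calibrate` command.

## Known limitations

* One interneuron class, point-ish compartments, no oscillatory
  readouts; the network is a working-memory span machine, not a
  general cortical model.
* The attractor's collapse is dominated by the ADP envelope plus
  recurrent NMDA drive; sensitivity to pure synapse-contact loss is
  weak compared to neuron loss and excitability changes, so
  experiments that hinge on small synapse-loss differentials carry
  wide seed-to-seed variance.
* Memantine's differential e-e/e-i NMDA block produces sub-percent
  changes of a minority input pathway; its directional effects in
  this network are small relative to trial noise.
* Firing rates carry a few-percent step-size bias at dt = 0.025 ms;
  dt is therefore part of the model definition.
* The synthetic voltammetry generator does not emulate electrode or
  uptake kinetics (see above), and the clinical table's two 78-week
  placebo rows enter the correlation like any other row — they are
  not recomputed from their source trials.
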