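# Methods

`stcnet` simulates a recurrent network of leaky integrate-and-fire (LIF)
neurons whose excitatory-to-excitatory synapses carry a calcium-based
early-phase weight and a tag/protein-gated late-phase weight (synaptic
tagging and capture, STC). A scalar neuromodulator concentration NM lowers
the protein-synthesis threshold, so the amount of neuromodulator present in
the minutes-to-hours after a learning event decides which synapse
populations are consolidated, and with them which neural code (rate-based
pattern completion vs. spike-timing structure) survives to long-term
memory. The package also implements the analysis battery used to quantify
those codes.

## Network and neuron model

Neurons (N_e excitatory, N_i inhibitory; defaults 1600/400) are connected
by independent directed Bernoulli draws with probability p_c = 0.1, no
self-connections, at most one synapse per ordered pair. The membrane
potential follows

    tau_m dV/dt = V_rev - V + V_PSP + V_bg + V_stim,

with threshold V_th = -55 mV, reset V_reset = -70 mV and a 2 ms refractory
clamp. V_PSP sums exponentially decaying (tau_syn = 5 ms) postsynaptic
potentials delivered with a 3 ms axonal delay; it is implemented as one
per-neuron exponential trace (mathematically identical to the explicit sum
over delayed spikes, and verified against it to 1e-9 mV). Inhibitory
weights enter this trace negatively; the static weights are w_ei = 2 h_0,
w_ie = w_ii = 4 h_0 with h_0 = 4.20075 mV.

V_bg is an Ornstein-Uhlenbeck (OU) process with stationary mean
R_m I_0 = 1.5 mV and stationary sd R_m sigma_wn / sqrt(2 tau_syn) = 5 mV,
modelling input from outside the network. All stochastic differential
equations are integrated by Euler-Maruyama at dt = 0.2 ms, with white-noise
terms drawn per step as Gaussians of sd sqrt(1/dt).

### Stimulus drive

Learning and recall stimulation enter as a second, per-neuron-independent
OU process emulating N_stim putative Poisson inputs at frequency f_stim:

    tau_syn dV_stim/dt = -V_stim
        + (N_stim f_stim + sqrt(N_stim f_stim) Gamma) tau_syn g h_0,

whose stationary mean is N_stim f_stim tau_syn g h_0. The factor tau_syn
makes mean and variance those of a summed exponential-PSP shot-noise
process; g (`stim_gain`, default 24) is the efficacy of one putative input
in units of h_0. The value of g was calibrated once against the
learning-phase operating point: at the reference learning frequency of
60 Hz the stimulated assembly must fire fast enough (~100-150 Hz) that
calcium at assembly-internal synapses crosses the potentiation threshold,
while synapses out of the assembly — whose calcium is driven by the
presynaptic rate only — potentiate much more weakly. This operating point
is what gives the per-neuron early-phase change sums their decisive
structure (see below); a drive that saturates every stimulated neuron at
the refractory limit, or one too weak to ignite the assembly, both destroy
the selectivity of consolidation. With g = 24 the non-core change sums
(~13 mV) fall between the protein thresholds of the high (5.5 mV) and low
(16.4 mV) neuromodulator levels, while core sums (~35 mV and above) exceed
both — the regime in which low NM consolidates only the assembly core and
high NM additionally consolidates the outgoing synapses.

## Plasticity model

Each E->E synapse carries calcium c, early-phase weight h and late-phase
weight z; the total weight is w = h + h_0 z. Calcium decays with
tau_c = 48.8 ms and jumps by c_pre = 0.6 per presynaptic spike (delayed by
18.8 ms) and c_post = 0.1655 per postsynaptic spike. The early phase obeys

    tau_h dh/dt = 0.1 (h_0 - h) + gamma_p (10 mV - h) H[c - theta_p]
                  - gamma_d h H[c - theta_d] + noise,

with the noise term (scale sigma_pl) active only while c exceeds theta_d
or theta_p. h is clipped to [0, 10 mV]: the lower bound prevents
noise-driven negative weights, the upper bound is the potentiation
attractor of the drift.

A synapse is tagged while |h - h_0| > theta_tag = 0.840149 mV. Each neuron
carries a protein amount p (tau_p = 1 h) synthesized toward alpha = 1
while the summed early-phase change of its incoming E->E synapses,
Sigma_j |h_j - h_0| (recomputed from the current weights, not
accumulated), exceeds theta_pro(NM) = 1/(NM + 0.001). The late phase
(tau_z = 1 h) grows toward 1 under an LTP tag and toward -0.5 under an LTD
tag, at a rate proportional to p; z is clipped to [-0.5, 1], the bounds of
its drift. Neuromodulation schedules are piecewise constant; onset is
measured from the end of learning stimulation (t = 11.1 s), since that is
when a consolidation-relevant signal can first act, and a duration of
"max" holds the level for the rest of the simulation.

With NM = 0 the threshold is 1000 mV, which exceeds the largest change sum
any default-topology neuron can reach (about 160 incoming synapses times
at most 5.8 mV ≈ 928 mV), so without neuromodulator no late-phase change
can ever occur — a property the tests verify both by this bound and
empirically.

## Protocol and fast-forward

An experiment runs: 10 s settling; three 0.1 s learning pulses to the
150-neuron assembly separated by 0.4 s breaks (onsets 10.0/10.5/11.0 s);
then recall — one 0.1 s pulse at 100 Hz to half the assembly — with onset
20.0 s (10 s condition) or 28810.0 s (8 h condition), so the rate
evaluation times are t = 20.1 s and 28810.1 s. For the 8 h condition the
spiking dynamics are computed only to 11.6 s (after stimulus transients
and calcium have decayed) and from 0.5 s before the recall pulse; the gap
is bridged by a fast-forward that advances h along its exact exponential
relaxation and integrates tag, protein and late-phase dynamics on a coarse
step dt_ff. Because the relaxation is multiplicative on h - h_0, the
change sums scale by one global factor and the tagged set only shrinks,
which the implementation exploits. The spiking engine applies the same
laziness exactly (deferred exponential decay of calcium and h while no
synapse is above theta_d), so it is bit-equivalent to the naive per-step
update, and integrates the hour-scale protein/late-phase equations on a
5 ms substep (`slow_update_every` = 25), numerically indistinguishable at
those time constants. dt_ff defaults to 0.1 s; the scaled-down experiments
use 1.0 s, which the fast-forward oracle test bounds against fine 0.2 ms
integration.

Branching: all experiment variants that share the learning protocol are
simulated once up to the end of learning and then branched (engine state
plus noise stream), which is bit-identical to independent runs because a
neuromodulator schedule cannot act before its onset.

## Analyses

- **Sliding rates.** Per-neuron rates from spike counts in a trailing
  half-open 0.5 s window (t - 0.5 s, t]; rates are multiples of 2 Hz. The
  trailing convention makes the window at t_recall cover the entire recall
  pulse.
- **Pattern completion Q** = (nu_ans - nu_ctrl) / nu_as over the
  recall-stimulated assembly half ("as"), the non-stimulated half ("ans")
  and the excitatory controls ("ctrl"); 1 is perfect input-defined
  completion, 0 none; undefined if the stimulated half is silent.
- **Rate mutual information.** Plug-in MI (bits) between the empirical
  per-neuron rate distributions at the end of learning (t = 11.0 s) and at
  recall, using exact discrete rate values as categories (no extra
  binning parameter — window rates are inherently discrete).
- **PCA dimensionality.** Smallest number of principal components
  explaining 70 % of the variance of the (neurons x 1 ms bins) recall
  raster, neurons as samples; computed with scikit-learn's PCA.
- **Spike-time stability.** Fraction of a neuron's final-learning-pulse
  spike bins (1 ms) that recur at identical bins during recall; neurons
  without learning-pulse spikes are excluded from the average. The control
  shuffles bin order independently per neuron and raster, preserving
  counts; its analytic expectation is hypergeometric (m/B for m recall
  spikes in B bins).
- **Temporal-sequence readout.** Ridge regression (alpha = 0.1, intercept
  column penalized with the rest, matching the stated objective) from the
  concatenated 1 ms-binned rasters of the three learning pulses and the
  recall pulse (400 bins) onto a Gaussian random-walk target (y[0] = 1)
  repeated per segment; performance is R^2 of the prediction on the recall
  segment alone. Neuron subsamples of size round(p_out * pool) are drawn
  without replacement per (network, target, p_out).
- **Stability-weight correlation.** Spearman rank correlation (scipy)
  between per-neuron stability of non-core neurons and the mean late-phase
  weight they receive from the core.

## Scaled-down study conditions

Desk-scale experiments use a 4x smaller preset: N_e = 400, N_i = 100,
assembly 40, recall set 20, with p_c = 0.4 so that per-neuron in-degrees
(200 overall, ~16 from the assembly) equal the full-size network's. This
in-degree-preserving downscale keeps the recurrent gain, the balanced
stimulation operating point and the absolute protein-threshold regime of
the full model, at a quarter of the neurons and synapses; consequently the
neuromodulator levels 0.06 (low) and 0.18 (high) carry over essentially
unchanged (the exact translation, a ~7 % shift, is provided by
`scaled_nm_level`). Qualitative-reproduction tests run 10 such networks
per condition; the full-size configuration is the package default and can
be run through the same API and CLI, but takes hours per network.

## What the synthetic fixtures do and do not emulate

The fixture generator produces paired learning/recall binned rasters with
a controllable probability that a learning spike recurs in the same bin,
optional low-rank temporal structure, and weight tables with labeled
synapse classes and controllable per-class potentiated fractions. These
reproduce the statistical structure the analysis functions consume (bin
overlap, rank, class composition) but none of the network's dynamical
correlations — no refractoriness, no E/I balance, no rate heterogeneity —
so tests built on them validate the measures, not the simulator. Claims
about the model itself always rest on simulated runs.

## Numerical choices and degenerate inputs

Forward Euler(-Maruyama) throughout at dt = 0.2 ms; threshold test V >=
V_th after the update, no crossing interpolation; spike times are step
boundaries. Heaviside gates use strict inequality. Per-step update order:
deliver due spikes, OU steps, membrane step and threshold, enqueue spikes,
plasticity. Zero-variance rasters have PCA dimensionality 0; Q returns NaN
when the stimulated subpopulation is silent; stability excludes (flags)
zero-spike neurons; the Spearman correlation requires at least three valid
points. Spike-time comparisons use a 1 ns guard against float round-off of
times on the dt grid.

## Known limitations

Current-based (not conductance-based) synapses; a single abstract
neuromodulator acting only on the protein-synthesis threshold; one cell
assembly; no replay or systems consolidation; the stimulus-efficacy gain g
is a calibrated effective parameter rather than a measured biophysical
quantity, and the scaled-down preset, while in-degree-preserving, cannot
reproduce full-size population statistics (e.g. readout R^2 magnitudes
grow with the number of available neurons).
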