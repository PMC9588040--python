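"""Membrane, input and postsynaptic-potential dynamics.

The membrane potential of a leaky integrate-and-fire neuron follows

    tau_m dV/dt = V_rev - V + V_PSP + V_bg + V_stim,

where V_PSP sums exponentially decaying postsynaptic potentials from within
the network (delivered with an axonal delay), V_bg is an Ornstein-Uhlenbeck
background drive representing input from outside the network, and V_stim is
an Ornstein-Uhlenbeck stimulus drive active only while a neuron is being
stimulated. On crossing V_th the neuron spikes, is reset to V_reset, and is
clamped there for the refractory period.

All steppers are forward Euler-Maruyama at the model time step dt, with the
white-noise terms drawn per step as Gaussians of standard deviation
sqrt(1/dt). They operate elementwise on scalars or arrays, so the network
engine uses the very same functions the unit tests exercise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import ModelParams


def ou_step_background(v_bg, params: ModelParams, noise_draw):
    """One Euler-Maruyama step of the background Ornstein-Uhlenbeck drive.

    tau_syn dV_bg/dt = -V_bg + R_m (I_0 + sigma_wn * Gamma), with Gamma white
    noise of variance 1/dt; ``noise_draw`` is a standard-normal draw.
    """
    p = params
    gamma = np.asarray(noise_draw) / np.sqrt(p.dt)
    return v_bg + (p.dt / p.tau_syn) * (
        -v_bg + p.R_m * (p.I_0 + p.sigma_wn * gamma)
    )


def ou_step_stimulus(v_stim, f_stim, params: ModelParams, noise_draw):
    """One Euler-Maruyama step of the stimulus Ornstein-Uhlenbeck drive.

    tau_syn dV_stim/dt = -V_stim + (N_stim f_stim + sqrt(N_stim f_stim) Gamma)
                                   * tau_syn * stim_gain * h_0.
    The drive emulates the summed postsynaptic potentials of N_stim putative
    input neurons firing Poisson at f_stim through synapses of efficacy
    stim_gain * h_0 (stationary mean N_stim f_stim tau_syn stim_gain h_0);
    with f_stim = 0 the trace simply decays.
    """
    f = np.asarray(f_stim, dtype=float)
    if np.any(f < 0):
        raise ValueError("stimulation frequency must be non-negative")
    p = params
    gamma = np.asarray(noise_draw) / np.sqrt(p.dt)
    mean = p.N_stim * f
    drive = (mean + np.sqrt(mean) * gamma) * p.tau_syn * p.stim_gain * p.h_0
    return v_stim + (p.dt / p.tau_syn) * (-v_stim + drive)


def ou_stationary_background(params: ModelParams) -> tuple[float, float]:
    """Closed-form stationary mean and standard deviation of the background OU."""
    mean = params.R_m * params.I_0
    sd = params.R_m * params.sigma_wn / np.sqrt(2.0 * params.tau_syn)
    return mean, sd


def ou_stationary_stimulus(f_stim: float, params: ModelParams) -> tuple[float, float]:
    """Closed-form stationary mean and sd of the stimulus OU at frequency f_stim."""
    w_eff = params.stim_gain * params.h_0
    mean = params.N_stim * f_stim * params.tau_syn * w_eff
    sd = (np.sqrt(params.N_stim * f_stim) * params.tau_syn * w_eff
          / np.sqrt(2.0 * params.tau_syn))
    return mean, sd


def psp_decay_step(psp_trace, params: ModelParams):
    """Exponential decay of the postsynaptic-potential trace over one step."""
    return psp_trace * np.exp(-params.dt / params.tau_syn)


def deliver_spike(psp_trace, weight):
    """Add an arriving postsynaptic potential of size ``weight`` to the trace.

    Called at arrival time, i.e. t_ax_delay after the presynaptic spike; the
    trace then decays with tau_syn, which reproduces the explicit
    sum-over-spikes form of the recurrent input exactly.
    """
    return psp_trace + weight


def psp_sum_explicit(t, spike_times, weights, params: ModelParams) -> float:
    """Direct evaluation of the recurrent-input sum (independent of the trace).

    V_PSP(t) = sum_k w_k exp(-(t - t_k - t_ax_delay)/tau_syn) Theta(t - t_k - t_ax_delay).
    """
    t_arr = np.asarray(spike_times, dtype=float) + params.t_ax_delay
    w = np.asarray(weights, dtype=float)
    lag = t - t_arr
    active = lag >= 0
    return float(np.sum(w[active] * np.exp(-lag[active] / params.tau_syn)))


def membrane_step(v, psp, v_bg, v_stim, refrac, params: ModelParams):
    """One Euler step of the membrane equation with threshold and reset.

    Refractory neurons stay clamped at V_reset and count down. Returns
    ``(v', refrac', spiked)``; works on scalars and arrays alike.
    """
    p = params
    v = np.asarray(v, dtype=float)
    refrac = np.asarray(refrac, dtype=np.int64)
    if np.any(~np.isfinite(v)):
        raise FloatingPointError("NaN/inf membrane potential")
    in_ref = refrac > 0
    drive = p.V_rev - v + np.asarray(psp) + np.asarray(v_bg) + np.asarray(v_stim)
    v_new = np.where(in_ref, p.V_reset, v + (p.dt / p.tau_m) * drive)
    refrac_new = np.where(in_ref, refrac - 1, refrac)
    spiked = (~in_ref) & (v_new >= p.V_th)
    v_new = np.where(spiked, p.V_reset, v_new)
    refrac_new = np.where(spiked, p.refractory_steps, refrac_new)
    return v_new, refrac_new, spiked


@dataclass
class SpikeRaster:
    """Spike events as parallel (neuron id, spike time) arrays.

    Times are in seconds. ``n_neurons`` fixes the row count of binned views.
    """

    neuron_ids: np.ndarray
    times: np.ndarray
    n_neurons: int

    def __post_init__(self) -> None:
        self.neuron_ids = np.asarray(self.neuron_ids, dtype=np.int64)
        self.times = np.asarray(self.times, dtype=float)
        if self.neuron_ids.shape != self.times.shape:
            raise ValueError("neuron_ids and times must have equal length")

    @property
    def n_spikes(self) -> int:
        return len(self.times)

    def in_window(self, t0: float, t1: float) -> "SpikeRaster":
        """Spikes with t0 <= t < t1."""
        sel = (self.times >= t0) & (self.times < t1)
        return SpikeRaster(self.neuron_ids[sel], self.times[sel], self.n_neurons)

    def counts_in_window(self, t0: float, t1: float,
                         half_open_left: bool = False) -> np.ndarray:
        """Per-neuron spike counts; (t0, t1] if half_open_left else [t0, t1)."""
        eps = 1e-9  # guard float round-off of spike times on the dt grid
        if half_open_left:
            sel = (self.times > t0 + eps) & (self.times <= t1 + eps)
        else:
            sel = (self.times >= t0 - eps) & (self.times < t1 - eps)
        return np.bincount(self.neuron_ids[sel], minlength=self.n_neurons)

    def select_neurons(self, ids) -> "SpikeRaster":
        ids = np.asarray(ids)
        sel = np.isin(self.neuron_ids, ids)
        return SpikeRaster(self.neuron_ids[sel], self.times[sel], self.n_neurons)

    @staticmethod
    def concatenate(rasters: list["SpikeRaster"]) -> "SpikeRaster":
        n = rasters[0].n_neurons
        return SpikeRaster(
            np.concatenate([r.neuron_ids for r in rasters]),
            np.concatenate([r.times for r in rasters]),
            n,
        )


def bin_raster(raster: SpikeRaster, bin_width: float, window: tuple[float, float],
               neuron_ids=None) -> np.ndarray:
    """Binned boolean spike matrix (neurons x bins).

    ``bin_width`` in seconds; the window [t0, t1) must be an integer multiple
    of it. An entry is 1 iff the neuron spiked at least once in the bin (with
    1 ms bins the refractory period guarantees at most one spike per bin).
    """
    t0, t1 = window
    if t1 <= t0:
        raise ValueError("empty binning window")
    n_bins_f = (t1 - t0) / bin_width
    n_bins = int(round(n_bins_f))
    if abs(n_bins_f - n_bins) > 1e-6 * max(1.0, n_bins) or n_bins == 0:
        raise ValueError("window length must be a positive multiple of bin_width")
    sub = raster.in_window(t0, t1)
    if neuron_ids is None:
        rows = sub.neuron_ids
        n_rows = raster.n_neurons
    else:
        neuron_ids = np.asarray(neuron_ids)
        lookup = -np.ones(raster.n_neurons, dtype=np.int64)
        lookup[neuron_ids] = np.arange(len(neuron_ids))
        keep = lookup[sub.neuron_ids] >= 0
        rows = lookup[sub.neuron_ids[keep]]
        sub = SpikeRaster(sub.neuron_ids[keep], sub.times[keep], raster.n_neurons)
        n_rows = len(neuron_ids)
    cols = np.floor((sub.times - t0) / bin_width).astype(np.int64)
    cols = np.clip(cols, 0, n_bins - 1)  # guard exact right-edge rounding
    mat = np.zeros((n_rows, n_bins), dtype=np.int8)
    mat[rows, cols] = 1
    return mat
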