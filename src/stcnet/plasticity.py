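"""Calcium-based early-phase plasticity and synaptic tagging and capture.

Each E->E synapse carries an early-phase weight h [mV], a late-phase weight
z (dimensionless, scaled by h_0 to give mV), and a postsynaptic calcium
concentration c. The total weight is w = h + h_0 z.

Calcium jumps by c_pre per presynaptic spike (delivered with delay
t_c_delay) and by c_post per postsynaptic spike, and decays with tau_c.
The early phase relaxes slowly toward h_0 and undergoes noisy potentiation
(c above theta_p) toward h_max and depression (c above theta_d) toward 0.
A synapse is tagged while |h - h_0| exceeds theta_tag. Each neuron carries
a protein amount p that is synthesized while the summed early-phase change
of its incoming synapses exceeds a neuromodulator-dependent threshold
theta_pro(NM) = 1/(NM + 0.001), and the late phase grows toward 1 (tagged
for potentiation) or -0.5 (tagged for depression) at a rate proportional
to p. This captures the synaptic tagging-and-capture route from transient
early-phase change to consolidated late-phase change, gated by the amount
of neuromodulator present in the minutes-to-hours after learning.

All steppers are elementwise (scalar or array) forward Euler at dt, except
``fast_forward`` which advances the slow tag/protein/late-phase system over
a stimulation-free consolidation gap on a coarse step, with h following its
exact exponential relaxation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import ModelParams

Z_MIN, Z_MAX = -0.5, 1.0


@dataclass(frozen=True)
class NMSchedule:
    """Piecewise-constant neuromodulator concentration over time.

    ``onset_min`` is measured in minutes after the end of the learning
    stimulation; ``duration_min`` is a duration in minutes or ``"max"``
    (neuromodulator present for the remainder of the simulation).
    """

    level: float = 0.0
    onset_min: float = 0.0
    duration_min: float | str = "max"
    t_learn_end: float = 11.1  # absolute time [s] the onset is measured from

    def __post_init__(self) -> None:
        if self.level < 0:
            raise ValueError("NM level must be non-negative")
        if self.onset_min < 0:
            raise ValueError("NM onset must be non-negative")
        if self.duration_min != "max" and float(self.duration_min) < 0:
            raise ValueError("NM duration must be non-negative or 'max'")

    @property
    def t_on(self) -> float:
        return self.t_learn_end + 60.0 * self.onset_min

    @property
    def t_off(self) -> float:
        if self.duration_min == "max":
            return np.inf
        return self.t_on + 60.0 * float(self.duration_min)

    def __call__(self, t) -> np.ndarray | float:
        t = np.asarray(t, dtype=float)
        out = np.where((t >= self.t_on) & (t < self.t_off), self.level, 0.0)
        return out if out.ndim else float(out)


def protein_threshold(nm) -> np.ndarray | float:
    """Neuromodulator-dependent protein synthesis threshold [mV]:
    theta_pro(NM) = 1 / (NM + 0.001)."""
    nm = np.asarray(nm, dtype=float)
    if np.any(nm < 0):
        raise ValueError("NM must be non-negative")
    out = 1.0 / (nm + 0.001)
    return out if out.ndim else float(out)


def calcium_step(c, n_pre_arrivals, n_post_spikes, params: ModelParams):
    """One step of calcium dynamics: exponential decay plus spike-evoked jumps.

    ``n_pre_arrivals`` counts presynaptic spikes whose delayed (t_c_delay)
    calcium influx falls in this step; ``n_post_spikes`` counts postsynaptic
    spikes in this step.
    """
    c = np.asarray(c, dtype=float) * np.exp(-params.dt / params.tau_c)
    out = c + params.c_pre * np.asarray(n_pre_arrivals) \
            + params.c_post * np.asarray(n_post_spikes)
    return out if out.ndim else float(out)


def early_phase_drift(h, c, params: ModelParams):
    """Deterministic right-hand side of the early-phase equation, times tau_h."""
    p = params
    above_p = np.asarray(c) > p.theta_p
    above_d = np.asarray(c) > p.theta_d
    return (0.1 * (p.h_0 - h)
            + p.gamma_p * (p.h_max - h) * above_p
            - p.gamma_d * h * above_d)


def early_phase_step(h, c, params: ModelParams, noise_draw=0.0):
    """One Euler-Maruyama step of the early-phase weight.

    The noise term is active only while calcium exceeds theta_d or theta_p
    (one Heaviside each, so its variance doubles above both thresholds);
    ``noise_draw`` is a standard-normal draw. The result is clipped to
    [0, h_max].
    """
    p = params
    c = np.asarray(c)
    n_active = (c > p.theta_p).astype(float) + (c > p.theta_d).astype(float)
    drift = early_phase_drift(h, c, params)
    noise = p.sigma_pl * np.sqrt(n_active * p.dt / p.tau_h) * np.asarray(noise_draw)
    out = np.clip(h + (p.dt / p.tau_h) * drift + noise, 0.0, p.h_max)
    return out if out.ndim else float(out)


def tag_indicator(h, params: ModelParams):
    """Tag state of a synapse: +1 (LTP tag), -1 (LTD tag), 0 (untagged)."""
    h = np.asarray(h, dtype=float)
    out = np.where(h - params.h_0 > params.theta_tag, 1,
                   np.where(params.h_0 - h > params.theta_tag, -1, 0))
    return out if out.ndim else int(out)


def early_change_sums(h, post_ids, n_neurons: int, params: ModelParams) -> np.ndarray:
    """Per-neuron sum of |h - h_0| over incoming E->E synapses [mV]."""
    return np.bincount(post_ids, weights=np.abs(np.asarray(h) - params.h_0),
                       minlength=n_neurons)


def protein_step(p_amount, early_change_sum, nm, params: ModelParams, dt=None):
    """One Euler step of the protein amount:
    tau_p dp/dt = -p + alpha * Theta[sum - theta_pro(NM)]."""
    dt = params.dt if dt is None else dt
    synth = np.asarray(early_change_sum) > protein_threshold(nm)
    out = np.asarray(p_amount, dtype=float) + (dt / params.tau_p) * (
        -np.asarray(p_amount) + params.alpha_p * synth
    )
    out = np.clip(out, 0.0, params.alpha_p)
    return out if out.ndim else float(out)


def late_phase_step(z, h, p_amount, params: ModelParams, dt=None):
    """One Euler step of the late-phase weight.

    tau_z dz/dt = p (1 - z) Theta[(h - h_0) - theta_tag]
                - p (z + 0.5) Theta[(h_0 - h) - theta_tag];
    z moves only while the synapse is tagged and protein is available, and
    is clipped to [-0.5, 1] (the drift bounds).
    """
    dt = params.dt if dt is None else dt
    tag = tag_indicator(h, params)
    dz = np.where(tag == 1, np.asarray(p_amount) * (1.0 - np.asarray(z)),
                  np.where(tag == -1,
                           -np.asarray(p_amount) * (np.asarray(z) + 0.5), 0.0))
    out = np.clip(np.asarray(z, dtype=float) + (dt / params.tau_z) * dz, Z_MIN, Z_MAX)
    return out if out.ndim else float(out)


def total_weight(h, z, params: ModelParams):
    """Total E->E weight w = h + h_0 z [mV] and weight in percent of h_0."""
    w = np.asarray(h, dtype=float) + params.h_0 * np.asarray(z)
    percent = 100.0 * w / params.h_0
    if w.ndim:
        return w, percent
    return float(w), float(percent)


def tag_vanish_time(h_start: float, params: ModelParams) -> float:
    """Time [s] until |h - h_0| decays below theta_tag, from pure relaxation.

    Solves h_0 + (h_start - h_0) exp(-0.1 t / tau_h) crossing the tagging
    threshold; returns 0 for an untagged start.
    """
    dev = abs(h_start - params.h_0)
    if dev <= params.theta_tag:
        return 0.0
    return (params.tau_h / 0.1) * float(np.log(dev / params.theta_tag))


def fast_forward(h, z, p_amount, post_ids, n_neurons: int,
                 t_start: float, t_end: float, nm_schedule: NMSchedule,
                 params: ModelParams, dt_ff: float = 0.1):
    """Advance synapse and protein state over a stimulation-free gap.

    During consolidation there is no stimulation and calcium stays below
    both plasticity thresholds, so h relaxes exponentially toward h_0
    (exactly), while the tag indicator, the per-neuron early-change sums,
    the protein equation and the late-phase equation are integrated on the
    coarse step ``dt_ff``. The stochastic early-phase term is inactive
    (calcium subthreshold). Returns ``(h', z', p')``.
    """
    if t_end < t_start:
        raise ValueError("t_end must not precede t_start")
    h = np.asarray(h, dtype=float)
    z = np.asarray(z, dtype=float).copy()
    p_amount = np.asarray(p_amount, dtype=float).copy()
    post_ids = np.asarray(post_ids)

    # Pure relaxation is multiplicative on the deviation h - h_0, so the
    # per-neuron change sums scale by the same exponential factor and the
    # tagged set only shrinks; this lets each coarse step run on the (small)
    # initially tagged subset instead of all synapses.
    dev0 = h - params.h_0
    sums0 = early_change_sums(h, post_ids, n_neurons, params)
    tagged = np.nonzero(np.abs(dev0) > params.theta_tag)[0]
    tag_sign = np.sign(dev0[tagged])
    rate = 0.1 / params.tau_h

    n_steps = int(np.ceil((t_end - t_start) / dt_ff - 1e-12)) if t_end > t_start else 0
    t = t_start
    for k in range(n_steps):
        t_next = min(t_start + (k + 1) * dt_ff, t_end)
        step = t_next - t
        decay = np.exp(-rate * (t - t_start))
        # state at the start of the sub-step drives p and z across it
        still = np.abs(dev0[tagged]) * decay > params.theta_tag
        idx = tagged[still]
        sign = tag_sign[still]
        pp = p_amount[post_ids[idx]]
        dz = np.where(sign > 0, pp * (1.0 - z[idx]), -pp * (z[idx] + 0.5))
        z[idx] = np.clip(z[idx] + (step / params.tau_z) * dz, Z_MIN, Z_MAX)
        p_amount = protein_step(p_amount, sums0 * decay, nm_schedule(t), params,
                                dt=step)
        tagged, tag_sign = idx, sign
        t = t_next
    h = params.h_0 + dev0 * np.exp(-rate * (t_end - t_start))
    return h, z, p_amount
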