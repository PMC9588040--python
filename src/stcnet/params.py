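"""Model constants for the spiking network and its plastic synapses.

All membrane-related quantities are expressed in mV / ms-compatible SI units:
times in seconds, potentials in mV, currents in nA, resistance in MOhm
(so that R_m * I gives mV directly). Calcium, late-phase weight, protein
amount and neuromodulator concentration are dimensionless.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace, asdict


@dataclass(frozen=True)
class ModelParams:
    """All constants of the neuron, network and plasticity model.

    Defaults correspond to a cortical/hippocampal-like recurrent network of
    leaky integrate-and-fire neurons (1600 excitatory, 400 inhibitory, 10 %
    random connectivity) with calcium-based early-phase plasticity and
    tag/protein-gated late-phase plasticity on E->E synapses.
    """

    # -- integration ------------------------------------------------------
    dt: float = 0.0002           # time step [s]

    # -- neuron and static network ---------------------------------------
    tau_m: float = 0.010         # membrane time constant [s]
    tau_syn: float = 0.005       # synaptic (and input-current) time constant [s]
    t_ax_delay: float = 0.003    # axonal spike delay [s]
    t_ref: float = 0.002         # refractory period [s]
    R_m: float = 10.0            # membrane resistance [MOhm]
    V_rev: float = -65.0         # reversal (resting) potential [mV]
    V_reset: float = -70.0       # reset potential [mV]
    V_th: float = -55.0          # spiking threshold [mV]
    I_0: float = 0.15            # mean background current [nA]
    sigma_wn: float = 0.05       # background current noise scale [nA s^1/2]
    N_e: int = 1600              # number of excitatory neurons
    N_i: int = 400               # number of inhibitory neurons
    p_c: float = 0.1             # connection probability
    h_0: float = 4.20075         # baseline E->E coupling strength [mV]
    w_ei_factor: float = 2.0     # E->I weight, in units of h_0
    w_ie_factor: float = 4.0     # I->E weight, in units of h_0
    w_ii_factor: float = 4.0     # I->I weight, in units of h_0
    N_stim: int = 4              # putative input neurons per stimulated cell
    stim_gain: float = 24.0      # efficacy multiplier of one putative input
    f_recall: float = 100.0      # recall stimulation frequency [Hz]
    r: float = 0.5               # fraction of assembly stimulated at recall
    assembly_size: int = 150     # excitatory neurons receiving the learning stimulus

    # -- calcium dynamics --------------------------------------------------
    t_c_delay: float = 0.0188    # delay of presynaptically evoked calcium [s]
    c_pre: float = 0.6           # presynaptic calcium contribution
    c_post: float = 0.1655       # postsynaptic calcium contribution
    tau_c: float = 0.0488        # calcium time constant [s]

    # -- early-phase plasticity -------------------------------------------
    tau_h: float = 688.4         # early-phase time constant [s]
    gamma_p: float = 1645.6      # potentiation rate
    gamma_d: float = 313.1       # depression rate
    theta_p: float = 3.0         # calcium threshold for potentiation
    theta_d: float = 1.2         # calcium threshold for depression
    sigma_pl: float = 2.90436    # plasticity noise scale [mV]
    h_max: float = 10.0          # upper bound of the early-phase weight [mV]

    # -- late phase, tag and proteins -------------------------------------
    tau_p: float = 3600.0        # protein time constant [s]
    tau_z: float = 3600.0        # late-phase time constant [s]
    alpha_p: float = 1.0         # protein synthesis rate
    theta_tag: float = 0.840149  # tagging threshold [mV]

    # -- numerics ----------------------------------------------------------
    #: protein/late-phase substep, in units of dt (their time constants are
    #: hours, so a 5 ms update is numerically indistinguishable from dt)
    slow_update_every: int = 25

    @property
    def w_ei(self) -> float:
        """E->I coupling strength [mV]."""
        return self.w_ei_factor * self.h_0

    @property
    def w_ie(self) -> float:
        """I->E coupling strength [mV]."""
        return self.w_ie_factor * self.h_0

    @property
    def w_ii(self) -> float:
        """I->I coupling strength [mV]."""
        return self.w_ii_factor * self.h_0

    @property
    def n_total(self) -> int:
        return self.N_e + self.N_i

    @property
    def recall_size(self) -> int:
        """Number of assembly neurons stimulated at recall: round(r * assembly)."""
        return int(round(self.r * self.assembly_size))

    @property
    def refractory_steps(self) -> int:
        return int(round(self.t_ref / self.dt))

    def __post_init__(self) -> None:
        positive = (
            "dt tau_m tau_syn t_ax_delay t_ref R_m tau_c tau_h tau_p tau_z "
            "gamma_p gamma_d theta_p theta_d h_0 h_max"
        ).split()
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        for name in ("sigma_wn", "sigma_pl", "c_pre", "c_post", "f_recall",
                     "alpha_p", "theta_tag", "t_c_delay"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.V_reset >= self.V_th:
            raise ValueError("V_reset must be below V_th")
        if self.theta_d >= self.theta_p:
            raise ValueError("theta_d must be below theta_p")
        if not 0 < self.p_c <= 1:
            raise ValueError("p_c must lie in (0, 1]")
        if not 0 < self.r <= 1:
            raise ValueError("r must lie in (0, 1]")
        if self.N_e < 0 or self.N_i < 0 or self.N_stim < 0:
            raise ValueError("neuron counts must be non-negative")
        if self.assembly_size > self.N_e:
            raise ValueError("assembly_size cannot exceed N_e")
        if self.slow_update_every < 1:
            raise ValueError("slow_update_every must be at least 1")

    def with_updates(self, **kwargs) -> "ModelParams":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**d)


def scaled_down_params(**overrides) -> ModelParams:
    """A 4x smaller network preset for desk-scale experiments.

    400 excitatory / 100 inhibitory neurons with a 40-neuron assembly
    (20 recalled), connected with p_c = 0.4 so that per-neuron input counts
    (and with them the recurrent gain and the per-neuron early-phase change
    sums that drive protein synthesis) match the full-size network. Because
    the assembly provides 16 rather than 15 incoming synapses per neuron on
    average, absolute neuromodulator regimes shift only marginally (see
    ``scaled_nm_level``).
    """
    base = dict(N_e=400, N_i=100, assembly_size=40, p_c=0.4)
    base.update(overrides)
    return ModelParams(**base)


#: Ratio by which per-neuron incoming-from-assembly synapse counts change in
#: the scaled preset (40 * 0.4 = 16 versus 150 * 0.1 = 15); used to translate
#: neuromodulator levels so that the protein synthesis threshold sits in the
#: same regime relative to the attainable change sums.
SCALED_SUM_RATIO = (40.0 * 0.4) / (150.0 * 0.1)


def scaled_nm_level(nm_full: float, sum_ratio: float = SCALED_SUM_RATIO) -> float:
    """Translate a neuromodulator level from the full-size network to a
    scaled-down one by preserving theta_pro relative to the attainable
    early-phase change sums (theta_pro_scaled = sum_ratio * theta_pro_full).
    """
    if nm_full < 0:
        raise ValueError("NM must be non-negative")
    if nm_full == 0.0:
        return 0.0
    theta_full = 1.0 / (nm_full + 0.001)
    theta_scaled = sum_ratio * theta_full
    return 1.0 / theta_scaled - 0.001
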