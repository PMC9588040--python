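"""Random network topology and synapse subpopulation labels.

Neurons are indexed 0..N_e+N_i-1 with the excitatory block first. The core
assembly (the neurons that receive the learning stimulus) is the first
``assembly_size`` excitatory ids, and the recall set is its first
``round(r * assembly_size)`` ids. E->E synapses are partitioned into four
classes relative to the assembly:

- ``core_internal``: both pre- and postsynaptic neuron in the assembly;
- ``outgoing``: presynaptic in the assembly, postsynaptic excitatory outside;
- ``incoming``: presynaptic excitatory outside, postsynaptic in the assembly;
- ``control``: both ends excitatory and outside the assembly.

Neurons reached by significantly strengthened outgoing synapses are the
"support neurons" recruited during consolidation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .params import ModelParams

SYNAPSE_CLASSES = ("core_internal", "outgoing", "incoming", "control")


@dataclass
class Topology:
    """Directed random connectivity plus subpopulation bookkeeping.

    ``pre`` / ``post`` list every directed connection (at most one synapse
    per ordered pair, no self-connections). ``exc_mask`` labels neuron class.
    """

    n_total: int
    pre: np.ndarray          # presynaptic neuron id per connection
    post: np.ndarray         # postsynaptic neuron id per connection
    exc_mask: np.ndarray     # True for excitatory neurons
    assembly_ids: np.ndarray
    recall_ids: np.ndarray

    @property
    def n_connections(self) -> int:
        return len(self.pre)

    @property
    def ee_mask(self) -> np.ndarray:
        """Boolean mask over connections selecting E->E synapses."""
        return self.exc_mask[self.pre] & self.exc_mask[self.post]

    def assembly_mask(self) -> np.ndarray:
        m = np.zeros(self.n_total, dtype=bool)
        m[self.assembly_ids] = True
        return m

    def to_frame(self) -> pd.DataFrame:
        """Edge list with synapse class labels (E->E classes, else 'static')."""
        labels = np.full(self.n_connections, "static", dtype=object)
        ee = self.ee_mask
        labels[ee] = classify_synapses(self)
        return pd.DataFrame(
            {"pre_id": self.pre, "post_id": self.post, "class": labels}
        )


def build_network(params: ModelParams, seed: int) -> Topology:
    """Draw the directed random topology.

    Each ordered pair (j, i), j != i, is connected independently with
    probability ``p_c``. Identical seeds give identical topologies.
    """
    if params.assembly_size > params.N_e:
        raise ValueError("assembly size exceeds the excitatory population")
    n = params.n_total
    rng = np.random.default_rng(seed)
    adj = rng.random((n, n)) < params.p_c
    np.fill_diagonal(adj, False)
    pre, post = np.nonzero(adj)
    exc_mask = np.zeros(n, dtype=bool)
    exc_mask[: params.N_e] = True
    assembly_ids = np.arange(params.assembly_size)
    recall_ids = assembly_ids[: params.recall_size]
    return Topology(
        n_total=n,
        pre=pre.astype(np.int64),
        post=post.astype(np.int64),
        exc_mask=exc_mask,
        assembly_ids=assembly_ids,
        recall_ids=recall_ids,
    )


def classify_synapses(topology: Topology) -> np.ndarray:
    """Label every E->E synapse by its position relative to the core assembly.

    Returns an array of strings (one per E->E synapse, in the order induced
    by ``topology.ee_mask``); the four classes partition the E->E synapses
    exhaustively and exclusively.
    """
    ee = topology.ee_mask
    pre = topology.pre[ee]
    post = topology.post[ee]
    in_assembly = topology.assembly_mask()
    pre_in = in_assembly[pre]
    post_in = in_assembly[post]
    labels = np.empty(len(pre), dtype=object)
    labels[pre_in & post_in] = "core_internal"
    labels[pre_in & ~post_in] = "outgoing"
    labels[~pre_in & post_in] = "incoming"
    labels[~pre_in & ~post_in] = "control"
    return labels


def static_weight(pre_is_exc: bool, post_is_exc: bool, params: ModelParams) -> float:
    """Static coupling strength [mV] for synapse classes involving inhibition.

    E->E synapses are plastic and have no static weight (ValueError).
    """
    if pre_is_exc and post_is_exc:
        raise ValueError("E->E synapses are plastic; use the plasticity model")
    if pre_is_exc:
        return params.w_ei
    if post_is_exc:
        return params.w_ie
    return params.w_ii


def signed_static_weight_matrix(topology: Topology, params: ModelParams) -> np.ndarray:
    """Dense (pre, post) matrix of static weights with inhibitory sign.

    E->E entries are zero (they are delivered from the plastic synapse state);
    inhibitory weights enter the postsynaptic-potential trace negatively.
    """
    n = topology.n_total
    w = np.zeros((n, n))
    pre_exc = topology.exc_mask[topology.pre]
    post_exc = topology.exc_mask[topology.post]
    for mask, val in (
        (pre_exc & ~post_exc, params.w_ei),
        (~pre_exc & post_exc, -params.w_ie),
        (~pre_exc & ~post_exc, -params.w_ii),
    ):
        w[topology.pre[mask], topology.post[mask]] = val
    return w
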