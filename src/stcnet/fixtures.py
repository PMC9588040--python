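"""Synthetic rasters and weight tables for exercising the analysis suite.

The generator emulates the statistical structure the analyses consume
without running the spiking simulator: paired learning/recall binned
rasters with a controllable probability that a learning spike recurs in the
same bin at recall, optional low-rank temporal structure for the PCA
dimensionality estimate, and E->E weight tables with labeled synapse
classes and a controllable fraction of potentiated synapses per class.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .params import ModelParams
from .topology import SYNAPSE_CLASSES


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a synthetic raster/weight fixture."""

    n_neurons: int = 100
    n_bins: int = 100
    rate_hz: float = 40.0            # per-neuron rate of the learning raster
    overlap: float = 0.5             # P(learning spike recurs in same recall bin)
    rank: int | None = None          # latent temporal rank (None = iid)
    bin_width: float = 0.001         # [s]
    frac_potentiated: dict = field(default_factory=dict)  # per synapse class
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.overlap <= 1.0:
            raise ValueError("overlap must lie in [0, 1]")
        if self.rank is not None and self.rank > min(self.n_neurons, self.n_bins):
            raise ValueError("rank cannot exceed the raster dimensions")
        if self.rate_hz * self.bin_width > 1.0:
            raise ValueError("rate implies more than one spike per bin")
        if self.rate_hz < 0:
            raise ValueError("rate must be non-negative")


def paired_rasters(spec: FixtureSpec) -> tuple[np.ndarray, np.ndarray]:
    """Learning/recall 0/1 raster pair with the requested bin overlap.

    Each learning spike recurs at the same recall bin with probability
    ``overlap``; otherwise the recall spike is moved to a uniformly chosen
    bin, so per-neuron spike counts are preserved in expectation.
    """
    rng = np.random.default_rng(spec.seed)
    p_spike = spec.rate_hz * spec.bin_width
    if spec.rank is None:
        learn = (rng.random((spec.n_neurons, spec.n_bins)) < p_spike)
    else:
        # low-rank structure: each neuron mixes `rank` latent bin profiles
        profiles = rng.random((spec.rank, spec.n_bins))
        loads = rng.dirichlet(np.ones(spec.rank), size=spec.n_neurons)
        prob = loads @ profiles
        prob *= p_spike * spec.n_bins / np.maximum(prob.sum(1, keepdims=True), 1e-12)
        learn = rng.random((spec.n_neurons, spec.n_bins)) < np.clip(prob, 0, 1)
    recall = np.zeros_like(learn)
    keep = rng.random(learn.shape) < spec.overlap
    recall |= learn & keep
    # displaced spikes land in uniformly random bins
    n_moved = (learn & ~keep).sum(axis=1)
    for i, k in enumerate(n_moved):
        if k:
            recall[i, rng.integers(0, spec.n_bins, size=k)] = True
    return learn.astype(np.int8), recall.astype(np.int8)


def low_rank_raster(n_neurons: int, n_bins: int, rank: int,
                    seed=0) -> np.ndarray:
    """Real-valued raster-shaped matrix of exact rank ``rank`` (for PCA tests)."""
    rng = np.random.default_rng(seed)
    u = rng.standard_normal((n_neurons, rank))
    v = rng.standard_normal((rank, n_bins))
    return u @ v


def weight_table(spec: FixtureSpec, params: ModelParams | None = None) -> pd.DataFrame:
    """Synthetic E->E weight table with labeled synapse classes.

    One row per synapse: (pre_id, post_id, h, z, class). Within each class a
    fraction ``frac_potentiated[class]`` (default 0) carries a potentiated
    early phase (2 h_0) and a consolidated late phase (z = 1); the rest sit
    at baseline.
    """
    params = params or ModelParams()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_neurons
    n_assembly = max(1, n // 4)
    pre, post = np.nonzero(rng.random((n, n)) < 0.2)
    keep = pre != post
    pre, post = pre[keep], post[keep]
    in_asm = lambda ids: ids < n_assembly
    cls = np.where(in_asm(pre) & in_asm(post), "core_internal",
                   np.where(in_asm(pre), "outgoing",
                            np.where(in_asm(post), "incoming", "control")))
    h = np.full(len(pre), params.h_0)
    z = np.zeros(len(pre))
    for c in SYNAPSE_CLASSES:
        frac = spec.frac_potentiated.get(c, 0.0)
        idx = np.nonzero(cls == c)[0]
        pot = idx[rng.random(len(idx)) < frac]
        h[pot] = 2.0 * params.h_0
        z[pot] = 1.0
    return pd.DataFrame({"pre_id": pre, "post_id": post, "h": h, "z": z,
                         "class": cls})


def generate_fixture(spec: FixtureSpec,
                     params: ModelParams | None = None) -> dict:
    """Paired rasters plus a weight table, as one bundle."""
    learn, recall = paired_rasters(spec)
    return {"learning": learn, "recall": recall,
            "weights": weight_table(spec, params)}
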