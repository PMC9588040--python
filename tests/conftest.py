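"""Shared fixtures.

The expensive fixture is ``nm_sweep_bank``: ten independent scaled-down
networks, each learned once and branched over neuromodulator levels
{none, low, high} for both the 10 s and the 8 h recall condition. It is
computed once per session and shared by the protocol-level and
acceptance-level tests.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pytest

from stcnet import (ModelParams, NMSchedule, ProtocolTimeline,
                    build_network, scaled_down_params)
from stcnet.protocol import run_experiment_set

NM_LEVELS = (0.0, 0.06, 0.18)
N_BANK_NETWORKS = 10


@pytest.fixture(scope="session")
def default_params() -> ModelParams:
    return ModelParams()


@pytest.fixture(scope="session")
def scaled_params() -> ModelParams:
    return scaled_down_params()


@pytest.fixture(scope="session")
def tiny_params() -> ModelParams:
    """A very small network for mechanics-level protocol tests."""
    return scaled_down_params(N_e=48, N_i=12, assembly_size=12)


@pytest.fixture(scope="session")
def nm_sweep_bank(scaled_params):
    """dict[(recall, nm_level)] -> list of RunRecords over 10 networks."""
    tl8 = replace(ProtocolTimeline().with_recall("8h"), dt_ff=1.0)
    tl10 = ProtocolTimeline().with_recall("10s")
    variants = [(tl8, NMSchedule(level=l)) for l in NM_LEVELS] \
        + [(tl10, NMSchedule(level=l)) for l in NM_LEVELS]
    keys = [("8h", l) for l in NM_LEVELS] + [("10s", l) for l in NM_LEVELS]
    bank = {k: [] for k in keys}
    for net in range(N_BANK_NETWORKS):
        seed = 1000 + net
        topo = build_network(scaled_params, seed)
        recs = run_experiment_set(scaled_params, topo, variants, seed)
        for key, rec in zip(keys, recs):
            bank[key].append(rec)
    return bank


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
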