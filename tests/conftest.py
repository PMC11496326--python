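"""Shared fixtures: small ground-truth networks and simulated recordings.

Heavier simulations are session-scoped so the suite pays for them once.
"""

import numpy as np
import pytest

from mtlnet import synth
from mtlnet.recording import EpochSet


@pytest.fixture(scope="session")
def two_region_spec():
    return synth.RegionSpec({"AMG": 2, "HPC": 2})


@pytest.fixture(scope="session")
def four_region_gt():
    """4 regions x 2 contacts, single edge AMG->HPC (strength 0.4, order 3)."""
    spec = synth.RegionSpec({"AMG": 2, "HPC": 2, "TP": 2, "PHP": 2})
    edges = [synth.CouplingEdge("AMG", "HPC", 0.4, lag=1)]
    return synth.make_ground_truth_mvar(spec, edges, order=3, seed=0,
                                        sampling_rate=250.0)


@pytest.fixture(scope="session")
def mtl_recording():
    """600 s recording at 2000 Hz from the summary mesiotemporal network."""
    gt = synth.mesiotemporal_ground_truth(seed=1)
    rec = synth.simulate_mvar_recording(gt, 600.0, seed=1)
    return gt, rec


def make_epochset(data_list, fs, labels, epoch_length=None, **kw):
    """Construct an EpochSet directly from raw arrays (test helper)."""
    n_samp = data_list[0].shape[0]
    if epoch_length is None:
        epoch_length = n_samp / fs
    return EpochSet(
        epochs=list(data_list),
        epoch_length=epoch_length,
        sampling_rate=fs,
        channel_labels=list(labels),
        start_times=[i * epoch_length for i in range(len(data_list))],
        **kw,
    )


@pytest.fixture
def epochs_from_array():
    return make_epochset


@pytest.fixture
def rng():
    """Fresh deterministic generator per test (order-independent)."""
    return np.random.default_rng(12345)
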