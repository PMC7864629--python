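"""Shared fixtures: expensive simulations are session-scoped so the
conductance-based model runs once per suite."""

from __future__ import annotations

import numpy as np
import pytest

from ephyskit.simulate.mea import SpikeTrainGenParams, simulate_mea_well
from ephyskit.simulate.neuron import (NeuronModelParams, StimulusProtocol,
                                      simulate_neuron)


@pytest.fixture(scope="session")
def ramp_trace():
    """One ramp-evoked sweep of the default model (25 kHz, noiseless)."""
    return simulate_neuron(NeuronModelParams(),
                           StimulusProtocol(kind="ramp"), seed=0)[0]


@pytest.fixture(scope="session")
def gsk_grid_traces():
    """Pulse-train sweeps across the SK-conductance grid {0, 1, 2, 4} nS,
    integrated as one batch (all other parameters fixed)."""
    grid = np.array([0.0, 1.0, 2.0, 4.0])
    params = NeuronModelParams(g_sk_ns=grid)
    traces = simulate_neuron(params, StimulusProtocol(kind="pulse_train"),
                             seed=0)
    return dict(zip(grid, traces))


@pytest.fixture(scope="session")
def benchmark_well():
    """The seeded synthetic MEA well used for burst-detector benchmarking:
    6 bursts/min, 10 spikes/burst, 10 ms intra-burst ISI, 0.5 Hz tonic,
    300 s, 64 electrodes."""
    params = SpikeTrainGenParams(
        n_electrodes=64, duration_s=300.0, active_fraction=1.0,
        tonic_rate_hz=0.5, burst_rate_per_min=6.0,
        spikes_per_burst_mean=10.0, intra_burst_isi_ms=10.0, seed=42)
    return simulate_mea_well(params)
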