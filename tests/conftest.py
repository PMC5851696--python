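import numpy as np
import pytest

from spikeinf.datatypes import NetworkGraph, SpikeTrainSet
from spikeinf.kernelize import KernelBlock


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_spikes():
    """Five neurons, 50 ms, fixed hand-written spike times."""
    return SpikeTrainSet(
        n=5,
        duration_ms=50.0,
        spikes=[
            np.array([0.0, 10.0, 31.0]),
            np.array([5.0, 22.0]),
            np.array([]),
            np.array([2.0, 3.0, 4.0, 40.0]),
            np.array([49.0]),
        ],
    )


@pytest.fixture
def two_neuron_graph():
    """Edge 0 -> 1, weight +25 mV, delay 1 ms."""
    w = np.zeros((2, 2))
    d = np.zeros((2, 2))
    w[1, 0] = 25.0
    d[1, 0] = 1.0
    return NetworkGraph(n=2, weight=w, delay=d, d_max=2.0,
                        neuron_type=np.array(["excitatory", "excitatory"],
                                             dtype=object))


def make_block(K, y):
    """KernelBlock from a raw non-negative kernel matrix and +/-1 labels."""
    K = np.asarray(K, dtype=float)
    y = np.asarray(y, dtype=np.int8)
    return KernelBlock(
        t_start=0, t_end=len(y), rows=np.arange(len(y)),
        Kp=K, y=y, A=y[:, None] * K,
        row_norms_sq=np.einsum("ij,ij->i", K, K),
    )


@pytest.fixture
def random_instance(rng):
    """Random 40-row x 8-column constraint instance."""
    def _make(T=40, n=8, seed=None):
        r = np.random.default_rng(seed) if seed is not None else rng
        K = np.abs(r.normal(size=(T, n)))
        y = np.where(r.random(T) < 0.3, 1, -1)
        return make_block(K, y)
    return _make
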