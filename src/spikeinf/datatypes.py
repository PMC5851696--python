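"""Core in-memory containers shared by every module.

A :class:`SpikeTrainSet` is the observable data — per-neuron sorted spike
times over a recording window.  A :class:`NetworkGraph` is the recovery
target — signed synaptic weights, propagation delays and per-neuron
excitatory/inhibitory types.  A :class:`RunConfig` is flat artifact
plumbing for reproducible pipelines.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = ["SpikeTrainSet", "NetworkGraph", "RunConfig"]


@dataclass
class SpikeTrainSet:
    """Per-neuron spike times (ms) over a recording of ``duration_ms``.

    ``spikes[i]`` is a strictly ascending float array of neuron *i*'s
    spike times, all in ``[0, duration_ms)``.  Neuron ids are ``0..n-1``.
    """

    n: int
    duration_ms: float
    spikes: list[np.ndarray]

    def __post_init__(self) -> None:
        if self.n != len(self.spikes):
            raise ValueError(f"n={self.n} but {len(self.spikes)} spike lists given")
        self.spikes = [np.asarray(s, dtype=np.float64) for s in self.spikes]
        self.validate()

    def validate(self) -> None:
        for i, s in enumerate(self.spikes):
            if s.size == 0:
                continue
            if np.any(np.diff(s) <= 0):
                raise ValueError(f"spike times of neuron {i} not strictly ascending")
            if s[0] < 0 or s[-1] >= self.duration_ms:
                raise ValueError(
                    f"neuron {i} has spikes outside [0, {self.duration_ms})"
                )

    @property
    def counts(self) -> np.ndarray:
        """Total spike count per neuron (alpha_i * T of the rate assumption)."""
        return np.array([len(s) for s in self.spikes], dtype=np.int64)

    @property
    def rates_hz(self) -> np.ndarray:
        """Mean firing rate per neuron in Hz."""
        return self.counts / (self.duration_ms / 1000.0)

    def to_bins(self, dt_ms: float) -> list[np.ndarray]:
        """Spike bin indices per neuron on a grid of step ``dt_ms``."""
        return [np.floor(s / dt_ms).astype(np.int64) for s in self.spikes]

    def n_bins(self, dt_ms: float) -> int:
        return int(np.ceil(self.duration_ms / dt_ms))

    def binary_matrix(self, dt_ms: float) -> np.ndarray:
        """T x n 0/1 spike-indicator matrix (at most one spike per bin)."""
        T = self.n_bins(dt_ms)
        S = np.zeros((T, self.n), dtype=np.float64)
        for i, b in enumerate(self.to_bins(dt_ms)):
            S[b, i] = 1.0
        return S

    def truncated(self, duration_ms: float) -> "SpikeTrainSet":
        """Prefix of the recording: spikes before ``duration_ms`` only."""
        if duration_ms > self.duration_ms:
            raise ValueError("cannot extend a recording by truncation")
        return SpikeTrainSet(
            n=self.n,
            duration_ms=duration_ms,
            spikes=[s[s < duration_ms] for s in self.spikes],
        )

    def subset(self, ids: Sequence[int]) -> "SpikeTrainSet":
        """Restrict to the given neuron ids (re-indexed 0..len(ids)-1)."""
        ids = list(ids)
        return SpikeTrainSet(
            n=len(ids),
            duration_ms=self.duration_ms,
            spikes=[self.spikes[i].copy() for i in ids],
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SpikeTrainSet):
            return NotImplemented
        return (
            self.n == other.n
            and np.isclose(self.duration_ms, other.duration_ms)
            and all(np.array_equal(a, b) for a, b in zip(self.spikes, other.spikes))
        )


EXC = "excitatory"
INH = "inhibitory"


@dataclass
class NetworkGraph:
    """Ground-truth synaptic graph.

    ``weight[i, j]`` is the weight (mV) of the directed connection
    ``j -> i`` (incoming weight g_j of post-synaptic neuron i);
    ``delay[i, j]`` is its propagation delay in ms, in ``(0, d_max]``.
    ``neuron_type[j]`` is ``"excitatory"`` or ``"inhibitory"`` and, by
    Dale's principle, fixes the sign of every nonzero entry of column j.
    """

    n: int
    weight: np.ndarray
    delay: np.ndarray
    d_max: float
    neuron_type: np.ndarray  # array of str, length n

    def __post_init__(self) -> None:
        self.weight = np.asarray(self.weight, dtype=np.float64)
        self.delay = np.asarray(self.delay, dtype=np.float64)
        self.neuron_type = np.asarray(self.neuron_type, dtype=object)
        self.validate()

    def validate(self) -> None:
        if self.weight.shape != (self.n, self.n):
            raise ValueError("weight matrix shape mismatch")
        if self.delay.shape != (self.n, self.n):
            raise ValueError("delay matrix shape mismatch")
        if np.any(np.diag(self.weight) != 0):
            raise ValueError("self-edges are not allowed")
        nz = self.weight != 0
        if np.any(self.delay[nz] <= 0) or np.any(self.delay[nz] > self.d_max):
            raise ValueError(f"delays of edges must lie in (0, {self.d_max}]")
        for j in range(self.n):
            col = self.weight[:, j]
            if self.neuron_type[j] == EXC and np.any(col < 0):
                raise ValueError(f"excitatory neuron {j} has a negative outgoing edge")
            if self.neuron_type[j] == INH and np.any(col > 0):
                raise ValueError(f"inhibitory neuron {j} has a positive outgoing edge")

    @property
    def is_excitatory(self) -> np.ndarray:
        return self.neuron_type == EXC

    @property
    def n_exc_edges(self) -> int:
        return int(np.sum(self.weight > 0))

    @property
    def n_inh_edges(self) -> int:
        return int(np.sum(self.weight < 0))

    @property
    def delta(self) -> float:
        """Inhibitory magnitude delta = n_exc/n_inh (edge counts) for the
        default +1/-delta builder; computed from realized signs."""
        n_inh = self.n_inh_edges
        if n_inh == 0:
            raise ValueError("no inhibitory edges: delta undefined")
        return self.n_exc_edges / n_inh

    def edge_type(self, post: int, pre: int) -> str:
        w = self.weight[post, pre]
        if w > 0:
            return "excitatory"
        if w < 0:
            return "inhibitory"
        return "void"

    def incoming_types(self, post: int) -> np.ndarray:
        """Type of every candidate incoming edge j -> post (j != post):
        'excitatory', 'void' or 'inhibitory', indexed by pre id."""
        t = np.array(
            ["void"] * self.n, dtype=object
        )
        t[self.weight[post, :] > 0] = "excitatory"
        t[self.weight[post, :] < 0] = "inhibitory"
        return t

    def subset(self, ids: Sequence[int]) -> "NetworkGraph":
        ids = np.asarray(list(ids), dtype=np.int64)
        return NetworkGraph(
            n=len(ids),
            weight=self.weight[np.ix_(ids, ids)].copy(),
            delay=self.delay[np.ix_(ids, ids)].copy(),
            d_max=self.d_max,
            neuron_type=self.neuron_type[ids].copy(),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, NetworkGraph):
            return NotImplemented
        return (
            self.n == other.n
            and np.array_equal(self.weight, other.weight)
            and np.array_equal(self.delay, other.delay)
            and self.d_max == other.d_max
            and np.array_equal(self.neuron_type, other.neuron_type)
        )


@dataclass
class RunConfig:
    """Flat key-value run configuration; every entry is str/int/float.

    A seed is always present so that any artifact is reproducible from
    its logged configuration alone.
    """

    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if "seed" not in self.params:
            raise ValueError("RunConfig requires a 'seed' entry")

    def __getitem__(self, key):
        return self.params[key]

    def get(self, key, default=None):
        return self.params.get(key, default)

    def updated(self, **kwargs) -> "RunConfig":
        p = dict(self.params)
        p.update(kwargs)
        return RunConfig(p)
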