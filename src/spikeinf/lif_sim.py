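"""Balanced random networks and leaky integrate-and-fire simulation.

The simulator integrates, on a fixed grid of step ``dt_ms``, the membrane
potential

    h_i(t) = h0 + sum_j g_ij * K_j(t) + v_i(t),

where ``K_j`` is an exponentially decaying synaptic kernel (time constant
``tau_m``) accumulated over pre-synaptic spikes delivered with per-edge
propagation delays, and ``v`` is additive membrane noise.  A deterministic
neuron fires when ``h >= theta``; a stochastic neuron fires with
probability ``f_s(h - theta)`` for an increasing gain function ``f_s``
(sigmoid by default).  After an own spike the membrane is reset: all
kernel accumulation restarts, so only pre-synaptic spikes emitted
*strictly after* the neuron's last own spike contribute.

Because an isolated noiseless network is silent, sustained activity comes
from an optional per-neuron independent background Poisson drive
(``drive_rate`` events/s of weight ``drive_weight`` mV, filtered through
the same membrane kernel); it can be mean-centered so that the effective
disturbance is zero-mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .datatypes import EXC, INH, NetworkGraph, SpikeTrainSet

__all__ = [
    "LIfParams",
    "NoiseConfig",
    "StochasticFiring",
    "HiddenTraffic",
    "MembraneTrace",
    "generate_network",
    "simulate_deterministic",
    "simulate_stochastic",
    "attach_hidden",
    "hide_neurons",
]


@dataclass
class LIfParams:
    """Membrane parameters: resting potential, threshold, time constant,
    integration step, and whether an own spike resets accumulation."""

    h0: float = 0.0
    theta: float = 20.0
    tau_m: float = 20.0
    dt_ms: float = 1.0
    reset: bool = True

    def __post_init__(self) -> None:
        if self.theta <= self.h0:
            raise ValueError("theta must exceed h0")
        if self.tau_m <= 0 or self.dt_ms <= 0:
            raise ValueError("tau_m and dt_ms must be positive")

    @property
    def rho(self) -> float:
        """Per-bin kernel decay factor exp(-dt/tau_m)."""
        return float(np.exp(-self.dt_ms / self.tau_m))


@dataclass
class NoiseConfig:
    """Membrane noise and background drive.

    ``sigma_v`` is the per-bin noise std (mV); ``delta_v_ms`` > 0 selects
    a moving-average colored noise whose correlation vanishes beyond that
    window (0 = white).  ``drive_rate`` (Hz) and ``drive_weight`` (mV)
    define the background Poisson drive; ``center_drive`` subtracts its
    stationary mean so the residual disturbance is zero-mean.
    """

    sigma_v: float = 0.0
    delta_v_ms: float = 0.0
    drive_rate: float = 0.0
    drive_weight: float = 0.0
    center_drive: bool = False

    def __post_init__(self) -> None:
        if self.sigma_v < 0 or self.delta_v_ms < 0 or self.drive_rate < 0:
            raise ValueError("noise parameters must be non-negative")
        if not np.all(np.isfinite([self.sigma_v, self.delta_v_ms,
                                   self.drive_rate, self.drive_weight])):
            raise ValueError("noise parameters must be finite")


@dataclass
class StochasticFiring:
    """Increasing firing probability f_s; the default is the logistic
    sigmoid f_s(x) = 1 / (1 + exp(-beta * x)) with gain ``beta`` 1/mV."""

    family: str = "sigmoid"
    beta: float = 1.0

    def __post_init__(self) -> None:
        if self.family != "sigmoid":
            raise ValueError(f"unknown firing family {self.family!r}")
        if self.beta <= 0:
            raise ValueError("beta must be positive")


@dataclass
class HiddenTraffic:
    """Bookkeeping for unobserved neurons attached to a visible network:
    ids of the hidden units and the hidden-to-visible weight block g',
    balanced so that E[g'] = 0."""

    m: int
    hidden_ids: np.ndarray
    gprime: np.ndarray  # (n_visible, m) weight block


@dataclass
class MembraneTrace:
    """Per-neuron membrane potential u_t = h(t) - h0 on the grid
    (diagnostic; recorded only on request)."""

    dt_ms: float
    u: np.ndarray  # (T, n)


def generate_network(
    n: int,
    frac_exc: float = 0.8,
    p_conn: float = 0.1,
    d_max: float = 2.0,
    seed: int = 0,
) -> NetworkGraph:
    """Balanced Erdos-Renyi network obeying Dale's principle.

    ``round(frac_exc * n)`` neurons are excitatory; each ordered pair
    j -> i (j != i) is connected with probability ``p_conn``.  Excitatory
    edges weigh +1 mV, inhibitory edges -delta mV with
    delta = n_exc_edges / n_inh_edges from the realized edge counts, so
    the total weight sums to zero.  Delays are i.i.d. uniform on
    (0, d_max].
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if not 0 < frac_exc < 1:
        raise ValueError("frac_exc must be in (0, 1)")
    if not 0 < p_conn <= 1:
        raise ValueError("p_conn must be in (0, 1]")
    if d_max <= 0:
        raise ValueError("d_max must be positive")

    rng = np.random.default_rng(seed)
    n_exc = int(round(frac_exc * n))
    neuron_type = np.array([EXC] * n_exc + [INH] * (n - n_exc), dtype=object)
    neuron_type = neuron_type[rng.permutation(n)]

    adj = rng.random((n, n)) < p_conn  # adj[i, j]: j -> i
    np.fill_diagonal(adj, False)

    exc_cols = neuron_type == EXC
    n_exc_edges = int(adj[:, exc_cols].sum())
    n_inh_edges = int(adj[:, ~exc_cols].sum())
    if n_inh_edges == 0:
        raise ValueError("no inhibitory edges realized: delta undefined")
    if n_exc_edges == 0:
        raise ValueError("no excitatory edges realized: network degenerate")
    delta = n_exc_edges / n_inh_edges

    weight = np.zeros((n, n))
    weight[:, exc_cols] = 1.0
    weight[:, ~exc_cols] = -delta
    weight[~adj] = 0.0

    delay = np.zeros((n, n))
    delay[adj] = d_max * (1.0 - rng.random(int(adj.sum())))  # uniform (0, d_max]

    return NetworkGraph(n=n, weight=weight, delay=delay, d_max=d_max,
                        neuron_type=neuron_type)


@njit(cache=True)
def _lif_loop(
    T, n, rho, theta_minus_h0, w, dbins, D,
    lam_drive, drive_weight, drive_mean,
    sigma, noise_pre, use_noise_pre,
    forced, use_forced,
    stochastic, beta, reset,
    record, trace, seed,
):
    """Grid-stepped LIF loop shared by the deterministic and stochastic
    simulators.  Returns a (T, n) uint8 spike indicator matrix.

    Reset semantics: when neuron i fires at bin t, its synaptic and drive
    accumulators clear and all in-transit arrivals to i (emitted at bins
    <= t) are dropped, so only traffic emitted strictly after t counts.
    """
    np.random.seed(seed)
    spikes = np.zeros((T, n), dtype=np.uint8)
    acc = np.zeros(n)
    drv = np.zeros(n)
    buf = np.zeros((D, n))
    h = np.zeros(n)
    fired = np.zeros(n, dtype=np.uint8)

    for t in range(T):
        c = t % D
        for i in range(n):
            acc[i] = acc[i] * rho + buf[c, i]
            buf[c, i] = 0.0
            if lam_drive > 0.0:
                k = np.random.poisson(lam_drive)
                drv[i] = drv[i] * rho + k * drive_weight
            h[i] = acc[i] + drv[i] - drive_mean
            if use_noise_pre:
                h[i] += noise_pre[t, i]
            elif sigma > 0.0:
                h[i] += sigma * np.random.normal()

        for i in range(n):
            if stochastic:
                x = beta * (h[i] - theta_minus_h0)
                if x >= 0.0:
                    p = 1.0 / (1.0 + np.exp(-x))
                else:
                    ex = np.exp(x)
                    p = ex / (1.0 + ex)
                fired[i] = 1 if np.random.random() < p else 0
            else:
                fired[i] = 1 if h[i] >= theta_minus_h0 else 0
            if use_forced and forced[t, i]:
                fired[i] = 1
            spikes[t, i] = fired[i]
            if record:
                trace[t, i] = h[i]

        # deliver outgoing spikes, then apply resets (a reset also drops
        # same-bin arrivals: contributions must be emitted strictly later)
        for j in range(n):
            if fired[j]:
                for i in range(n):
                    if w[i, j] != 0.0:
                        buf[(t + dbins[i, j]) % D, i] += w[i, j]
        if reset:
            for i in range(n):
                if fired[i]:
                    acc[i] = 0.0
                    drv[i] = 0.0
                    for d in range(D):
                        buf[d, i] = 0.0
    return spikes


def _delay_bins(graph: NetworkGraph, dt_ms: float) -> np.ndarray:
    """Delays rounded up to whole bins (>= 1 bin for existing edges)."""
    db = np.zeros((graph.n, graph.n), dtype=np.int64)
    nz = graph.weight != 0
    db[nz] = np.maximum(1, np.ceil(graph.delay[nz] / dt_ms).astype(np.int64))
    return db


def _colored_noise(rng, T, n, sigma, window_bins):
    """Moving-average noise: per-bin std sigma, correlation vanishing
    beyond ``window_bins`` bins."""
    k = max(1, int(window_bins))
    white = rng.standard_normal((T + k - 1, n))
    kernel = np.ones(k) / np.sqrt(k)
    out = np.empty((T, n))
    for i in range(n):
        out[:, i] = np.convolve(white[:, i], kernel, mode="valid")
    return sigma * out


def _run(
    graph: NetworkGraph,
    lif: LIfParams,
    noise: NoiseConfig,
    duration_ms: float,
    seed: int,
    stochastic: bool,
    beta: float = 1.0,
    forced_spikes=None,
    record_trace: bool = False,
):
    if duration_ms <= 0:
        raise ValueError("duration_ms must be positive")
    T = int(np.ceil(duration_ms / lif.dt_ms))
    n = graph.n
    dbins = _delay_bins(graph, lif.dt_ms)
    D = int(max(1, dbins.max()))

    rng = np.random.default_rng(seed)
    lam = noise.drive_rate * lif.dt_ms / 1000.0
    rho = lif.rho
    drive_mean = lam * noise.drive_weight / (1.0 - rho) if noise.center_drive else 0.0

    use_noise_pre = noise.sigma_v > 0 and noise.delta_v_ms > 0
    if use_noise_pre:
        window = noise.delta_v_ms / lif.dt_ms
        noise_pre = _colored_noise(rng, T, n, noise.sigma_v, window)
    else:
        noise_pre = np.zeros((1, 1))

    use_forced = forced_spikes is not None
    if use_forced:
        forced = np.zeros((T, n), dtype=np.uint8)
        for i, times in (
            forced_spikes.items() if isinstance(forced_spikes, dict)
            else enumerate(forced_spikes)
        ):
            for t_ms in times:
                if not 0 <= t_ms < duration_ms:
                    raise ValueError(f"forced spike at {t_ms} outside [0, {duration_ms})")
                forced[int(t_ms // lif.dt_ms), i] = 1
    else:
        forced = np.zeros((1, 1), dtype=np.uint8)

    trace = np.zeros((T, n)) if record_trace else np.zeros((1, 1))
    loop_seed = int(rng.integers(0, 2**31 - 1))

    spikes_mat = _lif_loop(
        T, n, rho, lif.theta - lif.h0, graph.weight, dbins, D,
        lam, noise.drive_weight, drive_mean,
        noise.sigma_v, noise_pre, use_noise_pre,
        forced, use_forced,
        stochastic, beta, lif.reset,
        record_trace, trace, loop_seed,
    )

    spike_lists = [
        np.nonzero(spikes_mat[:, i])[0].astype(np.float64) * lif.dt_ms
        for i in range(n)
    ]
    sts = SpikeTrainSet(n=n, duration_ms=T * lif.dt_ms, spikes=spike_lists)
    mt = MembraneTrace(dt_ms=lif.dt_ms, u=trace) if record_trace else None
    return sts, mt


def simulate_deterministic(
    graph: NetworkGraph,
    lif: LIfParams,
    noise: NoiseConfig,
    duration_ms: float,
    seed: int = 0,
    forced_spikes=None,
    record_trace: bool = False,
) -> tuple[SpikeTrainSet, MembraneTrace | None]:
    """Deterministic-noisy LIF dynamics: neuron i fires at bin t iff
    h_i(t) >= theta.  ``forced_spikes`` (dict id -> times or list of
    per-neuron time lists) are injected verbatim in addition to
    threshold-driven firing, for hand-checkable fixtures."""
    return _run(graph, lif, noise, duration_ms, seed, stochastic=False,
                forced_spikes=forced_spikes, record_trace=record_trace)


def simulate_stochastic(
    graph: NetworkGraph,
    lif: LIfParams,
    firing: StochasticFiring,
    noise: NoiseConfig,
    duration_ms: float,
    seed: int = 0,
    forced_spikes=None,
    record_trace: bool = False,
) -> SpikeTrainSet:
    """Stochastic LIF dynamics: per-bin Bernoulli firing with probability
    f_s(h - theta)."""
    sts, _ = _run(graph, lif, noise, duration_ms, seed, stochastic=True,
                  beta=firing.beta, forced_spikes=forced_spikes,
                  record_trace=record_trace)
    return sts


def attach_hidden(
    graph: NetworkGraph,
    m: int,
    frac_exc: float = 0.8,
    p_conn: float = 0.1,
    d_max: float | None = None,
    seed: int = 0,
) -> tuple[NetworkGraph, HiddenTraffic]:
    """Append ``m`` unobserved source neurons feeding the visible network.

    Hidden neurons receive no recurrent input (their spiking comes from
    the background drive alone, so their traffics are mutually
    independent) and project to visible neurons with balanced +1/-delta'
    weights, making the hidden weight block zero-mean by construction.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    rng = np.random.default_rng(seed)
    n = graph.n
    d_max = graph.d_max if d_max is None else d_max
    m_exc = int(round(frac_exc * m))
    h_type = np.array([EXC] * m_exc + [INH] * (m - m_exc), dtype=object)
    h_type = h_type[rng.permutation(m)]

    adj = rng.random((n, m)) < p_conn
    n_exc_edges = int(adj[:, h_type == EXC].sum())
    n_inh_edges = int(adj[:, h_type == INH].sum())
    if n_inh_edges == 0 or n_exc_edges == 0:
        raise ValueError("hidden block needs both excitatory and inhibitory edges")
    delta = n_exc_edges / n_inh_edges

    gprime = np.zeros((n, m))
    gprime[:, h_type == EXC] = 1.0
    gprime[:, h_type == INH] = -delta
    gprime[~adj] = 0.0

    N = n + m
    weight = np.zeros((N, N))
    weight[:n, :n] = graph.weight
    weight[:n, n:] = gprime
    delay = np.zeros((N, N))
    delay[:n, :n] = graph.delay
    delay[:n, n:][adj] = d_max * (1.0 - rng.random(int(adj.sum())))
    neuron_type = np.concatenate([graph.neuron_type, h_type])

    aug = NetworkGraph(n=N, weight=weight, delay=delay,
                       d_max=max(graph.d_max, d_max), neuron_type=neuron_type)
    traffic = HiddenTraffic(m=m, hidden_ids=np.arange(n, N), gprime=gprime)
    return aug, traffic


def hide_neurons(
    spikes: SpikeTrainSet,
    graph: NetworkGraph,
    ratio: float,
    seed: int = 0,
) -> tuple[SpikeTrainSet, NetworkGraph, np.ndarray]:
    """Remove ``floor(ratio * n)`` uniformly chosen neurons' spike trains
    and restrict the graph to the visible subnetwork; returns the hidden
    id list for bookkeeping."""
    if not 0 <= ratio < 1:
        raise ValueError("ratio must be in [0, 1)")
    n = spikes.n
    n_hidden = int(np.floor(ratio * n))
    if n - n_hidden < 2:
        raise ValueError("hiding would leave fewer than 2 visible neurons")
    rng = np.random.default_rng(seed)
    hidden = np.sort(rng.choice(n, size=n_hidden, replace=False))
    visible = np.setdiff1d(np.arange(n), hidden)
    return spikes.subset(visible), graph.subset(visible), hidden
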