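"""From spike trains to the kernelized constraint system.

On a grid of step ``dt_ms`` with T bins, the inference kernel matrix K'
(T x n, non-negative) filters each pre-synaptic spike train through a
decaying exponential with time constant ``tau_ms`` — either the full sum
over all past spikes or only the most recent one ("last-spike" mode).
The post-synaptic spike train becomes a +/-1 label vector y, and the
row-scaled matrix A = diag(y) K' turns firing consistency into linear
inequalities A w > 0.  Rows stream in M contiguous blocks so that only
one block is resident at a time; the concatenation of streamed blocks is
bit-identical to a single-block construction.

``true_kernel_matrix`` builds the *generative* kernel K instead — the
simulator's filter with true propagation delays and membrane time
constant — for consistency diagnostics against the ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import lfilter

from .datatypes import NetworkGraph, SpikeTrainSet

__all__ = [
    "KernelConfig",
    "KernelBlock",
    "encode_labels",
    "build_kernel_block",
    "subsample_decorrelated",
    "stream_blocks",
    "true_kernel_matrix",
]


@dataclass
class KernelConfig:
    """Inference-kernel settings.

    ``mode='full'`` sums the exponential over every past pre-synaptic
    spike (no delay modelling — delays are unknown at inference time);
    ``mode='last'`` keeps only the most recent pre-spike.  With
    ``reset_on_post``, pre-spikes emitted at or before the target's most
    recent spike are excluded, mirroring the generative membrane reset.
    ``delta`` is the decorrelated row-subsampling gap in bins (1 = keep
    all rows); ``window`` optionally fixes the rows per streamed block.
    """

    tau_ms: float = 20.0
    dt_ms: float = 1.0
    mode: str = "full"
    reset_on_post: bool = True
    delta: int = 1
    window: int | None = None

    def __post_init__(self) -> None:
        if self.tau_ms <= 0:
            raise ValueError("tau_ms must be positive")
        if self.dt_ms <= 0:
            raise ValueError("dt_ms must be positive")
        if self.mode not in ("full", "last"):
            raise ValueError(f"unknown kernel mode {self.mode!r}")
        if self.delta < 1:
            raise ValueError("delta must be >= 1")

    @property
    def rho(self) -> float:
        return float(np.exp(-self.dt_ms / self.tau_ms))


@dataclass
class KernelBlock:
    """A block of constraint rows: K' rows, +/-1 labels y, A = diag(y) K',
    cached per-row squared norms, and the global bin index of each row."""

    t_start: int
    t_end: int
    rows: np.ndarray        # global bin index per retained row
    Kp: np.ndarray          # (rows, n) inference kernel
    y: np.ndarray           # (rows,) labels in {-1, +1}
    A: np.ndarray           # (rows, n) = y[:, None] * Kp
    row_norms_sq: np.ndarray

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n(self) -> int:
        return self.Kp.shape[1]


def encode_labels(spikes: SpikeTrainSet, target: int, dt_ms: float = 1.0,
                  n_bins: int | None = None) -> np.ndarray:
    """+/-1 encoding of the target's spike train: +1 in bins where the
    target fires, -1 elsewhere."""
    if not 0 <= target < spikes.n:
        raise ValueError(f"target {target} out of range")
    T = spikes.n_bins(dt_ms) if n_bins is None else n_bins
    y = -np.ones(T, dtype=np.int8)
    b = spikes.to_bins(dt_ms)[target]
    y[b[b < T]] = 1
    return y


class _KernelStream:
    """Sequential block builder carrying O(n) state between blocks so the
    streamed concatenation equals the one-shot construction exactly."""

    def __init__(self, spikes: SpikeTrainSet, target: int, cfg: KernelConfig):
        self.cfg = cfg
        self.target = target
        self.n = spikes.n
        self.T = spikes.n_bins(cfg.dt_ms)
        self.rho = cfg.rho
        self.bins = spikes.to_bins(cfg.dt_ms)
        self.y_full = encode_labels(spikes, target, cfg.dt_ms, self.T)
        self.pos = 0
        # carried state
        self.zi = np.zeros((1, self.n))        # lfilter state for P
        self.r_prev = -1                        # last post-spike bin so far
        self.P_r_prev = np.zeros(self.n)        # P row at r_prev
        self.P_prev_row = np.zeros(self.n)      # P row at pos-1
        self.last_pre = -np.ones(self.n, dtype=np.int64)  # last pre-spike bin < pos

    def _spike_indicator(self, a: int, b: int) -> np.ndarray:
        s = np.zeros((b - a, self.n))
        for j in range(self.n):
            bj = self.bins[j]
            sel = bj[(bj >= a) & (bj < b)]
            s[sel - a, j] = 1.0
        return s

    def next_rows(self, b: int) -> KernelBlock:
        """Build rows [pos, b) and advance."""
        a = self.pos
        if not a < b <= self.T:
            raise ValueError(f"invalid row range [{a}, {b}) for T={self.T}")
        cfg, rho, n = self.cfg, self.rho, self.n
        s = self._spike_indicator(a, b)
        t_idx = np.arange(a, b)
        y = self.y_full[a:b]

        # P[t] = sum_{bin<=t} rho^(t-bin) over pre spikes (same-bin included)
        P, zi = lfilter([1.0], [1.0, -rho], s, axis=0, zi=self.zi)

        # last post-spike bin <= t-1, per row
        post_here = np.where(y == 1, t_idx, -1)
        rr = np.empty(b - a, dtype=np.int64)
        rr[0] = self.r_prev
        if b - a > 1:
            rr[1:] = np.maximum.accumulate(post_here[:-1])
            rr[1:] = np.maximum(rr[1:], self.r_prev)

        if cfg.mode == "full":
            # strictly-causal kernel: K[t] = rho * P[t-1]
            K = np.empty_like(P)
            K[0] = rho * self.P_prev_row
            if b - a > 1:
                K[1:] = rho * P[:-1]
            if cfg.reset_on_post:
                has_r = rr >= 0
                if np.any(has_r):
                    P_at_r = np.empty_like(P)
                    in_blk = rr >= a
                    P_at_r[in_blk] = P[rr[in_blk] - a]
                    P_at_r[~in_blk & has_r] = self.P_r_prev
                    fac = np.where(has_r, rho ** (t_idx - np.maximum(rr, 0)), 0.0)
                    K = K - fac[:, None] * np.where(has_r[:, None], P_at_r, 0.0)
                    np.clip(K, 0.0, None, out=K)
        else:  # last-spike mode
            pre_here = np.where(s > 0, t_idx[:, None], -1)
            lp = np.empty((b - a, n), dtype=np.int64)
            lp[0] = self.last_pre
            if b - a > 1:
                lp[1:] = np.maximum.accumulate(pre_here[:-1], axis=0)
                lp[1:] = np.maximum(lp[1:], self.last_pre[None, :])
            valid = lp >= 0
            if cfg.reset_on_post:
                valid &= lp > rr[:, None]
            K = np.where(valid, rho ** (t_idx[:, None] - np.maximum(lp, 0)), 0.0)

        K[:, self.target] = 0.0

        # advance carried state
        self.zi = zi
        self.P_prev_row = P[-1].copy()
        post_in_blk = t_idx[y == 1]
        if post_in_blk.size:
            self.r_prev = int(post_in_blk[-1])
            self.P_r_prev = P[self.r_prev - a].copy()
        for j in range(n):
            bj = self.bins[j]
            sel = bj[(bj >= a) & (bj < b)]
            if sel.size:
                self.last_pre[j] = int(sel[-1])
        self.pos = b

        A = y[:, None] * K
        return KernelBlock(
            t_start=a, t_end=b, rows=t_idx, Kp=K, y=y.copy(), A=A,
            row_norms_sq=np.einsum("ij,ij->i", K, K),
        )


def build_kernel_block(
    spikes: SpikeTrainSet,
    target: int,
    cfg: KernelConfig | None = None,
    rows: tuple[int, int] | None = None,
) -> KernelBlock:
    """Build the kernel block for bin range ``rows`` (default: the whole
    recording), using the complete spike history before the range."""
    cfg = cfg or KernelConfig()
    stream = _KernelStream(spikes, target, cfg)
    a, b = rows if rows is not None else (0, stream.T)
    if not 0 <= a < b <= stream.T:
        raise ValueError(f"invalid row range [{a}, {b}) for T={stream.T}")
    if a > 0:
        stream.next_rows(a)  # advance state; block discarded
    return stream.next_rows(b)


def subsample_decorrelated(
    block: KernelBlock, delta: int, keep_spike_rows: bool = False
) -> KernelBlock:
    """Keep every ``delta``-th row (starting at the block's first row);
    with ``keep_spike_rows`` additionally keep all +1 rows, preserving
    class balance."""
    if delta < 1:
        raise ValueError("delta must be >= 1")
    if delta == 1:
        return block
    keep = np.zeros(block.n_rows, dtype=bool)
    keep[::delta] = True
    if keep_spike_rows:
        keep |= block.y == 1
    idx = np.nonzero(keep)[0]
    return KernelBlock(
        t_start=block.t_start, t_end=block.t_end, rows=block.rows[idx],
        Kp=block.Kp[idx], y=block.y[idx], A=block.A[idx],
        row_norms_sq=block.row_norms_sq[idx],
    )


def stream_blocks(
    spikes: SpikeTrainSet,
    target: int,
    cfg: KernelConfig | None = None,
    M: int = 1,
):
    """Yield M contiguous blocks partitioning the row range, sizes within
    one row of T/M; concatenating them reproduces the single-block
    construction bit for bit."""
    cfg = cfg or KernelConfig()
    T = spikes.n_bins(cfg.dt_ms)
    if M < 1:
        raise ValueError("M must be >= 1")
    if M > T:
        raise ValueError(f"M={M} exceeds the number of rows T={T}")
    edges = np.cumsum([0] + [T // M + (1 if k < T % M else 0) for k in range(M)])
    stream = _KernelStream(spikes, target, cfg)
    for k in range(M):
        block = stream.next_rows(int(edges[k + 1]))
        if cfg.delta > 1:
            block = subsample_decorrelated(block, cfg.delta, keep_spike_rows=True)
        yield block


def true_kernel_matrix(
    spikes: SpikeTrainSet,
    graph: NetworkGraph,
    target: int,
    tau_m: float = 20.0,
    dt_ms: float = 1.0,
    reset: bool = True,
) -> np.ndarray:
    """Generative kernel K (T x n) for one post-synaptic neuron: the
    simulator's exponential filter with true per-edge delays (rounded up
    to whole bins) and, if ``reset``, restarting after each target spike
    so only pre-spikes emitted strictly after the target's last own spike
    contribute.  Meant for small instances (consistency diagnostics)."""
    rho = float(np.exp(-dt_ms / tau_m))
    T = spikes.n_bins(dt_ms)
    n = spikes.n
    bins = spikes.to_bins(dt_ms)
    post_bins = bins[target]
    K = np.zeros((T, n))
    for j in range(n):
        if j == target or graph.weight[target, j] == 0:
            continue
        d = max(1, int(np.ceil(graph.delay[target, j] / dt_ms)))
        for b in bins[j]:
            t0 = b + d
            if t0 >= T:
                continue
            if reset:
                # contributes until the first target spike at bin >= b
                nxt = post_bins[post_bins >= b]
                t1 = int(nxt[0]) if nxt.size else T - 1
                t1 = min(max(t1, t0), T - 1)
                if nxt.size and nxt[0] < t0:
                    continue  # reset swallowed the in-transit spike
            else:
                t1 = T - 1
            K[t0 : t1 + 1, j] += rho ** np.arange(t1 - t0 + 1)
    return K
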