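"""Solvers for the regularized hinge-loss connectivity problem.

For one post-synaptic neuron, given the constraint matrix A = diag(y) K'
(one row per time bin), we minimize

    ||w||_l  +  sum_t L(A_t w),        L(x) = max(0, 1 - x),

either in the primal with l = 1 (NeuInf: a perceptron-style pass,
``w += gamma * L(A_t w) * A_t``, interleaved with iterative
soft-thresholding) or via the Fenchel dual with l = 2 (Dual NeuInf:
stochastic dual coordinate ascent on

    E(lambda) = -c ||A^T lambda||^2 + sum_t lambda_t,  lambda in [0,1]^T,

with exact per-coordinate line maximization, hence no learning rate, and
w* = A^T lambda* trimmed by soft-thresholding).  Block-parallel variants
process streamed blocks with bounded resident rows; the dual one merges
per-block local updates with conservative 1/M scaling, the primal one
averages per-shard weight deltas within each block.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from numba import njit

from .kernelize import KernelBlock

__all__ = [
    "Hyper",
    "PrimalState",
    "DualState",
    "WeightEstimate",
    "hinge_loss",
    "soft_threshold",
    "neuinf_epoch",
    "neuinf",
    "dual_coordinate_step",
    "dual_neuinf",
    "parallel_solve",
    "aggregate_runs",
]


@dataclass
class Hyper:
    """Solver hyper-parameters.

    gamma: primal learning rate; eta: soft-threshold level; c: dual
    regularization constant; eps: optional modified-hinge slope in (0,1);
    epochs: full sweeps over the data; M: block count; workers: shards
    per block (primal) — all seeded and deterministic.  ``subgradient``
    switches the primal update from the loss-value-scaled rule to the
    classical constant-subgradient step.
    """

    algo: str = "dual"
    gamma: float = 0.05
    eta: float = 0.01
    c: float = 1.0
    eps: float | None = None
    epochs: int = 5
    M: int = 1
    workers: int = 1
    seed: int = 0
    ell: int | None = None
    subgradient: bool = False
    tol: float = 0.0  # relative objective-improvement stop (0 = run all epochs)
    fit_intercept: bool = True
    intercept_scale: float = 5.0

    def __post_init__(self) -> None:
        if self.algo not in ("neuinf", "dual", "parallel-neuinf", "parallel-dual"):
            raise ValueError(f"unknown algo {self.algo!r}")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if self.eta < 0:
            raise ValueError("eta must be non-negative")
        if self.c <= 0:
            raise ValueError("c must be positive")
        if self.eps is not None and not 0 < self.eps < 1:
            raise ValueError("eps must lie in (0, 1)")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.M < 1 or self.workers < 1:
            raise ValueError("M and workers must be >= 1")
        if self.ell is None:
            self.ell = 1 if "neuinf" in self.algo and "dual" not in self.algo else 2


@dataclass
class PrimalState:
    w: np.ndarray
    tau: int = 0  # update-step counter


@dataclass
class DualState:
    """Dual iterate: box-constrained lambda per retained row, the running
    combination u = A^T lambda (maintained incrementally and exactly),
    and the dual objective E(lambda)."""

    lam: np.ndarray
    u: np.ndarray
    c: float

    @property
    def objective(self) -> float:
        return float(-self.c * self.u @ self.u + self.lam.sum())


@dataclass
class WeightEstimate:
    """Inferred incoming-weight vector for one post-synaptic neuron.

    ``intercept`` is the fitted bias absorbing the (unknown) firing
    threshold; it is not a connection and is never soft-thresholded.
    """

    target: int
    w: np.ndarray
    algo: str
    hyper: Hyper | None = None
    objective: float | None = None
    n_runs: int = 1
    intercept: float = 0.0
    objective_trajectory: list = field(default_factory=list)


def _with_intercept(blocks: Sequence[KernelBlock], scale: float) -> list[KernelBlock]:
    """Append a constant column of value ``scale`` to every block: the
    margin becomes K'_t w + scale * w_bias, absorbing the threshold."""
    out = []
    for b in blocks:
        col = np.full((b.n_rows, 1), scale)
        Kp = np.hstack([b.Kp, col])
        out.append(KernelBlock(
            t_start=b.t_start, t_end=b.t_end, rows=b.rows, Kp=Kp, y=b.y,
            A=b.y[:, None] * Kp,
            row_norms_sq=b.row_norms_sq + scale * scale,
        ))
    return out


def hinge_loss(x, eps: float | None = None):
    """Hinge loss max(0, 1-x), or the modified decreasing variant
    max(eps*(1-x), 1-x) for eps in (0, 1)."""
    x = np.asarray(x, dtype=np.float64)
    if eps is None:
        out = np.maximum(0.0, 1.0 - x)
    else:
        if not 0 < eps < 1:
            raise ValueError("eps must lie in (0, 1)")
        out = np.maximum(eps * (1.0 - x), 1.0 - x)
    return out if out.ndim else float(out)


def soft_threshold(x, eta: float):
    """Shrink toward zero: x-eta above eta, x+eta below -eta, else 0."""
    if eta < 0:
        raise ValueError("eta must be non-negative")
    x = np.asarray(x, dtype=np.float64)
    out = np.sign(x) * np.maximum(np.abs(x) - eta, 0.0)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# primal NeuInf
# ---------------------------------------------------------------------------

@njit(cache=True)
def _neuinf_pass(w, A, order, gamma, eta, eps, use_eps, subgradient, n_shrink):
    """One pass over the given rows: loss-scaled update then elementwise
    soft-thresholding after every update (iterative shrinkage).  Only the
    first ``n_shrink`` coordinates are shrunk (the bias, if present, is
    exempt)."""
    n = w.shape[0]
    steps = 0
    for k in range(order.shape[0]):
        t = order[k]
        x = 0.0
        for i in range(n):
            x += A[t, i] * w[i]
        if use_eps:
            L = max(eps * (1.0 - x), 1.0 - x)
        else:
            L = max(0.0, 1.0 - x)
        if L == 0.0:
            continue
        coef = gamma * (1.0 if subgradient else L)
        if subgradient and x >= 1.0:
            continue
        for i in range(n):
            w[i] += coef * A[t, i]
            if i < n_shrink:
                if w[i] > eta:
                    w[i] -= eta
                elif w[i] < -eta:
                    w[i] += eta
                else:
                    w[i] = 0.0
        steps += 1
    return steps


def neuinf_epoch(state: PrimalState, block: KernelBlock, hyper: Hyper,
                 rng: np.random.Generator | None = None) -> PrimalState:
    """One epoch of primal NeuInf over a block, rows in seeded random
    order; rows with zero loss leave w unchanged."""
    if block.n_rows == 0:
        raise ValueError("block is empty")
    rng = rng or np.random.default_rng(hyper.seed)
    order = rng.permutation(block.n_rows)
    w = state.w
    steps = _neuinf_pass(
        w, block.A, order, hyper.gamma, hyper.eta,
        0.0 if hyper.eps is None else hyper.eps, hyper.eps is not None,
        hyper.subgradient, len(w),
    )
    if not np.all(np.isfinite(w)):
        raise FloatingPointError(
            "primal update diverged (non-finite weights); try a smaller gamma"
        )
    return PrimalState(w=w, tau=state.tau + steps)


def neuinf(blocks: Sequence[KernelBlock], hyper: Hyper | None = None) -> WeightEstimate:
    """Primal NeuInf over streamed blocks for ``hyper.epochs`` epochs."""
    hyper = hyper or Hyper(algo="neuinf")
    blocks = list(blocks)
    if not blocks or all(b.n_rows == 0 for b in blocks):
        raise ValueError("no data rows")
    n = blocks[0].n
    if hyper.fit_intercept:
        blocks = _with_intercept(blocks, hyper.intercept_scale)
    rng = np.random.default_rng(hyper.seed)
    w = np.zeros(n + (1 if hyper.fit_intercept else 0))
    tau = 0
    eps = 0.0 if hyper.eps is None else hyper.eps
    for _ in range(hyper.epochs):
        for b in blocks:
            if b.n_rows == 0:
                continue
            order = rng.permutation(b.n_rows)
            tau += _neuinf_pass(w, b.A, order, hyper.gamma, hyper.eta, eps,
                                hyper.eps is not None, hyper.subgradient, n)
            if not np.all(np.isfinite(w)):
                raise FloatingPointError(
                    "primal update diverged (non-finite weights); "
                    "try a smaller gamma")
    obj = float(np.sum(hinge_loss(
        np.concatenate([b.A @ w for b in blocks]), hyper.eps))
        + np.sum(np.abs(w[:n])))
    est = WeightEstimate(target=-1, w=w[:n], algo="neuinf", hyper=hyper,
                         objective=obj)
    if hyper.fit_intercept:
        est.intercept = float(w[n] * hyper.intercept_scale)
    return est


# ---------------------------------------------------------------------------
# Dual NeuInf (stochastic dual coordinate ascent)
# ---------------------------------------------------------------------------

@njit(cache=True)
def _dual_sweep(A, norms_sq, lam, u, c, order):
    """Exact coordinate maximization of E along each visited row, clipped
    to [0, 1]; u is maintained incrementally.  Zero-norm rows skipped."""
    n = A.shape[1]
    for k in range(order.shape[0]):
        t = order[k]
        nt = norms_sq[t]
        if nt == 0.0:
            lam[t] = 1.0  # E increases linearly in a zero-norm coordinate
            continue
        au = 0.0
        for i in range(n):
            au += A[t, i] * u[i]
        new = lam[t] + (1.0 - 2.0 * c * au) / (2.0 * c * nt)
        if new < 0.0:
            new = 0.0
        elif new > 1.0:
            new = 1.0
        d = new - lam[t]
        if d != 0.0:
            lam[t] = new
            for i in range(n):
                u[i] += d * A[t, i]


def dual_coordinate_step(state: DualState, t: int, block: KernelBlock,
                         c: float | None = None) -> DualState:
    """Single exact coordinate-ascent step on row ``t`` of a block
    (in place); the dual objective never decreases."""
    c = state.c if c is None else c
    if c <= 0:
        raise ValueError("c must be positive")
    _dual_sweep(block.A, block.row_norms_sq, state.lam, state.u, c,
                np.array([t], dtype=np.int64))
    return state


def _sweep_blocks(blocks, lam_per_block, u, c, rng):
    for b, lam in zip(blocks, lam_per_block):
        if b.n_rows:
            order = rng.permutation(b.n_rows)
            _dual_sweep(b.A, b.row_norms_sq, lam, u, c, order)


def _dual_objective(lam_per_block, u, c):
    return float(-c * u @ u + sum(l.sum() for l in lam_per_block))


def dual_neuinf(blocks: Sequence[KernelBlock], hyper: Hyper | None = None,
                return_state: bool = False) -> WeightEstimate:
    """Dual NeuInf: seeded-random coordinate sweeps for ``hyper.epochs``
    epochs (or until the relative objective gain drops below
    ``hyper.tol``), then w* = A^T lambda* trimmed by soft-thresholding."""
    hyper = hyper or Hyper(algo="dual")
    blocks = list(blocks)
    if not blocks or all(b.n_rows == 0 for b in blocks):
        raise ValueError("no data rows")
    n = blocks[0].n
    if hyper.fit_intercept:
        blocks = _with_intercept(blocks, hyper.intercept_scale)
    rng = np.random.default_rng(hyper.seed)
    lam_per_block = [np.zeros(b.n_rows) for b in blocks]
    u = np.zeros(blocks[0].n)
    traj = []
    for _ in range(hyper.epochs):
        _sweep_blocks(blocks, lam_per_block, u, hyper.c, rng)
        E = _dual_objective(lam_per_block, u, hyper.c)
        traj.append(E)
        if hyper.tol > 0 and len(traj) > 1:
            if traj[-1] - traj[-2] < hyper.tol * max(1.0, abs(traj[-1])):
                break
    w_star = u[:n].copy()
    est = WeightEstimate(
        target=-1, w=soft_threshold(w_star, hyper.eta), algo="dual",
        hyper=hyper, objective=traj[-1], objective_trajectory=traj,
    )
    est.w_raw = w_star
    if hyper.fit_intercept:
        est.intercept = float(u[n] * hyper.intercept_scale)
    if return_state:
        est.state = DualState(lam=np.concatenate(lam_per_block), u=u, c=hyper.c)
    return est


# ---------------------------------------------------------------------------
# block-parallel variants
# ---------------------------------------------------------------------------

def _parallel_dual(blocks, hyper):
    """CoCoA-style rounds: each block runs a local sweep on copies of
    (lambda_b, u), then updates merge with conservative 1/M scaling.
    With M = 1 this reduces exactly to the sequential algorithm."""
    M = len(blocks)
    n = blocks[0].n
    if hyper.fit_intercept:
        blocks = _with_intercept(blocks, hyper.intercept_scale)
    rng = np.random.default_rng(hyper.seed)
    lam_per_block = [np.zeros(b.n_rows) for b in blocks]
    u = np.zeros(blocks[0].n)
    traj = []
    for _ in range(hyper.epochs):
        if M == 1:  # exact reduction to the sequential algorithm
            b = blocks[0]
            if b.n_rows:
                order = rng.permutation(b.n_rows)
                _dual_sweep(b.A, b.row_norms_sq, lam_per_block[0], u,
                            hyper.c, order)
            traj.append(_dual_objective(lam_per_block, u, hyper.c))
            continue
        d_lams = []
        d_u_total = np.zeros(u.shape[0])
        for b, lam in zip(blocks, lam_per_block):
            if b.n_rows == 0:
                d_lams.append(np.zeros(0))
                continue
            order = rng.permutation(b.n_rows)
            lam_loc = lam.copy()
            u_loc = u.copy()
            _dual_sweep(b.A, b.row_norms_sq, lam_loc, u_loc, hyper.c, order)
            d_lams.append(lam_loc - lam)
            d_u_total += u_loc - u
        for lam, d in zip(lam_per_block, d_lams):
            if d.size:
                lam += d / M
        u += d_u_total / M
        traj.append(_dual_objective(lam_per_block, u, hyper.c))
    w_star = u[:n].copy()
    est = WeightEstimate(
        target=-1, w=soft_threshold(w_star, hyper.eta), algo="parallel-dual",
        hyper=hyper, objective=traj[-1], objective_trajectory=traj,
    )
    est.w_raw = w_star
    if hyper.fit_intercept:
        est.intercept = float(u[n] * hyper.intercept_scale)
    return est


def _parallel_neuinf(blocks, hyper):
    """Blocks processed sequentially; within a block the permuted rows
    are sharded across ``workers``, each shard starts from the block-entry
    weights, and the per-shard deltas are merged by averaging."""
    n = blocks[0].n
    if hyper.fit_intercept:
        blocks = _with_intercept(blocks, hyper.intercept_scale)
    n_aug = blocks[0].n
    rng = np.random.default_rng(hyper.seed)
    w = np.zeros(n_aug)
    tau = 0
    eps = 0.0 if hyper.eps is None else hyper.eps
    use_eps = hyper.eps is not None
    for _ in range(hyper.epochs):
        for b in blocks:
            if b.n_rows == 0:
                continue
            order = rng.permutation(b.n_rows)
            if hyper.workers == 1:  # exact reduction to the sequential pass
                tau += _neuinf_pass(w, b.A, order, hyper.gamma, hyper.eta,
                                    eps, use_eps, hyper.subgradient, n)
            else:
                shards = np.array_split(order, hyper.workers)
                deltas = np.zeros((len(shards), n_aug))
                for k, shard in enumerate(shards):
                    wk = w.copy()
                    if shard.size:
                        tau += _neuinf_pass(wk, b.A, shard, hyper.gamma,
                                            hyper.eta, eps, use_eps,
                                            hyper.subgradient, n)
                    deltas[k] = wk - w
                w = w + deltas.mean(axis=0)
            if not np.all(np.isfinite(w)):
                raise FloatingPointError(
                    "primal update diverged (non-finite weights); "
                    "try a smaller gamma")
    obj = float(np.sum(hinge_loss(
        np.concatenate([b.A @ w for b in blocks]), hyper.eps))
        + np.sum(np.abs(w[:n])))
    est = WeightEstimate(target=-1, w=w[:n], algo="parallel-neuinf",
                         hyper=hyper, objective=obj)
    if hyper.fit_intercept:
        est.intercept = float(w[n] * hyper.intercept_scale)
    return est


def parallel_solve(blocks: Iterable[KernelBlock], hyper: Hyper | None = None,
                   workers: int | None = None) -> WeightEstimate:
    """Block-parallel solve.  ``hyper.algo`` selects the primal or dual
    merge rule; with M = 1 (and workers = 1 for the primal) the result is
    identical to the sequential solver on the same seed."""
    hyper = hyper or Hyper(algo="parallel-dual")
    if workers is not None:
        hyper = replace(hyper, workers=workers)
    if hyper.workers < 1:
        raise ValueError("workers must be >= 1")
    blocks = list(blocks)
    if not blocks or all(b.n_rows == 0 for b in blocks):
        raise ValueError("no data rows")
    if "dual" in hyper.algo:
        return _parallel_dual(blocks, hyper)
    return _parallel_neuinf(blocks, hyper)


def aggregate_runs(estimates: Sequence[WeightEstimate]) -> WeightEstimate:
    """Entrywise mean of several runs on the same target (the multi-run
    aggregation protocol that averages association matrices before
    ternarization)."""
    if not estimates:
        raise ValueError("no estimates to aggregate")
    n = len(estimates[0].w)
    target = estimates[0].target
    for e in estimates:
        if len(e.w) != n:
            raise ValueError("mismatched weight-vector lengths")
        if e.target != target:
            raise ValueError("mismatched targets")
    w = np.mean([e.w for e in estimates], axis=0)
    return WeightEstimate(
        target=target, w=w, algo=estimates[0].algo,
        n_runs=sum(e.n_runs for e in estimates),
        intercept=float(np.mean([e.intercept for e in estimates])),
    )
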