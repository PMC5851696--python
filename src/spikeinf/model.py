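"""Model/Results interface over the kernelization and solvers.

:class:`ConnectivityModel` holds the observed spike trains, one target
post-synaptic neuron and the kernel settings; :meth:`fit` runs a solver
and returns :class:`ConnectivityResults` carrying the estimated incoming
weights, solver diagnostics and evaluation helpers.  ``fit_aggregate``
implements the multi-run protocol (several hyper-parameter settings,
entrywise-averaged), and :func:`fit_network` maps the per-neuron problem
over every post-synaptic neuron.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .datatypes import NetworkGraph, SpikeTrainSet
from .inference import (
    Hyper,
    WeightEstimate,
    aggregate_runs,
    dual_neuinf,
    neuinf,
    parallel_solve,
)
from .kernelize import KernelConfig, stream_blocks

__all__ = ["ConnectivityModel", "ConnectivityResults", "fit_network"]

# eta grid of the default five-run aggregation protocol
DEFAULT_ETA_GRID = (0.0, 0.01, 0.02, 0.05, 0.1)


class ConnectivityModel:
    """Incoming-connectivity model for one post-synaptic neuron.

    Parameters
    ----------
    spikes : SpikeTrainSet
        Observed spike trains of all recorded neurons.
    target : int
        Post-synaptic neuron whose incoming weights are inferred.
    kernel : KernelConfig, optional
        Inference-kernel settings (exponential filter, grid, reset).
    """

    def __init__(self, spikes: SpikeTrainSet, target: int,
                 kernel: KernelConfig | None = None):
        if not 0 <= target < spikes.n:
            raise ValueError(f"target {target} out of range 0..{spikes.n - 1}")
        self.spikes = spikes
        self.target = target
        self.kernel = kernel or KernelConfig()
        self._blocks_cache: dict[int, list] = {}

    @classmethod
    def from_files(cls, spikes_path, target: int,
                   kernel: KernelConfig | None = None,
                   n_hint: int | None = None) -> "ConnectivityModel":
        from .io_formats import read_spikes

        return cls(read_spikes(spikes_path, n_hint=n_hint), target, kernel)

    def blocks(self, M: int = 1) -> list:
        if M not in self._blocks_cache:
            self._blocks_cache.clear()  # keep at most one M resident
            self._blocks_cache[M] = list(
                stream_blocks(self.spikes, self.target, self.kernel, M=M))
        return self._blocks_cache[M]

    def fit(self, hyper: Hyper | None = None, **kwargs) -> "ConnectivityResults":
        """Solve for the incoming weights with the selected algorithm.

        Keyword arguments override :class:`Hyper` fields, e.g.
        ``fit(algo="dual", eta=0.02, epochs=10, seed=3)``.
        """
        if hyper is None:
            hyper = Hyper(**kwargs)
        elif kwargs:
            hyper = replace(hyper, **kwargs)
        blocks = self.blocks(M=hyper.M)
        if hyper.algo == "neuinf":
            est = neuinf(blocks, hyper)
        elif hyper.algo == "dual":
            est = dual_neuinf(blocks, hyper)
        else:
            est = parallel_solve(blocks, hyper)
        est.target = self.target
        return ConnectivityResults(self, est)

    def fit_aggregate(self, hyper: Hyper | None = None,
                      eta_grid=DEFAULT_ETA_GRID, **kwargs) -> "ConnectivityResults":
        """Multi-run aggregation protocol: one fit per soft-threshold
        level in ``eta_grid`` (each with its own seed, hence its own row
        ordering), entrywise-averaged.

        The grid values are *relative*: each run's threshold is
        ``eta * max|w|`` of that run's raw weights, so the sparsity
        levels are comparable across solver scales.
        """
        if hyper is None:
            hyper = Hyper(**kwargs)
        elif kwargs:
            hyper = replace(hyper, **kwargs)
        from .inference import soft_threshold

        runs = []
        for k, eta in enumerate(eta_grid):
            h = replace(hyper, eta=0.0, seed=hyper.seed + k)
            est = self.fit(h).estimate
            scale = float(np.max(np.abs(est.w))) if np.any(est.w) else 0.0
            est.w = soft_threshold(est.w, float(eta) * scale)
            runs.append(est)
        est = aggregate_runs(runs)
        est.hyper = hyper
        return ConnectivityResults(self, est)


@dataclass
class ConnectivityResults:
    """Fit results: the weight estimate plus evaluation conveniences."""

    model: ConnectivityModel
    estimate: WeightEstimate

    @property
    def weights(self) -> np.ndarray:
        return self.estimate.w

    @property
    def objective(self) -> float | None:
        return self.estimate.objective

    def predict_spikes(self, spikes: SpikeTrainSet | None = None):
        """Predicted +/-1 labels and accuracy on the given (default:
        training) spike trains."""
        from .evaluation import predict_spikes

        spikes = spikes or self.model.spikes
        blocks = stream_blocks(spikes, self.model.target, self.model.kernel, M=1)
        return predict_spikes(self.weights, blocks,
                              intercept=self.estimate.intercept)

    def ternarize(self) -> np.ndarray:
        from .evaluation import ternarize

        return ternarize(self.weights, self_id=self.model.target)

    def evaluate(self, truth: NetworkGraph) -> dict:
        from .evaluation import evaluate_weights

        return evaluate_weights(self.weights, truth, self.model.target)

    def sign_match_rate(self, truth: NetworkGraph) -> float:
        """Fraction of true nonzero incoming connections whose estimated
        weight has the matching sign."""
        g = truth.weight[self.model.target, :]
        nz = np.nonzero(g)[0]
        nz = nz[nz != self.model.target]
        if nz.size == 0:
            return float("nan")
        return float(np.mean(np.sign(self.weights[nz]) == np.sign(g[nz])))

    def summary(self, truth: NetworkGraph | None = None) -> str:
        e = self.estimate
        w = self.weights
        lines = [
            "Connectivity inference results",
            "==============================",
            f"target neuron:        {e.target}",
            f"algorithm:            {e.algo} ({e.n_runs} run(s) aggregated)",
            f"candidates (n):       {len(w)}",
            f"nonzero weights:      {int(np.sum(w != 0))}",
            f"weight range:         [{w.min():+.4g}, {w.max():+.4g}]",
        ]
        if e.objective is not None:
            lines.append(f"final objective:      {e.objective:.6g}")
        if truth is not None:
            ev = self.evaluate(truth)
            lines.append(f"sign-match rate:      {self.sign_match_rate(truth):.3f}")
            for typ in ("excitatory", "void", "inhibitory"):
                m = ev["type_stats"][typ]
                if m["mean"] is not None:
                    lines.append(
                        f"mean w ({typ:<11s}): {m['mean']:+.4g}  "
                        f"(var {m['var']:.3g}, n={m['count']})"
                    )
            for typ in ("excitatory", "inhibitory"):
                auc = ev["roc"][typ]["auc"]
                if auc is not None:
                    lines.append(f"AUC ({typ:<11s}):    {auc:.3f}")
        return "\n".join(lines)

    def plot_weights(self, truth: NetworkGraph | None = None, ax=None):
        """Stem plot of inferred incoming weights, colored by true type
        when the ground truth is given."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(8, 3))
        w = self.weights
        idx = np.arange(len(w))
        if truth is None:
            ax.stem(idx, w)
        else:
            types = truth.incoming_types(self.model.target)
            colors = {"excitatory": "tab:red", "void": "tab:gray",
                      "inhibitory": "tab:blue"}
            for typ, col in colors.items():
                sel = types == typ
                ax.vlines(idx[sel], 0, w[sel], color=col, label=typ)
        ax.axhline(0, lw=0.5, color="k")
        ax.set_xlabel("pre-synaptic neuron")
        ax.set_ylabel("inferred weight")
        ax.legend(loc="best", fontsize="small")
        return ax


def fit_network(
    spikes: SpikeTrainSet,
    targets=None,
    kernel: KernelConfig | None = None,
    hyper: Hyper | None = None,
    aggregate: bool = False,
    eta_grid=DEFAULT_ETA_GRID,
) -> dict[int, WeightEstimate]:
    """Fit the incoming weights of every target (default: all neurons);
    the per-neuron problems are independent."""
    hyper = hyper or Hyper()
    targets = range(spikes.n) if targets is None else targets
    out: dict[int, WeightEstimate] = {}
    for tgt in targets:
        m = ConnectivityModel(spikes, tgt, kernel)
        h = replace(hyper, seed=hyper.seed + 1000 * tgt)
        res = m.fit_aggregate(h, eta_grid=eta_grid) if aggregate else m.fit(h)
        out[tgt] = res.estimate
    return out
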