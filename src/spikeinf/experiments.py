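"""Reference experiment protocols on synthetic balanced networks.

These functions bundle the study conditions used throughout the
package's benchmarks: a 50-neuron balanced (80/20, +1/-delta mV)
recurrent LIF network with delays up to 2 ms on a 1 ms grid, threshold
20 mV, membrane constant 20 ms, and an independent background Poisson
drive (1600 Hz x 0.5 mV) calibrated so neurons fire at roughly 4-8 Hz.
Inference uses the full-sum exponential kernel (tau' = 20 ms) with
post-spike reset, decorrelated row subsampling every 20 bins (spike rows
always retained, for class balance), and the block-parallel dual solver
with an intercept absorbing the unknown threshold, aggregated over the
five-level relative soft-threshold grid.

Every function takes an explicit seed and is fully deterministic.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .datatypes import NetworkGraph, SpikeTrainSet
from .evaluation import evaluate_weights, hidden_sweep, precision_recall, ternarize
from .inference import Hyper
from .kernelize import KernelConfig
from .lif_sim import LIfParams, NoiseConfig, StochasticFiring, generate_network, \
    simulate_deterministic, simulate_stochastic
from .model import ConnectivityModel

__all__ = [
    "study_network",
    "study_recording",
    "study_kernel",
    "study_hyper",
    "sign_recovery_experiment",
    "hidden_robustness_experiment",
]

#: conditions of the benchmark simulations
N_NEURONS = 50
FRAC_EXC = 0.8
P_CONN = 0.2
D_MAX_MS = 2.0
THETA_MV = 20.0
TAU_M_MS = 20.0
DT_MS = 1.0
DRIVE_RATE_HZ = 1600.0
DRIVE_WEIGHT_MV = 0.5
#: durations (ms) at which recovery is scored
DURATIONS_MS = (60_000.0, 120_000.0, 300_000.0, 600_000.0)


def study_network(seed: int, n: int = N_NEURONS) -> NetworkGraph:
    return generate_network(n=n, frac_exc=FRAC_EXC, p_conn=P_CONN,
                            d_max=D_MAX_MS, seed=seed)


def study_recording(
    graph: NetworkGraph,
    duration_ms: float,
    seed: int,
    stochastic: bool = False,
    beta: float = 4.0,
) -> SpikeTrainSet:
    lif = LIfParams(theta=THETA_MV, tau_m=TAU_M_MS, dt_ms=DT_MS)
    noise = NoiseConfig(drive_rate=DRIVE_RATE_HZ, drive_weight=DRIVE_WEIGHT_MV)
    if stochastic:
        return simulate_stochastic(graph, lif, StochasticFiring(beta=beta),
                                   noise, duration_ms, seed=seed)
    spikes, _ = simulate_deterministic(graph, lif, noise, duration_ms, seed=seed)
    return spikes


def study_kernel() -> KernelConfig:
    return KernelConfig(tau_ms=20.0, dt_ms=DT_MS, mode="full",
                        reset_on_post=True, delta=20)


def study_hyper(seed: int, algo: str = "parallel-dual", M: int = 4) -> Hyper:
    return Hyper(algo=algo, M=M, c=1.0, epochs=5, eta=0.0, seed=seed,
                 fit_intercept=True, intercept_scale=5.0)


def sign_recovery_experiment(
    seed: int,
    durations_ms=DURATIONS_MS,
    target: int = 0,
    stochastic: bool = False,
) -> dict:
    """Simulate one study network for the longest duration, then score
    sign recovery, per-type weight means and ROC AUCs on growing
    prefixes of the recording (five-run aggregated parallel-dual fits).

    Returns a dict keyed by duration (ms) with per-duration results plus
    the graph and full recording.
    """
    graph = study_network(seed)
    full = study_recording(graph, max(durations_ms), seed=seed + 100,
                           stochastic=stochastic)
    out = {"graph": graph, "spikes": full, "per_duration": {}}
    for dur in durations_ms:
        spikes = full.truncated(dur)
        model = ConnectivityModel(spikes, target, study_kernel())
        res = model.fit_aggregate(study_hyper(seed + 3))
        ev = evaluate_weights(res.weights, graph, target)
        out["per_duration"][dur] = {
            "results": res,
            "sign_match": res.sign_match_rate(graph),
            "type_means": {t: ev["type_stats"][t]["mean"]
                           for t in ev["type_stats"]},
            "auc_exc": ev["roc"]["excitatory"]["auc"],
            "auc_inh": ev["roc"]["inhibitory"]["auc"],
            "precision_recall": ev["precision_recall"],
        }
    return out


def hidden_robustness_experiment(
    seed: int,
    ratio: float = 0.2,
    graphs_per_ratio: int = 5,
    duration_ms: float = 300_000.0,
    n_targets: int = 3,
) -> list[dict]:
    """Hide a fraction of the neurons (several seeded hidings), infer on
    the visible spike trains only, and compare precision/recall of
    excitatory+inhibitory detection against the ratio-0 baseline."""
    graph = study_network(seed)
    spikes = study_recording(graph, duration_ms, seed=seed + 100)
    return hidden_sweep(
        spikes, graph, ratios=(0.0, ratio),
        graphs_per_ratio=graphs_per_ratio,
        targets=range(n_targets),
        kernel=study_kernel(),
        hyper=study_hyper(seed + 3),
        aggregate=True,
        seed=seed + 11,
    )
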