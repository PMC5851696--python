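"""Plain-text readers and writers for spike trains, graphs, weights,
reports and run configuration.

Spike files are one spike per row (``neuron_id <sep> time_ms``), graphs
and weight vectors are edge lists (``pre post weight_mv [delay_ms]``),
reports are JSON, and run configuration is a flat ``key=value`` file.
Separators may be tabs, commas or runs of spaces; lines starting with
``#`` are comments.  Every writer/reader pair round-trips exactly.
"""

from __future__ import annotations

import json
import logging
import re
from pathlib import Path

import numpy as np

from .datatypes import NetworkGraph, RunConfig, SpikeTrainSet

logger = logging.getLogger(__name__)

_SEP = re.compile(r"[,\t ]+")


class ParseError(ValueError):
    """Malformed input file; the message names the offending line."""


def _tokenize(path):
    """Yield (line_number, fields) for data lines of a text table."""
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            yield lineno, _SEP.split(line)


def read_spikes(
    path, n_hint: int | None = None, duration_ms: float | None = None,
    dt_ms: float = 1.0,
) -> SpikeTrainSet:
    """Read a two-column spike file into a :class:`SpikeTrainSet`.

    ``n`` is ``n_hint`` if given, else ``max id + 1``.  Input rows may be
    unsorted; per-neuron lists are sorted (with a log notice).  Unless
    overridden, ``duration_ms`` is the latest spike time plus one grid
    step ``dt_ms``.
    """
    ids: list[int] = []
    times: list[float] = []
    for lineno, fields in _tokenize(path):
        if len(fields) != 2:
            raise ParseError(f"{path}:{lineno}: expected 2 fields, got {len(fields)}")
        try:
            i = int(fields[0])
            t = float(fields[1])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-numeric field: {exc}") from None
        if t < 0:
            raise ParseError(f"{path}:{lineno}: negative spike time {t}")
        if i < 0:
            raise ParseError(f"{path}:{lineno}: negative neuron id {i}")
        if n_hint is not None and i >= n_hint:
            raise ParseError(f"{path}:{lineno}: neuron id {i} >= n_hint={n_hint}")
        ids.append(i)
        times.append(t)

    n = n_hint if n_hint is not None else (max(ids) + 1 if ids else 0)
    if duration_ms is None:
        duration_ms = (max(times) + dt_ms) if times else dt_ms

    spikes = [[] for _ in range(n)]
    for i, t in zip(ids, times):
        spikes[i].append(t)
    out = []
    unsorted_seen = False
    for s in spikes:
        a = np.asarray(s, dtype=np.float64)
        if a.size > 1 and np.any(np.diff(a) < 0):
            unsorted_seen = True
            a = np.sort(a)
        out.append(a)
    if unsorted_seen:
        logger.info("read_spikes(%s): unsorted input; sorted per neuron", path)
    return SpikeTrainSet(n=n, duration_ms=float(duration_ms), spikes=out)


def write_spikes(spike_set: SpikeTrainSet, path) -> None:
    """Write a spike set as a tab-separated two-column file.

    Neurons with no spikes leave no rows; pass ``n_hint`` on read to
    restore them.
    """
    with open(path, "w") as fh:
        fh.write(f"# spike trains: n={spike_set.n} duration_ms={spike_set.duration_ms}\n")
        fh.write("# neuron_id\ttime_ms\n")
        for i, s in enumerate(spike_set.spikes):
            for t in s:
                fh.write(f"{i}\t{t:.6f}\n")


def read_graph(path, n_hint: int | None = None, d_max: float | None = None) -> NetworkGraph:
    """Read a ground-truth graph edge list ``pre post weight_mv delay_ms``.

    Neuron types are recovered from outgoing edge signs (Dale's
    principle); neurons with no outgoing edge default to excitatory.
    """
    edges = {}
    max_id = -1
    for lineno, fields in _tokenize(path):
        if len(fields) != 4:
            raise ParseError(f"{path}:{lineno}: expected 4 fields, got {len(fields)}")
        try:
            pre, post = int(fields[0]), int(fields[1])
            w, d = float(fields[2]), float(fields[3])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-numeric field: {exc}") from None
        if pre == post:
            raise ParseError(f"{path}:{lineno}: self-edge {pre}->{post}")
        if (pre, post) in edges:
            raise ParseError(f"{path}:{lineno}: duplicate edge {pre}->{post}")
        if d <= 0:
            raise ParseError(f"{path}:{lineno}: delay {d} <= 0")
        edges[(pre, post)] = (w, d)
        max_id = max(max_id, pre, post)

    n = n_hint if n_hint is not None else max_id + 1
    if d_max is None:
        d_max = max((d for _, d in edges.values()), default=1.0)
    weight = np.zeros((n, n))
    delay = np.zeros((n, n))
    for (pre, post), (w, d) in edges.items():
        if pre >= n or post >= n:
            raise ParseError(f"{path}: edge {pre}->{post} exceeds n={n}")
        if d > d_max:
            raise ParseError(f"{path}: delay {d} of edge {pre}->{post} > d_max={d_max}")
        weight[post, pre] = w
        delay[post, pre] = d

    neuron_type = np.array(
        ["inhibitory" if np.any(weight[:, j] < 0) else "excitatory" for j in range(n)],
        dtype=object,
    )
    return NetworkGraph(n=n, weight=weight, delay=delay, d_max=float(d_max),
                        neuron_type=neuron_type)


def write_graph(graph: NetworkGraph, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# graph: n={graph.n} d_max={graph.d_max}\n")
        fh.write("# pre\tpost\tweight_mv\tdelay_ms\n")
        post_idx, pre_idx = np.nonzero(graph.weight)
        for post, pre in zip(post_idx, pre_idx):
            fh.write(
                f"{pre}\t{post}\t{float(graph.weight[post, pre])!r}\t{float(graph.delay[post, pre])!r}\n"
            )


def write_weights(weights: dict[int, np.ndarray], path) -> None:
    """Write inferred incoming weights, one edge per row (no delays)."""
    with open(path, "w") as fh:
        fh.write("# inferred weights\n# pre\tpost\tweight\n")
        for post in sorted(weights):
            w = weights[post]
            for pre in range(len(w)):
                if w[pre] != 0:
                    fh.write(f"{pre}\t{post}\t{float(w[pre])!r}\n")


def read_weights(path, n: int) -> dict[int, np.ndarray]:
    out: dict[int, np.ndarray] = {}
    seen = set()
    for lineno, fields in _tokenize(path):
        if len(fields) != 3:
            raise ParseError(f"{path}:{lineno}: expected 3 fields, got {len(fields)}")
        pre, post, w = int(fields[0]), int(fields[1]), float(fields[2])
        if (pre, post) in seen:
            raise ParseError(f"{path}:{lineno}: duplicate edge {pre}->{post}")
        seen.add((pre, post))
        if post not in out:
            out[post] = np.zeros(n)
        out[post][pre] = w
    return out


def write_report(report: dict, path) -> None:
    def _default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, (np.bool_,)):
            return bool(o)
        raise TypeError(f"not JSON-serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, default=_default)
        fh.write("\n")


def read_report(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def write_config(config: RunConfig, path) -> None:
    with open(path, "w") as fh:
        fh.write("# run configuration\n")
        for k in sorted(config.params):
            fh.write(f"{k}={config.params[k]!r}\n")


def read_config(path) -> RunConfig:
    import ast

    params = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ParseError(f"{path}:{lineno}: expected key=value")
            k, v = line.split("=", 1)
            try:
                params[k.strip()] = ast.literal_eval(v.strip())
            except (ValueError, SyntaxError):
                params[k.strip()] = v.strip()
    return RunConfig(params)


def _ensure_parent(path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
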