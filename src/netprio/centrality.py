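"""Betweenness centrality: fast Brandes implementation plus a brute-force oracle.

Values are UNNORMALIZED sums over unordered node pairs of shortest-path
fractions. Parallel computation partitions Brandes accumulation by source
vertex into fixed-size chunks, so results are bit-identical for any worker
count (the floating-point summation order never depends on scheduling).
"""

from __future__ import annotations

from collections import deque
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass

import networkx as nx

from netprio.ppin_io import InteractionNetwork

#: sources per parallel chunk; fixed so chunking (and hence float summation
#: order) is independent of the worker count
_CHUNK_SIZE = 64

_ORACLE_GUARD = 64


class DisconnectedNetworkError(ValueError):
    """Betweenness here is defined on connected networks only."""


@dataclass
class CentralityTable:
    """Per-gene betweenness values for one labeled network."""

    label: str
    values: dict

    def __getitem__(self, gene: str) -> float:
        return self.values[gene]

    def __len__(self) -> int:
        return len(self.values)


def _check_connected(net: InteractionNetwork) -> None:
    if net.n_nodes == 0:
        raise DisconnectedNetworkError("empty network")
    if net.n_nodes > 1 and not nx.is_connected(net.graph):
        raise DisconnectedNetworkError(
            f"{net.source_label or 'network'} is disconnected; "
            "betweenness requires a connected (giant-component) input"
        )


def _adjacency(net: InteractionNetwork) -> dict:
    # sorted neighbor lists -> deterministic BFS visit order
    return {v: sorted(net.graph.neighbors(v)) for v in sorted(net.graph.nodes)}


def _brandes_chunk(args) -> dict:
    """Brandes accumulation restricted to a subset of source vertices."""
    adj, sources = args
    bc = dict.fromkeys(adj, 0.0)
    for s in sources:
        stack: list[str] = []
        pred: dict[str, list[str]] = {v: [] for v in adj}
        sigma = dict.fromkeys(adj, 0.0)
        sigma[s] = 1.0
        dist = {s: 0}
        queue = deque([s])
        while queue:
            v = queue.popleft()
            stack.append(v)
            dv = dist[v]
            sv = sigma[v]
            for w in adj[v]:
                if w not in dist:
                    dist[w] = dv + 1
                    queue.append(w)
                if dist[w] == dv + 1:
                    sigma[w] += sv
                    pred[w].append(v)
        delta = dict.fromkeys(adj, 0.0)
        while stack:
            w = stack.pop()
            coeff = (1.0 + delta[w]) / sigma[w]
            for v in pred[w]:
                delta[v] += sigma[v] * coeff
            if w != s:
                bc[w] += delta[w]
    return bc


def betweenness(
    net: InteractionNetwork,
    normalized: bool = False,
    workers: int = 1,
) -> CentralityTable:
    """Betweenness centrality of every node, deterministic for any ``workers``.

    BC(v) = sum over unordered pairs (s, t), s != v != t, of
    sigma_st(v) / sigma_st with unweighted shortest paths. With
    ``normalized=True`` values are divided by (n-1)(n-2)/2.
    """
    _check_connected(net)
    adj = _adjacency(net)
    sources = list(adj)
    chunks = [
        sources[i : i + _CHUNK_SIZE] for i in range(0, len(sources), _CHUNK_SIZE)
    ]
    if workers > 1 and len(chunks) > 1:
        with ProcessPoolExecutor(max_workers=workers) as pool:
            partials = list(pool.map(_brandes_chunk, [(adj, c) for c in chunks]))
    else:
        partials = [_brandes_chunk((adj, c)) for c in chunks]

    total = dict.fromkeys(adj, 0.0)
    for part in partials:  # ordered accumulation: bitwise worker invariance
        for v, x in part.items():
            total[v] += x
    for v in total:
        total[v] *= 0.5  # undirected: each pair visited from both endpoints
    n = len(adj)
    if normalized and n > 2:
        scale = 2.0 / ((n - 1) * (n - 2))
        for v in total:
            total[v] *= scale
    return CentralityTable(label=net.source_label, values=total)


def _bfs_counts(adj: dict, s: str) -> tuple[dict, dict]:
    """Distances and shortest-path counts from one source (plain BFS)."""
    dist = {s: 0}
    sigma = {s: 1}
    queue = deque([s])
    while queue:
        v = queue.popleft()
        for w in adj[v]:
            if w not in dist:
                dist[w] = dist[v] + 1
                sigma[w] = 0
                queue.append(w)
            if dist[w] == dist[v] + 1:
                sigma[w] += sigma[v]
    return dist, sigma


def betweenness_oracle(
    net: InteractionNetwork, guard: int = _ORACLE_GUARD
) -> CentralityTable:
    """Brute-force betweenness by per-pair shortest-path counting.

    For every unordered pair (s, t) runs BFS from both ends; a node v lies on
    a shortest s-t path iff d_s(v) + d_t(v) = d_s(t), contributing
    sigma_s(v) * sigma_t(v) / sigma_s(t). Structurally independent of the
    Brandes implementation; guarded to small networks.
    """
    _check_connected(net)
    if net.n_nodes > guard:
        raise ValueError(f"oracle guard exceeded: {net.n_nodes} > {guard} nodes")
    adj = _adjacency(net)
    nodes = list(adj)
    bfs = {s: _bfs_counts(adj, s) for s in nodes}
    bc = dict.fromkeys(nodes, 0.0)
    for i, s in enumerate(nodes):
        dist_s, sigma_s = bfs[s]
        for t in nodes[i + 1 :]:
            dist_t, sigma_t = bfs[t]
            d = dist_s[t]
            n_paths = sigma_s[t]
            for v in nodes:
                if v == s or v == t:
                    continue
                if dist_s[v] + dist_t[v] == d:
                    bc[v] += sigma_s[v] * sigma_t[v] / n_paths
    return CentralityTable(label=net.source_label, values=bc)
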