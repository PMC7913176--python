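"""Synthetic scale-free interaction networks with planted seed modules and bridges.

Fixtures emulate the topology the pipeline is designed for: heavy-tailed
degree distributions, seed-dense modules, and a low-degree connector gene
that carries all traffic between the two modules *inside the extracted
disease subnetwork*. The full network keeps alternative hub-level routes
between the two sides so degree-matched random networks do not depend on the
connector; only the seed-anchored subnetwork funnels through it. Everything
is reproducible from a :class:`FixtureSpec` and round-trips through the
generic TSV readers.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np

from netprio.ppin_io import InteractionNetwork, SeedList

@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic PPIN fixture."""

    n_nodes: int
    attachment: int = 2
    n_modules: int = 2
    seeds_per_module: int = 8
    bridge_count: int = 1
    bridge_degree: int = 2
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nodes < 10:
            raise ValueError("n_nodes must be >= 10")
        if self.attachment < 1 or self.attachment >= self.n_nodes:
            raise ValueError("attachment must satisfy 1 <= m < n_nodes")
        if min(self.n_modules, self.seeds_per_module, self.bridge_count) < 1:
            raise ValueError("all counts must be positive")
        if self.bridge_degree < 2:
            raise ValueError("bridge_degree must be >= 2")
        if self.n_modules * self.seeds_per_module > self.n_nodes:
            raise ValueError("more seeds requested than nodes available")


def _node_name(i: int) -> str:
    return f"G{i:04d}"


def generate_ppin(spec: FixtureSpec) -> InteractionNetwork:
    """Connected scale-free-like network by preferential attachment.

    Deterministic given ``spec.rng_seed``; the construction adds
    ``attachment`` edges per incoming node, giving exactly
    ``attachment * (n_nodes - attachment)`` edges.
    """
    raw = nx.barabasi_albert_graph(spec.n_nodes, spec.attachment, seed=spec.rng_seed)
    graph = nx.relabel_nodes(raw, {i: _node_name(i) for i in raw.nodes})
    return InteractionNetwork(
        graph=graph, source_label=f"fixture(n={spec.n_nodes},seed={spec.rng_seed})"
    )


def plant_bridge(
    ppin: InteractionNetwork,
    module_a_seeds: frozenset | set,
    module_b_seeds: frozenset | set,
    bridge_degree: int = 2,
) -> tuple[InteractionNetwork, str]:
    """Rewire so every route between the seed modules' neighborhoods runs
    through one low-degree bridge gene, while the full network keeps
    hub-level detours.

    The node set is split into two sides (module A's seeds with the first
    half of the sorted node list, module B's with the rest). A subnetwork
    induced on seeds plus first neighbors can only ever contain edges whose
    BOTH endpoints are seeds or seed neighbors, so exactly those cross-side
    edges are removed; every other cross-side edge is left in place,
    preserving hub-level mixing for degree-matched random networks. A new
    bridge node of exactly ``bridge_degree`` is then wired alternately to
    seeds of the two modules, making it the unique inter-module connector of
    the seed-anchored subnetwork.

    Raises ``ValueError`` when the rewiring would disconnect the network.
    """
    module_a_seeds, module_b_seeds = set(module_a_seeds), set(module_b_seeds)
    if module_a_seeds & module_b_seeds:
        raise ValueError("seed modules must be disjoint")
    seeds = module_a_seeds | module_b_seeds
    nodes = sorted(ppin.graph.nodes)
    missing = seeds - set(nodes)
    if missing:
        raise ValueError(f"seed genes not in network: {sorted(missing)}")

    half = set(nodes[: len(nodes) // 2])
    side_a = (half | module_a_seeds) - module_b_seeds
    side_b = set(nodes) - side_a
    if not side_a or not side_b:
        raise ValueError("rewiring would disconnect the network: one side is empty")

    graph = ppin.graph.copy()
    # iterate: repairs may create new seed neighbors whose cross edges must
    # then be removed too; every round deletes at least one edge, so the
    # loop terminates
    while True:
        protected = set(seeds)
        for s in seeds:
            protected.update(graph.neighbors(s))
        doomed = [
            (u, v)
            for u, v in graph.edges
            if (u in side_a) != (v in side_a)
            and u in protected
            and v in protected
        ]
        if not doomed:
            break
        graph.remove_edges_from(doomed)
        # re-attach fragments with same-side edges: intra-side edges can never
        # add a second inter-module route to a seed-anchored subnetwork
        comps = sorted(nx.connected_components(graph), key=lambda c: (-len(c), min(c)))
        main = comps[0]
        for comp in comps[1:]:
            u = min(comp - protected, default=min(comp))
            same_side = side_a if u in side_a else side_b
            candidates = main & same_side
            if not candidates:
                raise ValueError(
                    "rewiring would disconnect the network: a fragment has no "
                    "same-side re-attachment point"
                )
            v = min(candidates - protected, default=min(candidates))
            graph.add_edge(u, v)
            main = main | comp

    bridge = "BRIDGE1"
    while bridge in graph:
        bridge += "X"
    seq_a, seq_b = sorted(module_a_seeds), sorted(module_b_seeds)
    for i in range(bridge_degree):
        pool = seq_a if i % 2 == 0 else seq_b
        graph.add_edge(bridge, pool[(i // 2) % len(pool)])

    net = InteractionNetwork(graph=graph, source_label=f"{ppin.source_label}|bridged")
    return net, bridge


def bridged_fixture(spec: FixtureSpec) -> tuple[InteractionNetwork, SeedList, str]:
    """Full fixture: scale-free PPIN, two low-degree seed modules, one planted bridge.

    Each module is a low-degree cluster around one high-degree anchor hub of
    its half of the node list: seeds are drawn from the anchor's low-degree
    neighbors (degree at most ``attachment + 1``), falling back to the
    lowest-degree nodes of the half when the anchor's neighborhood is too
    small. Clustering keeps each module's disease-subnetwork chunk connected,
    mimicking a seed-dense functional module. The returned seed list is the
    union of both modules (the bridge is NOT a seed).
    """
    if spec.n_modules != 2:
        raise ValueError("bridged_fixture requires exactly 2 modules")
    ppin = generate_ppin(spec)
    nodes = sorted(ppin.graph.nodes)
    half = len(nodes) // 2
    degree = dict(ppin.graph.degree)
    cap = spec.attachment + 1
    rng = np.random.default_rng(spec.rng_seed)

    def _pick(side_nodes: list) -> frozenset:
        anchor = max(side_nodes, key=lambda v: (degree[v], v))
        pool = sorted(
            v
            for v in ppin.graph.neighbors(anchor)
            if v in set(side_nodes) and degree[v] <= cap
        )
        if len(pool) < spec.seeds_per_module:
            extra = sorted(
                (v for v in side_nodes if v not in pool and v != anchor),
                key=lambda v: (degree[v], v),
            )
            pool += extra[: spec.seeds_per_module - len(pool)]
        idx = rng.choice(len(pool), size=spec.seeds_per_module, replace=False)
        return frozenset(pool[i] for i in idx)

    module_a = _pick(nodes[:half])
    module_b = _pick(nodes[half:])
    net, bridge = plant_bridge(ppin, module_a, module_b, spec.bridge_degree)
    seeds = SeedList(
        symbols=module_a | module_b,
        provenance=f"fixture-modules(seed={spec.rng_seed})",
    )
    return net, seeds, bridge


def write_fixture(
    net: InteractionNetwork, seeds: SeedList, out_dir: str | Path
) -> tuple[Path, Path]:
    """Write the fixture as a generic TSV edge list plus a seed list file."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    edges_path = out_dir / "network.tsv"
    seeds_path = out_dir / "seeds.txt"
    with open(edges_path, "w") as fh:
        for u, v in sorted(tuple(sorted(e)) for e in net.graph.edges):
            fh.write(f"{u}\t{v}\n")
    with open(seeds_path, "w") as fh:
        fh.write(f"# seed list: {seeds.provenance}\n")
        for sym in sorted(seeds.symbols):
            fh.write(sym + "\n")
    return edges_path, seeds_path
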