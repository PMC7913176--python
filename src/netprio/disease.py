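"""Disease-specific subnetwork construction around a seed gene list.

Construction order is fixed: induce the subgraph on mapped seeds plus their
first neighbors, prune single-degree non-seed nodes (one pass by default),
then keep the largest connected component.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from netprio.ppin_io import InteractionNetwork, SeedList, giant_component

log = logging.getLogger(__name__)

PRUNE_MODES = ("single_pass", "fixpoint")


class SeedMappingError(ValueError):
    """No seed symbol maps into the network."""


class StrataMismatchError(ValueError):
    """Seed gene missing from the degree strata (inconsistent inputs)."""


@dataclass
class DiseaseNetwork:
    """Pruned giant-component subnetwork anchored on a seed list.

    ``mapped_seeds`` are all seeds found in the source PPIN (some may be lost
    to pruning/component selection); ``seed_flags`` covers exactly the nodes
    of the final network.
    """

    network: InteractionNetwork
    seed_flags: dict
    mapped_seeds: frozenset
    mapped_seed_count: int
    lost_seed_count: int

    @property
    def nodes(self) -> frozenset:
        return self.network.nodes

    def surviving_seeds(self) -> frozenset:
        return frozenset(g for g, flag in self.seed_flags.items() if flag)


def extract_disease_network(
    ppin: InteractionNetwork,
    seeds: SeedList,
    prune_mode: str = "single_pass",
) -> DiseaseNetwork:
    """Build the disease network: induce on seeds + first neighbors, prune, keep giant component.

    Node induction automatically includes seed-seed, seed-neighbor and
    neighbor-neighbor edges. Pruning removes nodes whose degree in the induced
    subgraph is 1 and which are not mapped seeds; by default this is a single
    simultaneous pass (``prune_mode='fixpoint'`` iterates to exhaustion).

    Raises :class:`SeedMappingError` when no seed maps into ``ppin``.
    """
    if prune_mode not in PRUNE_MODES:
        raise ValueError(f"prune_mode must be one of {PRUNE_MODES}")
    node_set = set(ppin.graph.nodes)
    mapped = frozenset(seeds.symbols & node_set)
    lost = len(seeds.symbols) - len(mapped)
    if not mapped:
        raise SeedMappingError(
            f"no seed from {seeds.provenance or 'seed list'} maps into "
            f"{ppin.source_label or 'network'}"
        )

    keep = set(mapped)
    for s in mapped:
        keep.update(ppin.graph.neighbors(s))
    sub = ppin.graph.subgraph(keep).copy()

    while True:
        to_drop = [v for v in sub.nodes if sub.degree(v) == 1 and v not in mapped]
        sub.remove_nodes_from(to_drop)
        if prune_mode == "single_pass" or not to_drop:
            break

    pruned = InteractionNetwork(
        graph=sub, source_label=f"{ppin.source_label}|disease"
    )
    giant = giant_component(pruned)
    flags = {v: (v in mapped) for v in giant.graph.nodes}
    log.info(
        "disease network from %s: %d/%d seeds mapped, %d nodes, %d edges",
        ppin.source_label, len(mapped), len(seeds.symbols),
        giant.n_nodes, giant.n_edges,
    )
    return DiseaseNetwork(
        network=giant,
        seed_flags=flags,
        mapped_seeds=mapped,
        mapped_seed_count=len(mapped),
        lost_seed_count=lost,
    )


def seed_degree_profile(disease_net: DiseaseNetwork, strata) -> dict[int, int]:
    """Count mapped seed genes per degree interval of the full-PPIN strata.

    The degree used is the gene's degree in the full PPIN the strata were
    built from. The counts sum to ``mapped_seed_count``.

    Raises :class:`StrataMismatchError` if a mapped seed is absent from the
    strata (the strata were built from a different network).
    """
    counts: dict[int, int] = {b: 0 for b in strata.members}
    for gene in disease_net.mapped_seeds:
        try:
            idx = strata.gene_bin[gene]
        except KeyError:
            raise StrataMismatchError(
                f"seed gene {gene} not covered by the degree strata"
            ) from None
        counts[idx] = counts.get(idx, 0) + 1
    return counts
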