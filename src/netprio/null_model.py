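"""Degree-stratified random background networks and per-gene null accumulation.

Random seed sets are drawn without replacement within contiguous degree
intervals of the full PPIN so every replicate's seed set reproduces the true
seed set's degree profile bin by bin. Each replicate then reuses the exact
disease-network construction (induce, prune, giant component) and betweenness
computation, and per-gene counters are accumulated.
"""

from __future__ import annotations

import logging
import os
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass, field

import numpy as np

from netprio.centrality import betweenness, CentralityTable
from netprio.disease import DiseaseNetwork, extract_disease_network, seed_degree_profile
from netprio.ppin_io import InteractionNetwork, SeedList

log = logging.getLogger(__name__)

TIE_RULES = ("strict", "weak")


class ReplicateError(RuntimeError):
    """A null replicate failed; the message carries the replicate index."""


@dataclass(frozen=True)
class DegreeStrata:
    """Contiguous degree intervals [1..w], [w+1..2w], ... over the full PPIN.

    ``members`` maps interval index -> sorted gene tuple; ``gene_bin`` maps
    each PPIN gene to its interval index. Every node is in exactly one bin.
    """

    bin_width: int
    members: dict
    gene_bin: dict

    def interval(self, idx: int) -> tuple[int, int]:
        """(low, high) degree bounds of bin ``idx`` (inclusive)."""
        return idx * self.bin_width + 1, (idx + 1) * self.bin_width


@dataclass
class NullAccumulator:
    """Per-gene counters over R background networks.

    n[g]: replicates where g is present with a defined betweenness.
    r[g]: replicates where g's betweenness exceeded its disease-network value
    (strict by default). bc_sum[g]: running sum of background values (mean is
    bc_sum/n, over present replicates only). Genes never seen have n = r = 0.
    """

    replicates: int
    disease_genes: frozenset
    tie_rule: str = "strict"
    n: dict = field(default_factory=dict)
    r: dict = field(default_factory=dict)
    bc_sum: dict = field(default_factory=dict)
    replicate_nodes: list = field(default_factory=list)
    replicate_edges: list = field(default_factory=list)

    def n_g(self, gene: str) -> int:
        return self.n.get(gene, 0)

    def r_g(self, gene: str) -> int:
        return self.r.get(gene, 0)

    def mean_bc(self, gene: str) -> float:
        n = self.n.get(gene, 0)
        return self.bc_sum.get(gene, 0.0) / n if n else float("nan")

    def untracked_genes(self) -> frozenset:
        """Genes seen in replicates but absent from the disease network."""
        return frozenset(self.n) - self.disease_genes

    def size_summary(self) -> dict:
        nodes = np.asarray(self.replicate_nodes, dtype=float)
        edges = np.asarray(self.replicate_edges, dtype=float)
        return {
            "replicate_nodes_mean": float(nodes.mean()) if nodes.size else float("nan"),
            "replicate_nodes_sd": float(nodes.std(ddof=1)) if nodes.size > 1 else 0.0,
            "replicate_edges_mean": float(edges.mean()) if edges.size else float("nan"),
            "replicate_edges_sd": float(edges.std(ddof=1)) if edges.size > 1 else 0.0,
        }


def build_strata(ppin: InteractionNetwork, bin_width: int = 3) -> DegreeStrata:
    """Partition all PPIN genes into contiguous degree intervals of ``bin_width``."""
    if bin_width < 1:
        raise ValueError(f"bin_width must be >= 1, got {bin_width}")
    gene_bin: dict[str, int] = {}
    members: dict[int, list] = {}
    for gene, degree in ppin.graph.degree:
        idx = (degree - 1) // bin_width if degree >= 1 else 0
        gene_bin[gene] = idx
        members.setdefault(idx, []).append(gene)
    frozen = {idx: tuple(sorted(genes)) for idx, genes in members.items()}
    return DegreeStrata(bin_width=bin_width, members=frozen, gene_bin=gene_bin)


def sample_random_seeds(
    strata: DegreeStrata, per_bin_counts: dict, rng_seed: int
) -> SeedList:
    """Draw a random gene set matching ``per_bin_counts`` exactly, bin by bin.

    Sampling is without replacement within each bin (the pool is the entire
    PPIN membership of the bin, true seeds included). Deterministic given
    ``rng_seed``.
    """
    rng = np.random.default_rng(rng_seed)
    chosen: list[str] = []
    for idx in sorted(strata.members):
        want = int(per_bin_counts.get(idx, 0))
        if want == 0:
            continue
        pool = strata.members[idx]
        if want > len(pool):
            low, high = strata.interval(idx)
            raise ValueError(
                f"bin [{low}-{high}] holds {len(pool)} genes but {want} requested"
            )
        picked = rng.choice(len(pool), size=want, replace=False)
        chosen.extend(pool[i] for i in picked)
    return SeedList(
        symbols=frozenset(chosen), provenance=f"stratified-sample(rng_seed={rng_seed})"
    )


def replicate_seed(master_seed: int, replicate: int) -> int:
    """Counter-based per-replicate RNG seed: scheduling cannot change results."""
    return int(np.random.SeedSequence([master_seed, replicate]).generate_state(1)[0])


# ---------------------------------------------------------------------------
# replicate execution (worker-state pattern keeps the PPIN unpickled per task)

_STATE: dict = {}


def _init_worker(ppin, strata, per_bin_counts, master_seed, prune_mode):
    _STATE["ppin"] = ppin
    _STATE["strata"] = strata
    _STATE["counts"] = per_bin_counts
    _STATE["master_seed"] = master_seed
    _STATE["prune_mode"] = prune_mode


def _run_replicate(rep: int):
    try:
        ppin = _STATE["ppin"]
        seeds = sample_random_seeds(
            _STATE["strata"], _STATE["counts"], replicate_seed(_STATE["master_seed"], rep)
        )
        net = extract_disease_network(ppin, seeds, prune_mode=_STATE["prune_mode"])
        bc = betweenness(net.network)
        return rep, net.network.n_nodes, net.network.n_edges, bc.values
    except Exception as exc:  # re-raised with replicate index by the driver
        raise ReplicateError(f"replicate {rep} failed: {exc}") from exc


def run_null(
    ppin: InteractionNetwork,
    disease_net: DiseaseNetwork,
    strata: DegreeStrata,
    R: int,
    master_seed: int,
    *,
    disease_bc: CentralityTable | None = None,
    tie_rule: str = "strict",
    prune_mode: str = "single_pass",
    workers: int = 1,
    _sampler=None,
) -> NullAccumulator:
    """Accumulate per-gene null statistics over ``R`` background networks.

    Each replicate draws a degree-matched random seed set, rebuilds a network
    with the identical construction used for the disease network, computes
    betweenness, and for every present gene increments n, adds to the running
    betweenness sum, and increments r when the replicate value beats the
    disease-network value (strictly under ``tie_rule='strict'``; ties count
    under ``'weak'``). Genes absent from the disease network are tracked too
    but flagged for exclusion from prioritization.

    Deterministic given ``master_seed`` regardless of ``workers``. ``_sampler``
    is a test hook: a callable ``replicate_index -> SeedList`` overriding the
    stratified sampler (forces ``workers=1``).
    """
    if R < 1:
        raise ValueError(f"R must be >= 1, got {R}")
    if tie_rule not in TIE_RULES:
        raise ValueError(f"tie_rule must be one of {TIE_RULES}")
    if disease_bc is None:
        disease_bc = betweenness(disease_net.network)
    per_bin = seed_degree_profile(disease_net, strata)
    baseline = disease_bc.values

    acc = NullAccumulator(
        replicates=R, disease_genes=disease_net.nodes, tie_rule=tie_rule
    )

    def _consume(rep, n_nodes, n_edges, values):
        acc.replicate_nodes.append(n_nodes)
        acc.replicate_edges.append(n_edges)
        for gene, value in values.items():
            acc.n[gene] = acc.n.get(gene, 0) + 1
            acc.bc_sum[gene] = acc.bc_sum.get(gene, 0.0) + value
            base = baseline.get(gene)
            if base is None:
                continue
            beats = value > base if tie_rule == "strict" else value >= base
            if beats:
                acc.r[gene] = acc.r.get(gene, 0) + 1

    if _sampler is not None:
        for rep in range(R):
            seeds = _sampler(rep)
            net = extract_disease_network(ppin, seeds, prune_mode=prune_mode)
            bc = betweenness(net.network)
            _consume(rep, net.network.n_nodes, net.network.n_edges, bc.values)
        return acc

    _init_worker(ppin, strata, per_bin, master_seed, prune_mode)
    if workers > 1:
        ctx_workers = min(workers, os.cpu_count() or 1, R)
        with ProcessPoolExecutor(
            max_workers=ctx_workers,
            initializer=_init_worker,
            initargs=(ppin, strata, per_bin, master_seed, prune_mode),
        ) as pool:
            # map preserves submission order -> ordered accumulation
            for rep, n_nodes, n_edges, values in pool.map(
                _run_replicate, range(R), chunksize=max(1, R // (ctx_workers * 4))
            ):
                _consume(rep, n_nodes, n_edges, values)
    else:
        for rep in range(R):
            _consume(*_run_replicate(rep))
    log.info(
        "null model: R=%d, %s", R,
        ", ".join(f"{k}={v:.1f}" for k, v in acc.size_summary().items()),
    )
    return acc
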