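"""Empirical p-values, FDR adjustment, relative betweenness and overlap tests."""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from netprio.centrality import CentralityTable
from netprio.disease import DiseaseNetwork
from netprio.null_model import NullAccumulator
from netprio.ppin_io import RESULT_COLUMNS, InteractionNetwork, SeedList

log = logging.getLogger(__name__)


class PrioritizationError(ValueError):
    pass


def empirical_pvalue(r_g: int, n_g: int) -> float:
    """Empirical tail probability P = (r + 1)/(n + 1).

    ``r_g`` counts background networks where the gene's betweenness beat its
    disease-network value; ``n_g`` counts background networks where the gene
    was present at all. The degenerate (0, 0) case yields 1.0.
    """
    if r_g < 0 or n_g < 0:
        raise PrioritizationError(f"negative counts: r={r_g}, n={n_g}")
    if r_g > n_g:
        raise PrioritizationError(f"r ({r_g}) exceeds n ({n_g})")
    return (r_g + 1) / (n_g + 1)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved.

    adjusted_(i) = min_{j >= i} p_(j) * m / j over the ascending order
    statistics, capped at 1.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise PrioritizationError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


def summarize(
    disease_bc: CentralityTable,
    acc: NullAccumulator,
    seeds: SeedList,
    alpha: float = 0.05,
    *,
    ppin: InteractionNetwork | None = None,
    disease_net: DiseaseNetwork | None = None,
) -> pd.DataFrame:
    """Per-gene prioritization table for every disease-network gene.

    p-values come from :func:`empirical_pvalue`; the BH adjustment is applied
    over the whole family of disease-network genes (seeds included).
    ``relative_bc`` is disease betweenness over the MEAN background
    betweenness across replicates where the gene was present (NaN when the
    gene was never present or the mean is 0). ``degree_ppin`` /
    ``degree_disease`` are filled when the corresponding networks are given.
    """
    if not 0 < alpha < 1:
        raise PrioritizationError(f"alpha must be in (0, 1), got {alpha}")
    genes = sorted(disease_bc.values)
    ppin_deg = ppin.degrees() if ppin is not None else {}
    dis_deg = (
        disease_net.network.degrees() if disease_net is not None else {}
    )
    missing_from_acc = [g for g in genes if g not in acc.n and acc.replicates > 0]
    if missing_from_acc:
        log.info(
            "%d gene(s) never appeared in any background network", len(missing_from_acc)
        )

    rows = []
    for g in genes:
        n_g, r_g = acc.n_g(g), acc.r_g(g)
        mean_bg = acc.mean_bc(g)
        bc = disease_bc.values[g]
        rel = (
            bc / mean_bg
            if n_g > 0 and not math.isnan(mean_bg) and mean_bg > 0
            else float("nan")
        )
        rows.append(
            {
                "gene": g,
                "degree_ppin": ppin_deg.get(g, np.nan),
                "degree_disease": dis_deg.get(g, np.nan),
                "bc_disease": bc,
                "mean_bc_random": mean_bg,
                "relative_bc": rel,
                "n_g": n_g,
                "r_g": r_g,
                "p_value": empirical_pvalue(r_g, n_g),
                "is_seed": g in seeds.symbols,
            }
        )
    df = pd.DataFrame(rows)
    df["p_adjusted"] = bh_adjust(df["p_value"].to_numpy())
    df["is_significant"] = df["p_adjusted"] < alpha
    df["is_novel"] = df["is_significant"] & ~df["is_seed"]
    df = df[RESULT_COLUMNS]
    return df.sort_values(["p_value", "gene"], kind="stable").reset_index(drop=True)


@dataclass(frozen=True)
class OverlapTest:
    """Hypergeometric upper-tail test of the overlap between two gene lists."""

    a: int
    b: int
    k: int
    universe: int
    p_value: float
    overlap_genes: tuple

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "a": self.a,
                    "b": self.b,
                    "k": self.k,
                    "N": self.universe,
                    "p_value": self.p_value,
                    "overlap_genes": ",".join(self.overlap_genes),
                }
            ]
        )


def overlap_test(
    novel_a: Iterable[str], novel_b: Iterable[str], universe: Iterable[str]
) -> OverlapTest:
    """P(overlap >= k) when drawing |a| genes from the universe with |b| successes."""
    set_a, set_b, set_u = set(novel_a), set(novel_b), set(universe)
    if not set_a <= set_u or not set_b <= set_u:
        raise PrioritizationError("gene lists must be subsets of the universe")
    k = len(set_a & set_b)
    n_u, n_a, n_b = len(set_u), len(set_a), len(set_b)
    p = float(hypergeom.sf(k - 1, n_u, n_b, n_a))
    p = min(max(p, 0.0), 1.0)
    return OverlapTest(
        a=n_a,
        b=n_b,
        k=k,
        universe=n_u,
        p_value=p,
        overlap_genes=tuple(sorted(set_a & set_b)),
    )
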