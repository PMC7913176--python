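"""Read, clean, and canonicalize protein-interaction edge lists, seed lists and symbol maps.

All gene symbols are normalized once on input: surrounding whitespace stripped
and letters uppercased. Comparisons after that point are case-sensitive exact
matches. Placeholder tokens (``-``, ``N/A``, empty) are treated as missing.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import networkx as nx
import pandas as pd

log = logging.getLogger(__name__)

DIALECTS = ("generic_tsv", "biogrid_tab3", "hprd_flat")

_MISSING_TOKENS = {"", "-", "N/A", "NA", "NONE"}
_HUMAN_TAXON = "9606"
_HUMAN_NAME = "HOMO SAPIENS"

#: header for prioritization result tables (see :func:`write_results`)
RESULT_COLUMNS = [
    "gene",
    "degree_ppin",
    "degree_disease",
    "bc_disease",
    "mean_bc_random",
    "relative_bc",
    "n_g",
    "r_g",
    "p_value",
    "p_adjusted",
    "is_seed",
    "is_significant",
    "is_novel",
]

_SYMBOL_RE = re.compile(r"^[A-Z0-9][A-Z0-9._@/-]*$")

# lowercase header tokens commonly seen atop two-column edge lists
_HEADER_WORDS = {
    "gene", "gene1", "gene2", "gene_a", "gene_b", "genea", "geneb",
    "source", "target", "node1", "node2", "symbol", "symbol_a", "symbol_b",
    "interactor_a", "interactor_b", "protein1", "protein2", "from", "to",
}


class NetworkReadError(ValueError):
    """Malformed or unusable network input."""


class EmptyNetworkError(NetworkReadError):
    """No edges survived cleaning."""


def normalize_symbol(raw: object) -> str:
    """Uppercase-and-strip a raw symbol; return '' for missing placeholders."""
    if raw is None or (isinstance(raw, float) and raw != raw):
        return ""
    sym = str(raw).strip().upper()
    if sym in _MISSING_TOKENS:
        return ""
    return sym


@dataclass
class InteractionNetwork:
    """Undirected simple graph of gene symbols.

    Invariants: no self-loops, no duplicate edges (edges are unordered pairs),
    every edge endpoint is a node. ``meta`` carries bookkeeping counts from
    reading/cleaning (dropped rows, removed self-loops, merges, ...).
    """

    graph: nx.Graph
    source_label: str = ""
    meta: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def nodes(self) -> frozenset:
        return frozenset(self.graph.nodes)

    def edges(self) -> set[frozenset]:
        return {frozenset(e) for e in self.graph.edges}

    def degrees(self) -> dict[str, int]:
        return dict(self.graph.degree)

    def validate(self) -> None:
        """Raise AssertionError if simple-graph invariants are violated."""
        assert not any(u == v for u, v in self.graph.edges), "self-loop present"
        for u, v in self.graph.edges:
            assert u in self.graph and v in self.graph


@dataclass(frozen=True)
class SeedList:
    """Unique gene symbols with a provenance label.

    May contain symbols absent from any given network; mapping loss is
    reported downstream, never fatal here.
    """

    symbols: frozenset
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.symbols)


@dataclass(frozen=True)
class SymbolMap:
    """Single-valued alias -> approved-symbol mapping.

    Aliases missing from the map pass through unchanged.
    """

    mapping: Mapping[str, str]

    def resolve(self, symbol: str) -> str:
        return self.mapping.get(symbol, symbol)

    def __len__(self) -> int:
        return len(self.mapping)


# ---------------------------------------------------------------------------
# readers


def _looks_like_header(fields: list[str]) -> bool:
    for f in fields[:2]:
        tok = f.strip()
        if not tok:
            continue
        if tok.lower() in _HEADER_WORDS:
            return True
        if not _SYMBOL_RE.match(tok.upper()):
            return True
    return False


def _iter_generic(path: Path, header: object) -> Iterator[tuple[str, str]]:
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        first = True
        for row in reader:
            if not row:
                continue
            if first:
                first = False
                if header is True or (header == "auto" and _looks_like_header(row)):
                    continue
            a = row[0] if len(row) > 0 else ""
            b = row[1] if len(row) > 1 else ""
            yield a, b


def _find_column(columns: Iterable[str], *needles: str) -> str | None:
    lowered = {c.lower(): c for c in columns}
    for needle in needles:
        if needle in lowered:
            return lowered[needle]
    return None


def _is_human(value: object) -> bool:
    tok = str(value).strip().upper()
    return tok == _HUMAN_TAXON or _HUMAN_NAME in tok


def _iter_biogrid(path: Path, counts: dict) -> Iterator[tuple[str, str]]:
    df = pd.read_csv(path, sep="\t", dtype=str, comment=None)
    col_a = _find_column(df.columns, "official symbol interactor a")
    col_b = _find_column(df.columns, "official symbol interactor b")
    org_a = _find_column(
        df.columns, "organism id interactor a", "organism name interactor a"
    )
    org_b = _find_column(
        df.columns, "organism id interactor b", "organism name interactor b"
    )
    if None in (col_a, col_b, org_a, org_b):
        raise NetworkReadError(
            f"{path}: biogrid_tab3 requires official-symbol and organism columns"
        )
    for _, row in df.iterrows():
        if not (_is_human(row[org_a]) and _is_human(row[org_b])):
            counts["rows_dropped_nonhuman"] += 1
            continue
        yield row[col_a], row[col_b]


def _iter_hprd(path: Path) -> Iterator[tuple[str, str]]:
    # HPRD binary-interaction flat file: gene symbols at fixed columns 0 and 3
    with open(path, newline="") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row:
                continue
            a = row[0] if len(row) > 0 else ""
            b = row[3] if len(row) > 3 else ""
            yield a, b


def read_network(
    path: str | Path,
    dialect: str = "generic_tsv",
    header: object = "auto",
    source_label: str | None = None,
) -> InteractionNetwork:
    """Read an undirected PPI network from an edge-list file.

    Parameters
    ----------
    path:
        Input file.
    dialect:
        One of ``generic_tsv`` (two symbol columns), ``biogrid_tab3``
        (named official-symbol + organism columns; non-human rows dropped) or
        ``hprd_flat`` (gene symbols at fixed positions 0 and 3, no header).
    header:
        For ``generic_tsv`` only: ``"auto"`` (detect a header row from
        non-symbol tokens), ``True`` (skip first row) or ``False``.

    Returns a simple graph: rows with missing symbols are dropped and counted,
    self-loops removed, duplicate edges collapsed (``meta`` records all counts).
    """
    path = Path(path)
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    if not path.exists():
        raise FileNotFoundError(path)

    counts = {
        "rows_total": 0,
        "rows_dropped_missing": 0,
        "rows_dropped_nonhuman": 0,
        "candidate_edges": 0,
        "self_loops_removed": 0,
        "duplicate_edges_removed": 0,
    }
    if dialect == "generic_tsv":
        pairs = _iter_generic(path, header)
    elif dialect == "biogrid_tab3":
        pairs = _iter_biogrid(path, counts)
    else:
        pairs = _iter_hprd(path)

    graph = nx.Graph()
    for raw_a, raw_b in pairs:
        counts["rows_total"] += 1
        a, b = normalize_symbol(raw_a), normalize_symbol(raw_b)
        if not a or not b:
            counts["rows_dropped_missing"] += 1
            continue
        counts["candidate_edges"] += 1
        if a == b:
            counts["self_loops_removed"] += 1
            continue
        if graph.has_edge(a, b):
            counts["duplicate_edges_removed"] += 1
            continue
        graph.add_edge(a, b)
    counts["rows_total"] += counts["rows_dropped_nonhuman"]

    if graph.number_of_edges() == 0:
        raise EmptyNetworkError(
            f"{path}: no edges survived cleaning (dialect={dialect})"
        )
    label = source_label if source_label is not None else path.stem
    net = InteractionNetwork(graph=graph, source_label=label, meta=counts)
    log.info(
        "read %s (%s): %d nodes, %d edges; dropped %d missing-symbol and %d "
        "non-human rows, %d self-loops, %d duplicates",
        path, dialect, net.n_nodes, net.n_edges,
        counts["rows_dropped_missing"], counts["rows_dropped_nonhuman"],
        counts["self_loops_removed"], counts["duplicate_edges_removed"],
    )
    return net


def read_seed_list(path: str | Path, provenance: str | None = None) -> SeedList:
    """Read a seed gene list: one symbol per line, '#' starts a comment."""
    path = Path(path)
    symbols = set()
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0]
            sym = normalize_symbol(line)
            if sym:
                symbols.add(sym)
    return SeedList(
        symbols=frozenset(symbols),
        provenance=provenance if provenance is not None else str(path),
    )


def read_symbol_map(path: str | Path) -> SymbolMap:
    """Read a two-column alias -> approved-symbol TSV.

    Raises ``ValueError`` if an alias maps to two different symbols.
    """
    mapping: dict[str, str] = {}
    with open(path, newline="") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if len(row) < 2:
                continue
            alias, approved = normalize_symbol(row[0]), normalize_symbol(row[1])
            if not alias or not approved:
                continue
            if alias in mapping and mapping[alias] != approved:
                raise ValueError(
                    f"{path}: alias {alias} maps to both {mapping[alias]} and {approved}"
                )
            mapping[alias] = approved
    return SymbolMap(mapping=mapping)


# ---------------------------------------------------------------------------
# transforms


def apply_symbol_map(net: InteractionNetwork, symbol_map: SymbolMap) -> InteractionNetwork:
    """Relabel every node through the map (identity when absent).

    Nodes collapsing onto one approved symbol have their edge sets merged;
    self-loops created by merging are removed. The merge count is logged and
    stored in ``meta['nodes_merged']``.
    """
    mapping = {v: symbol_map.resolve(v) for v in net.graph.nodes}
    relabeled = nx.relabel_nodes(net.graph, mapping, copy=True)
    merged = net.graph.number_of_nodes() - relabeled.number_of_nodes()
    relabeled.remove_edges_from(nx.selfloop_edges(relabeled))
    if merged:
        log.info("symbol map merged %d node(s) in %s", merged, net.source_label)
    meta = dict(net.meta)
    meta["nodes_merged"] = merged
    return InteractionNetwork(graph=relabeled, source_label=net.source_label, meta=meta)


def giant_component(net: InteractionNetwork) -> InteractionNetwork:
    """Return the largest connected component.

    Size ties are broken deterministically by the lexicographically smallest
    member symbol.
    """
    if net.n_nodes == 0:
        raise EmptyNetworkError(f"{net.source_label or 'network'}: empty network")
    components = sorted(
        nx.connected_components(net.graph), key=lambda c: (-len(c), min(c))
    )
    best = components[0]
    if len(best) == net.n_nodes:
        return net
    sub = net.graph.subgraph(best).copy()
    meta = dict(net.meta)
    meta["giant_component_fraction"] = len(best) / net.n_nodes
    return InteractionNetwork(graph=sub, source_label=net.source_label, meta=meta)


# ---------------------------------------------------------------------------
# result tables


def write_results(results: pd.DataFrame, path: str | Path) -> None:
    """Write a prioritization table as TSV.

    Columns follow :data:`RESULT_COLUMNS`; rows sorted by p_value then gene.
    """
    df = results.copy()
    for col in RESULT_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"results table missing column {col!r}")
    df = df[RESULT_COLUMNS].sort_values(["p_value", "gene"], kind="stable")
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_results(path: str | Path) -> pd.DataFrame:
    """Read back a TSV written by :func:`write_results`."""
    df = pd.read_csv(path, sep="\t")
    for col in ("is_seed", "is_significant", "is_novel"):
        if col in df.columns:
            df[col] = df[col].astype(bool)
    return df
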