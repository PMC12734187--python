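"""Domain types and file I/O shared by the whole pipeline.

Gene identifiers are treated as opaque symbols, case-normalized to uppercase.
Node order is always canonical (lexicographic), so loading the same inputs
twice yields identical indexing and therefore identical matrices downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("mdignn")

__all__ = [
    "GeneGraph",
    "LabelSet",
    "FeatureMatrix",
    "RunConfig",
    "read_edge_list",
    "read_labels",
    "read_feature_table",
    "write_edge_list",
    "write_predictions",
    "load_config",
    "save_config",
]


def normalize_symbol(symbol: str) -> str:
    """Canonical form of a gene symbol: stripped, uppercased."""
    return symbol.strip().upper()


@dataclass(frozen=True)
class GeneGraph:
    """A directed gene network.

    ``nodes`` is the canonical (lexicographic) roster of unique gene symbols;
    ``edges`` is a list of ``(source_index, target_index, weight, tags)``
    with at most one entry per directed (source, target) pair and no
    self-loops. ``tags`` is a frozenset of source-database names.
    """

    nodes: tuple[str, ...]
    edges: tuple[tuple[int, int, float, frozenset[str]], ...]
    directed: bool = True

    def __post_init__(self):
        n = len(self.nodes)
        if len(set(self.nodes)) != n:
            raise ValueError("duplicate node identifiers")
        seen = set()
        for u, v, w, _ in self.edges:
            if not (0 <= u < n and 0 <= v < n):
                raise ValueError(f"edge endpoint ({u},{v}) out of range")
            if u == v:
                raise ValueError(f"self-loop at node {self.nodes[u]}")
            if (u, v) in seen:
                raise ValueError(f"duplicate edge ({self.nodes[u]},{self.nodes[v]})")
            if not (0.0 < w <= 1.0):
                raise ValueError(f"edge weight {w} outside (0, 1]")
            seen.add((u, v))

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def node_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.nodes)}

    def edge_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """(sources, targets) index arrays; empty int arrays for an edgeless graph."""
        if not self.edges:
            return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
        arr = np.asarray([(u, v) for u, v, _, _ in self.edges], dtype=np.int64)
        return arr[:, 0], arr[:, 1]

    def tags(self) -> frozenset[str]:
        out: set[str] = set()
        for _, _, _, t in self.edges:
            out |= t
        return frozenset(out)

    @staticmethod
    def from_symbol_edges(
        edges: dict[tuple[str, str], tuple[float, frozenset[str]]],
        extra_nodes: set[str] = frozenset(),
    ) -> "GeneGraph":
        """Build a graph from {(src_symbol, tgt_symbol): (weight, tags)}."""
        roster = set(extra_nodes)
        for u, v in edges:
            roster.add(u)
            roster.add(v)
        nodes = tuple(sorted(roster))
        idx = {g: i for i, g in enumerate(nodes)}
        built = tuple(
            sorted(
                (idx[u], idx[v], w, tags)
                for (u, v), (w, tags) in edges.items()
                if u != v
            )
        )
        return GeneGraph(nodes=nodes, edges=built)


@dataclass(frozen=True)
class LabelSet:
    """Positive / negative / unknown partition of the graph's nodes."""

    positives: frozenset[str]
    negatives: frozenset[str]
    unknown: frozenset[str]

    def __post_init__(self):
        if self.positives & self.negatives:
            raise ValueError("positive and negative sets overlap")

    def masks(self, graph: GeneGraph) -> tuple[np.ndarray, np.ndarray]:
        """(y, labeled_mask): y[i]=1 for positives, 0 otherwise."""
        y = np.zeros(graph.n_nodes, dtype=np.float64)
        labeled = np.zeros(graph.n_nodes, dtype=bool)
        for i, g in enumerate(graph.nodes):
            if g in self.positives:
                y[i] = 1.0
                labeled[i] = True
            elif g in self.negatives:
                labeled[i] = True
        return y, labeled


@dataclass
class FeatureMatrix:
    """N×F real node-feature matrix aligned to a GeneGraph's node order.

    ``column_blocks`` maps block names ('biological', 'sys', 'topological')
    to (start, stop) column spans; the spans tile [0, F).
    """

    values: np.ndarray
    gene_order: tuple[str, ...]
    column_blocks: dict[str, tuple[int, int]] = field(default_factory=dict)
    column_names: tuple[str, ...] | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("feature matrix must be 2-D")
        if self.values.shape[0] != len(self.gene_order):
            raise ValueError("row count does not match gene order")
        if np.isnan(self.values).any():
            raise ValueError("feature matrix contains missing values")
        if self.column_blocks:
            width = sum(b - a for a, b in self.column_blocks.values())
            if width != self.values.shape[1]:
                raise ValueError("column block widths do not sum to F")

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def block(self, name: str) -> np.ndarray:
        a, b = self.column_blocks[name]
        return self.values[:, a:b]


@dataclass
class RunConfig:
    """Model and training configuration.

    Defaults reproduce the published architecture search result: 64 filters,
    Chebyshev order K=1, 2 layers, dropout 0.5, Adam lr 1e-3 / weight decay
    5e-3, 3000-epoch cap with patience 100, full-batch training.
    """

    q: float = 0.25
    num_filters: int = 64
    cheb_order: int = 1
    num_layers: int = 2
    dropout: float = 0.5
    edge_dropout: float = 0.1
    lr: float = 1e-3
    weight_decay: float = 5e-3
    max_epochs: int = 3000
    patience: int = 100
    seed: int = 0
    channel_attention: bool = True
    spatial_attention: bool = True
    attention_reduction: int = 8
    gcn_mode: bool = False
    use_sys: bool = True
    use_enhancement: bool = True
    network_sources: tuple[str, ...] | None = None

    def __post_init__(self):
        if self.q < 0:
            raise ValueError("q must be >= 0")
        if not (0 <= self.dropout < 1) or not (0 <= self.edge_dropout < 1):
            raise ValueError("dropout rates must be in [0, 1)")
        if self.lr <= 0 or self.weight_decay < 0:
            raise ValueError("lr must be > 0 and weight_decay >= 0")
        if self.cheb_order < 0:
            raise ValueError("Chebyshev order must be >= 0")
        if self.gcn_mode:
            self.q = 0.0

    def replace(self, **kw) -> "RunConfig":
        return replace(self, **kw)


# ---------------------------------------------------------------------------
# Readers / writers


def read_edge_list(
    path,
    score_column: int | None = None,
    min_score: float | None = None,
    tag: str = "default",
    symbol_normalizer=normalize_symbol,
) -> dict[tuple[str, str], tuple[float, frozenset[str]]]:
    """Read a TSV edge list into a symbol-keyed edge fragment.

    Rows must have >= 2 columns (source, target). If ``score_column`` is
    given (0-based), rows with score <= ``min_score`` are dropped (strict
    '>' threshold semantics). Self-loops are dropped. Returns a dict
    suitable for :meth:`GeneGraph.from_symbol_edges`.
    """
    edges: dict[tuple[str, str], tuple[float, frozenset[str]]] = {}
    tags = frozenset([tag])
    n_rows = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}: malformed row at line {lineno}: {line!r}")
            u = symbol_normalizer(parts[0])
            v = symbol_normalizer(parts[1])
            if not u or not v:
                raise ValueError(f"{path}: empty gene symbol at line {lineno}")
            n_rows += 1
            weight = 1.0
            if score_column is not None:
                if score_column >= len(parts):
                    raise ValueError(
                        f"{path}: missing score column at line {lineno}"
                    )
                try:
                    score = float(parts[score_column])
                except ValueError as exc:
                    raise ValueError(
                        f"{path}: non-numeric score at line {lineno}"
                    ) from exc
                if min_score is not None and not score > min_score:
                    continue
                weight = min(max(score, np.finfo(float).tiny), 1.0)
            if u == v:
                continue
            prev = edges.get((u, v))
            if prev is not None:
                edges[(u, v)] = (max(prev[0], weight), prev[1] | tags)
            else:
                edges[(u, v)] = (weight, tags)
    if n_rows == 0:
        logger.warning("edge list %s is empty", path)
    return edges


def write_edge_list(graph: GeneGraph, path) -> None:
    """Write a graph as TSV (source, target, weight, comma-joined tags)."""
    with open(path, "w") as fh:
        for u, v, w, tags in graph.edges:
            fh.write(
                f"{graph.nodes[u]}\t{graph.nodes[v]}\t{w:g}\t{','.join(sorted(tags))}\n"
            )


def read_labels(pos_path, neg_path, graph: GeneGraph) -> LabelSet:
    """Read positive/negative gene lists (one symbol per line).

    Genes absent from the graph are dropped (count logged). A gene present
    in both files is a hard error.
    """

    def read_set(path) -> set[str]:
        out: set[str] = set()
        with open(path) as fh:
            for line in fh:
                sym = normalize_symbol(line)
                if sym:
                    out.add(sym)
        return out

    pos, neg = read_set(pos_path), read_set(neg_path)
    both = pos & neg
    if both:
        raise ValueError(
            f"gene(s) in both label files: {', '.join(sorted(both))}"
        )
    in_graph = set(graph.nodes)
    dropped = (pos | neg) - in_graph
    if dropped:
        logger.info("dropped %d labeled genes absent from graph", len(dropped))
    pos &= in_graph
    neg &= in_graph
    return LabelSet(
        positives=frozenset(pos),
        negatives=frozenset(neg),
        unknown=frozenset(in_graph - pos - neg),
    )


def read_feature_table(path, graph: GeneGraph) -> tuple[np.ndarray, tuple[str, ...]]:
    """Read a gene-keyed TSV feature table aligned to the graph's node order.

    The first column holds gene symbols; remaining columns are numeric
    features. Genes missing from the table are zero-filled (count logged);
    table genes absent from the graph are ignored.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = [normalize_symbol(str(g)) for g in df.index]
    values = np.zeros((graph.n_nodes, df.shape[1]), dtype=np.float64)
    missing = 0
    for i, g in enumerate(graph.nodes):
        if g in df.index:
            values[i] = df.loc[g].to_numpy(dtype=np.float64)
        else:
            missing += 1
    if missing:
        logger.info("zero-filled %d genes absent from %s", missing, path)
    return values, tuple(df.columns)


def write_predictions(table: pd.DataFrame, path) -> None:
    """Write a prediction table as TSV: gene, probability, label_status, rank.

    Rows are ordered by probability descending, ties broken alphabetically
    by gene symbol.
    """
    cols = ["gene", "probability", "label_status", "rank"]
    out = table.loc[:, cols].sort_values(
        ["probability", "gene"], ascending=[False, True]
    )
    out = out.assign(rank=np.arange(1, len(out) + 1))
    out.to_csv(path, sep="\t", index=False)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "network_sources" in raw and raw["network_sources"] is not None:
        raw["network_sources"] = tuple(raw["network_sources"])
    return RunConfig(**raw)


def save_config(config: RunConfig, path) -> None:
    data = {
        k: (list(v) if isinstance(v, tuple) else v)
        for k, v in vars(config).items()
    }
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)
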