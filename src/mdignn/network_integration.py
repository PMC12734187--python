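"""Merging multi-source directed networks and undirected PPI into one graph.

Each source is an edge-list file with its own confidence-filtering rule
(numeric threshold, categorical confidence levels, or none). Undirected
sources are expanded to reciprocal directed edge pairs; duplicate directed
edges across sources collapse to a single edge that retains the union of
source tags. Confidence scores act only as ingestion filters — downstream
spectral operators use the binary adjacency.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .core_io import GeneGraph, normalize_symbol, read_edge_list

logger = logging.getLogger("mdignn")

__all__ = ["SourceSpec", "integrate", "filter_categorical", "subset_sources"]


@dataclass(frozen=True)
class SourceSpec:
    """One network source: a named edge-list file plus its filtering rule.

    ``kind`` is 'directed' or 'undirected'; ``min_score`` enables a strict
    '>' numeric threshold on ``score_column``; ``allowed_levels`` enables a
    categorical confidence filter on ``level_column``.
    """

    name: str
    path: str
    kind: str = "directed"
    score_column: int | None = None
    min_score: float | None = None
    level_column: int | None = None
    allowed_levels: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self):
        if self.kind not in ("directed", "undirected"):
            raise ValueError(f"unknown source kind {self.kind!r}")
        if self.min_score is not None and self.score_column is None:
            raise ValueError("threshold rule requires a score column")
        if self.allowed_levels and self.level_column is None:
            raise ValueError("categorical rule requires a level column")


def filter_categorical(rows: list[list[str]], allowed_levels, level_column: int):
    """Keep rows whose confidence level is in ``allowed_levels``.

    Rows with a missing level value are dropped with a warning.
    """
    allowed = {str(level).strip().lower() for level in allowed_levels}
    kept = []
    n_missing = 0
    for row in rows:
        if level_column >= len(row) or not str(row[level_column]).strip():
            n_missing += 1
            continue
        if str(row[level_column]).strip().lower() in allowed:
            kept.append(row)
    if n_missing:
        logger.warning("dropped %d rows with missing confidence level", n_missing)
    return kept


def _read_source(spec: SourceSpec) -> dict:
    if spec.allowed_levels:
        # categorical rule: pre-filter rows, then parse the survivors
        with open(spec.path) as fh:
            rows = [
                line.rstrip("\n").split("\t")
                for line in fh
                if line.strip() and not line.startswith("#")
            ]
        rows = filter_categorical(rows, spec.allowed_levels, spec.level_column)
        edges: dict = {}
        for row in rows:
            if len(row) < 2:
                raise ValueError(f"{spec.path}: malformed row {row!r}")
            u, v = normalize_symbol(row[0]), normalize_symbol(row[1])
            if u == v:
                continue
            prev = edges.get((u, v))
            tags = frozenset([spec.name])
            edges[(u, v)] = (1.0, tags if prev is None else prev[1] | tags)
        return edges
    return read_edge_list(
        spec.path,
        score_column=spec.score_column,
        min_score=spec.min_score,
        tag=spec.name,
    )


def integrate(sources: list[SourceSpec]) -> GeneGraph:
    """Merge all sources into one directed GeneGraph.

    Undirected sources contribute both edge orientations. The result is
    independent of source ordering; the node roster is the union of all
    edge endpoints, in canonical order.
    """
    if not sources:
        raise ValueError("at least one source is required")
    merged: dict[tuple[str, str], tuple[float, frozenset[str]]] = {}

    def add(u: str, v: str, w: float, tags: frozenset[str]):
        prev = merged.get((u, v))
        if prev is None:
            merged[(u, v)] = (w, tags)
        else:
            merged[(u, v)] = (max(prev[0], w), prev[1] | tags)

    for spec in sources:
        fragment = _read_source(spec)
        logger.info("source %s: %d edges retained", spec.name, len(fragment))
        for (u, v), (w, tags) in fragment.items():
            add(u, v, w, tags)
            if spec.kind == "undirected":
                add(v, u, w, tags)
    return GeneGraph.from_symbol_edges(merged)


def subset_sources(graph: GeneGraph, tags) -> GeneGraph:
    """Keep only edges tagged with at least one of ``tags``.

    Isolated nodes are retained so that feature-matrix alignment is
    preserved (ablation runs reuse the full feature matrix).
    """
    tags = frozenset(tags)
    if not tags:
        raise ValueError("tags must be nonempty")
    known = graph.tags()
    unknown = tags - known
    if unknown:
        raise ValueError(
            f"unknown tag(s) {sorted(unknown)}; graph has {sorted(known)}"
        )
    edges = tuple(e for e in graph.edges if e[3] & tags)
    return GeneGraph(nodes=graph.nodes, edges=edges)
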