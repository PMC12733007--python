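"""Directed TF graph construction and cascade (simple-path) enumeration.

A cascade is a maximal simple directed path rooted at a source node
(in-degree 0). Chain length is the number of TFs in the path; the cascade
level is length - 1 and is reported as the label ``L{level}``. Enumeration
is a depth-first search with visited-set cycle pruning, lexicographic
neighbour order, and exact-duplicate removal, so output is deterministic
across runs and platforms.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Optional

import networkx as nx
import pandas as pd

from .extraction import DirectedEdge

logger = logging.getLogger(__name__)

DEFAULT_MAX_LENGTH = 64
DEFAULT_MAX_CASCADES = 1_000_000


class TruncationWarning(UserWarning):
    """Enumeration hit a safety cap; results are a truncated subset."""


@dataclass(frozen=True)
class Cascade:
    """An ordered chain of distinct TFs; level = chain length - 1."""

    chain: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.chain) != len(set(self.chain)):
            raise ValueError(f"cascade chain revisits a node: {self.chain}")
        if len(self.chain) < 1:
            raise ValueError("empty cascade")

    @property
    def length(self) -> int:
        return len(self.chain)

    @property
    def level(self) -> int:
        return len(self.chain) - 1

    @property
    def level_label(self) -> str:
        return f"L{self.level}"


def build_graph(edges: Iterable[DirectedEdge]) -> nx.DiGraph:
    """Directed TF graph from deduplicated edges; isolated nodes excluded.

    A repeated (regulator, target) pair violates the dedup precondition and
    is rejected (collapse modes first, see ``extraction.collapse_modes``).
    """
    g = nx.DiGraph()
    for e in edges:
        if e.regulator == e.target:
            raise ValueError(f"self-loop {e.regulator} not allowed")
        if g.has_edge(e.regulator, e.target):
            raise ValueError(
                f"duplicate edge {e.regulator}->{e.target}: dedupe input first"
            )
        g.add_edge(e.regulator, e.target, mode=e.mode, score=e.score)
    logger.info("graph: %d nodes, %d edges", g.number_of_nodes(), g.number_of_edges())
    return g


def find_sources(graph: nx.DiGraph) -> list[str]:
    """Nodes with in-degree zero, sorted lexicographically."""
    return sorted(n for n in graph.nodes if graph.in_degree(n) == 0)


def enumerate_cascades(graph: nx.DiGraph,
                       max_length: int = DEFAULT_MAX_LENGTH,
                       max_cascades: int = DEFAULT_MAX_CASCADES,
                       include_prefixes: bool = False) -> list[Cascade]:
    """All maximal simple directed paths from every source node.

    A path is emitted when no out-neighbour of its last node can extend it
    without revisiting a node (maximality), or at every prefix of length
    >= 2 when ``include_prefixes`` is set. Duplicate node sequences are
    removed and output is sorted lexicographically by chain. Hitting either
    safety cap raises a loud ``TruncationWarning``; a graph whose every node
    lies on a cycle has no sources and yields an (explicitly warned) empty
    result.
    """
    if any(graph.has_edge(n, n) for n in graph.nodes):
        raise ValueError("graph has self-loops")
    sources = find_sources(graph)
    if graph.number_of_nodes() and not sources:
        warnings.warn(
            "graph has no in-degree-0 source nodes (every node lies on a "
            "cycle); no cascades enumerated",
            TruncationWarning, stacklevel=2,
        )
        return []

    neighbours = {n: sorted(graph.successors(n)) for n in graph.nodes}
    out: set[tuple[str, ...]] = set()
    truncated_length = False
    capped = False

    for source in sources:
        if capped:
            break
        # iterative DFS carrying the current path and an iterator stack
        path = [source]
        on_path = {source}
        stack = [iter(neighbours[source])]
        extended = [False]
        while stack:
            nxt = next(stack[-1], None)
            if nxt is None:
                emit = not extended[-1] or (include_prefixes and len(path) >= 2)
                if emit and len(path) >= 2:
                    out.add(tuple(path))
                    if len(out) >= max_cascades:
                        capped = True
                        break
                stack.pop()
                extended.pop()
                on_path.discard(path.pop())
                continue
            if nxt in on_path:
                continue  # cycle pruning
            extended[-1] = True
            if len(path) >= max_length:
                truncated_length = True
                # cap reached: emit the capped path itself
                out.add(tuple(path))
                if len(out) >= max_cascades:
                    capped = True
                    break
                continue
            path.append(nxt)
            on_path.add(nxt)
            stack.append(iter(neighbours[nxt]))
            extended.append(False)
            if include_prefixes and len(path) >= 2:
                out.add(tuple(path))
                if len(out) >= max_cascades:
                    capped = True
                    break

    if truncated_length:
        warnings.warn(
            f"cascades truncated at max_length={max_length}; longer paths exist",
            TruncationWarning, stacklevel=2,
        )
    if capped:
        warnings.warn(
            f"enumeration stopped at max_cascades={max_cascades}; output is "
            "a truncated subset",
            TruncationWarning, stacklevel=2,
        )

    unreached = set(graph.nodes) - {n for c in out for n in c} - set(sources)
    if unreached and graph.number_of_nodes():
        logger.info("%d node(s) unreachable from any source", len(unreached))
    return [Cascade(chain=c) for c in sorted(out)]


def to_cascade_table(cascades: Iterable[Cascade]) -> pd.DataFrame:
    """Wide NA-padded table: cascade_id, Level label, TF 1 ... TF maxlen."""
    cascades = list(cascades)
    width = max((c.length for c in cascades), default=0)
    cols = ["cascade_id", "Level"] + [f"TF {i}" for i in range(1, width + 1)]
    rows = []
    for i, c in enumerate(cascades, start=1):
        padded = list(c.chain) + [pd.NA] * (width - c.length)
        rows.append([i, c.level_label, *padded])
    return pd.DataFrame(rows, columns=cols)


def table_to_cascades(table: pd.DataFrame) -> list[Cascade]:
    """Inverse of ``to_cascade_table`` (chains only, ids dropped)."""
    tf_cols = [c for c in table.columns if c.startswith("TF ")]
    out = []
    for _, row in table.iterrows():
        chain = tuple(str(v) for v in row[tf_cols] if pd.notna(v) and v != "")
        out.append(Cascade(chain=chain))
    return out


def level_histogram(table: pd.DataFrame) -> dict[int, int]:
    """Chain length -> number of cascades; values sum to the row count."""
    tf_cols = [c for c in table.columns if c.startswith("TF ")]
    if table.empty:
        return {}
    lengths = table[tf_cols].notna().sum(axis=1)
    return {int(k): int(v) for k, v in lengths.value_counts().sort_index().items()}


def eda_summary(table: pd.DataFrame) -> dict:
    """Univariate summary of the wide cascade table.

    Per TF position: distinct symbol count, top-5 symbols with counts, and
    the structurally-missing fraction (cascades shorter than the position).
    Globals: row count, number of distinct levels, top-5 levels.
    """
    tf_cols = [c for c in table.columns if c.startswith("TF ")]
    n = len(table)
    positions = {}
    for col in tf_cols:
        s = table[col].dropna()
        counts = s.value_counts()
        positions[col] = {
            "distinct": int(counts.size),
            "top5": [(str(k), int(v)) for k, v in counts.head(5).items()],
            "missing_fraction": float((n - len(s)) / n) if n else 0.0,
        }
    level_counts = table["Level"].value_counts() if n else pd.Series(dtype=int)
    return {
        "n_rows": n,
        "n_positions": len(tf_cols),
        "n_distinct_levels": int(level_counts.size),
        "top5_levels": [(str(k), int(v)) for k, v in level_counts.head(5).items()],
        "positions": positions,
    }
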