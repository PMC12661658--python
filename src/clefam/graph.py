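"""Weighted undirected gene-gene graph container used across the pipeline."""

from __future__ import annotations

from collections.abc import Iterable, Iterator
from pathlib import Path

import networkx as nx
import pandas as pd


class SimilarityGraph:
    """Undirected weighted graph over gene identifiers.

    Edges are stored once under a canonical (sorted) node-pair key; weights
    are finite and non-negative (-log10 pseudo-E-values for sequence
    networks, distance-derived affinities for kNN graphs).  Self-edges are
    rejected.
    """

    def __init__(self, nodes: Iterable[str] = ()) -> None:
        self._nodes: set[str] = set(nodes)
        self._edges: dict[tuple[str, str], float] = {}
        self._adj: dict[str, dict[str, float]] = {n: {} for n in self._nodes}

    @staticmethod
    def _key(u: str, v: str) -> tuple[str, str]:
        return (u, v) if u <= v else (v, u)

    # -- construction -------------------------------------------------
    def add_node(self, n: str) -> None:
        if n not in self._nodes:
            self._nodes.add(n)
            self._adj[n] = {}

    def add_edge(self, u: str, v: str, weight: float) -> None:
        if u == v:
            raise ValueError(f"self-edge on node {u!r} not allowed")
        w = float(weight)
        if not (w >= 0.0) or w != w or w == float("inf"):
            raise ValueError(f"edge weight must be finite and >= 0, got {weight}")
        self.add_node(u)
        self.add_node(v)
        self._edges[self._key(u, v)] = w
        self._adj[u][v] = w
        self._adj[v][u] = w

    def remove_edge(self, u: str, v: str) -> None:
        del self._edges[self._key(u, v)]
        del self._adj[u][v]
        del self._adj[v][u]

    # -- queries ------------------------------------------------------
    @property
    def nodes(self) -> set[str]:
        return set(self._nodes)

    def edges(self) -> Iterator[tuple[str, str, float]]:
        for (u, v), w in sorted(self._edges.items()):
            yield u, v, w

    def n_edges(self) -> int:
        return len(self._edges)

    def has_edge(self, u: str, v: str) -> bool:
        return self._key(u, v) in self._edges

    def weight(self, u: str, v: str) -> float:
        return self._edges[self._key(u, v)]

    def neighbors(self, n: str) -> dict[str, float]:
        return dict(self._adj[n])

    def degree(self, n: str) -> int:
        return len(self._adj[n])

    def copy(self) -> "SimilarityGraph":
        g = SimilarityGraph(self._nodes)
        for (u, v), w in self._edges.items():
            g.add_edge(u, v, w)
        return g

    def __len__(self) -> int:
        return len(self._nodes)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SimilarityGraph):
            return NotImplemented
        return self._nodes == other._nodes and self._edges == other._edges

    # -- conversions --------------------------------------------------
    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(sorted(self._nodes))
        for (u, v), w in self._edges.items():
            g.add_edge(u, v, weight=w)
        return g

    def connected_components(self) -> list[set[str]]:
        return [set(c) for c in nx.connected_components(self.to_networkx())]

    # -- I/O ----------------------------------------------------------
    def to_tsv(self, path: str | Path) -> None:
        rows = [(u, v, w) for u, v, w in self.edges()]
        df = pd.DataFrame(rows, columns=["gene_a", "gene_b", "weight"])
        df.to_csv(path, sep="\t", index=False)
        # isolated nodes are carried in a sidecar comment-free node file
        # only when needed by callers; edge list is the primary exchange.

    @classmethod
    def from_tsv(cls, path: str | Path, nodes: Iterable[str] = ()) -> "SimilarityGraph":
        df = pd.read_csv(path, sep="\t")
        g = cls(nodes)
        for row in df.itertuples(index=False):
            g.add_edge(str(row.gene_a), str(row.gene_b), float(row.weight))
        return g
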