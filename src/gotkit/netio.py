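"""Temporal network containers and edge-list I/O.

A temporal network is an ordered sequence of snapshots over a shared node
universe with active-edge semantics: an edge belongs to the snapshot(s) in
which it is observed and must re-appear to persist.  Edge lists are plain
whitespace-separated text — ``source target snapshot`` for temporal
networks, ``source target`` for static ones — with ``#`` comment lines.

Node ids are opaque strings; each TemporalNetwork maps them to dense
integers (stable across snapshots) for the census and transition machinery.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import networkx as nx
import pandas as pd

logger = logging.getLogger("gotkit")

__all__ = [
    "Snapshot",
    "TemporalNetwork",
    "read_temporal_edgelist",
    "write_temporal_edgelist",
    "read_static_edgelist",
    "write_static_edgelist",
    "aggregate",
    "global_metrics",
]


def _norm_edge(u: str, v: str) -> tuple[str, str]:
    return (u, v) if u <= v else (v, u)


@dataclass(frozen=True)
class Snapshot:
    """One time slice: an undirected simple graph (no self-loops), possibly
    with declared isolated nodes."""
    nodes: frozenset
    edges: frozenset  # of lexicographically ordered (u, v) tuples

    @classmethod
    def from_edges(cls, edges: Iterable[tuple[str, str]],
                   nodes: Iterable[str] = (),
                   drop_self_loops: bool = False) -> "Snapshot":
        es = set()
        dropped = 0
        for u, v in edges:
            if u == v:
                if not drop_self_loops:
                    raise ValueError(f"self-loop on node {u!r}")
                dropped += 1
                continue
            es.add(_norm_edge(u, v))
        if dropped:
            logger.warning("dropped %d self-loop(s)", dropped)
        ns = set(nodes)
        for u, v in es:
            ns.add(u)
            ns.add(v)
        return cls(nodes=frozenset(ns), edges=frozenset(es))

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g

    def int_adjacency(self, node_index: dict) -> dict[int, set[int]]:
        """Adjacency over dense integer ids (only nodes present here)."""
        adj: dict[int, set[int]] = {node_index[n]: set() for n in self.nodes}
        for u, v in self.edges:
            iu, iv = node_index[u], node_index[v]
            adj[iu].add(iv)
            adj[iv].add(iu)
        return adj


@dataclass
class TemporalNetwork:
    """Ordered snapshots over a shared node universe.

    ``meta`` may carry the informational start time and snapshot interval
    of the observation window (they never enter any computation) plus
    provenance such as the generating model.
    """
    snapshots: list[Snapshot]
    name: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.snapshots:
            raise ValueError("a temporal network needs at least one snapshot")

    @property
    def n_snapshots(self) -> int:
        return len(self.snapshots)

    @property
    def node_index(self) -> dict:
        """Stable node-id -> dense integer mapping over all snapshots."""
        universe = set()
        for s in self.snapshots:
            universe |= s.nodes
        return {n: i for i, n in enumerate(sorted(universe))}


def read_temporal_edgelist(path, name: str | None = None) -> TemporalNetwork:
    """Parse ``source target snapshot`` lines into a TemporalNetwork.

    Snapshot indices are 0-based; max(index) + 1 snapshots are produced and
    missing intermediate indices yield empty snapshots.  Duplicate edges
    within a snapshot collapse, self-loops are dropped with a warning.
    """
    path = Path(path)
    per_t: dict[int, set] = {}
    self_loops = 0
    n_lines = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise ValueError(
                    f"{path}:{lineno}: expected 'source target snapshot', got {line!r}")
            u, v, t_str = parts[0], parts[1], parts[2]
            try:
                t = int(t_str)
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: snapshot index {t_str!r} is not an integer")
            if t < 0:
                raise ValueError(f"{path}:{lineno}: negative snapshot index {t}")
            n_lines += 1
            if u == v:
                self_loops += 1
                continue
            per_t.setdefault(t, set()).add(_norm_edge(u, v))
    if n_lines == 0:
        raise ValueError(f"{path}: no edges found")
    if self_loops:
        logger.warning("%s: dropped %d self-loop(s)", path, self_loops)
    n_snap = max(per_t) + 1 if per_t else 1
    snapshots = [
        Snapshot.from_edges(per_t.get(t, ())) for t in range(n_snap)
    ]
    return TemporalNetwork(snapshots=snapshots, name=name or path.stem)


def write_temporal_edgelist(net: TemporalNetwork, path) -> None:
    with open(path, "w") as fh:
        for t, snap in enumerate(net.snapshots):
            for u, v in sorted(snap.edges):
                fh.write(f"{u}\t{v}\t{t}\n")


def read_static_edgelist(path) -> Snapshot:
    edges = []
    path = Path(path)
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ValueError(
                    f"{path}:{lineno}: expected 'source target', got {line!r}")
            edges.append((parts[0], parts[1]))
    if not edges:
        raise ValueError(f"{path}: no edges found")
    return Snapshot.from_edges(edges, drop_self_loops=True)


def write_static_edgelist(snapshot: Snapshot, path) -> None:
    with open(path, "w") as fh:
        for u, v in sorted(snapshot.edges):
            fh.write(f"{u}\t{v}\n")


def aggregate(net: TemporalNetwork) -> Snapshot:
    """Union of all snapshot edge and node sets (the aggregate network)."""
    nodes: set = set()
    edges: set = set()
    for s in net.snapshots:
        nodes |= s.nodes
        edges |= s.edges
    return Snapshot(nodes=frozenset(nodes), edges=frozenset(edges))


def global_metrics(net: TemporalNetwork) -> pd.DataFrame:
    """Per-snapshot global summary metrics.

    Columns: node count, edge count, average degree (2|E|/|V|), global
    clustering coefficient (transitivity) and the characteristic path
    length of the largest connected component (0 when fewer than 2 nodes).
    """
    records = []
    for t, snap in enumerate(net.snapshots):
        g = snap.to_networkx()
        n, m = snap.n_nodes, snap.n_edges
        avg_deg = 2 * m / n if n else 0.0
        clust = nx.transitivity(g) if n else 0.0
        cpl = 0.0
        if n >= 2:
            lcc = max(nx.connected_components(g), key=len)
            if len(lcc) >= 2:
                cpl = nx.average_shortest_path_length(g.subgraph(lcc))
        records.append({"snapshot": t, "nodes": n, "edges": m,
                        "avg_degree": avg_deg, "clustering": clust,
                        "path_length": cpl})
    return pd.DataFrame.from_records(records).set_index("snapshot")
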