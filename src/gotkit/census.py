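"""Subgraph census: connected induced k-subgraph enumeration and
per-node orbit frequencies.

Enumeration uses ESU-style recursive extension (grow a subgraph only
through nodes outside the closed neighbourhood and with a higher id than
the root), which yields every connected induced k-node subset exactly
once.  From the enumerated occurrences the per-node orbit-frequency
matrix Fr — whose row for node u is its graphlet degree vector GDV(u) —
and the derived graphlet degree distribution (GDD) are computed.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np
import pandas as pd

from .catalog import GraphletCatalog, pair_order
from .netio import Snapshot

__all__ = [
    "enumerate_connected",
    "orbit_frequency_matrix",
    "graphlet_frequencies",
    "gdd_from_fr",
    "ndd",
]

_K_RANGE = (2, 6)


def _check_census_k(k: int) -> None:
    if not _K_RANGE[0] <= k <= _K_RANGE[1]:
        raise ValueError(f"census size k={k} outside supported range {_K_RANGE}")


def _esu(adj: dict[int, set[int]], k: int) -> Iterator[tuple[int, ...]]:
    """Yield every k-node set with a connected induced subgraph, once."""
    if k == 1:
        for v in adj:
            yield (v,)
        return

    def extend(sub: tuple[int, ...], ext: set[int], closed: set[int], root: int):
        if len(sub) == k - 1:
            for w in ext:
                yield tuple(sorted(sub + (w,)))
            return
        ext = set(ext)
        while ext:
            w = ext.pop()
            new_ext = ext | {u for u in adj[w] if u > root and u not in closed}
            yield from extend(sub + (w,), new_ext, closed | adj[w] | {w}, root)

    for v in adj:
        ext0 = {u for u in adj[v] if u > v}
        if ext0 or k == 1:
            yield from extend((v,), ext0, adj[v] | {v}, v)


def _occurrence_stream(adj: dict[int, set[int]], k: int,
                       pairs: list[tuple[int, int]]) -> Iterator[tuple[tuple[int, ...], int]]:
    """Yield (sorted node tuple, adjacency bit mask) per occurrence."""
    for occ in _esu(adj, k):
        mask = 0
        for b, (i, j) in enumerate(pairs):
            if occ[j] in adj[occ[i]]:
                mask |= 1 << b
        yield occ, mask


def enumerate_connected(snapshot: Snapshot, k: int,
                        node_index: dict | None = None) -> Iterator[tuple]:
    """Stream every node set of size k inducing a connected subgraph.

    Node tuples are sorted by the internal dense integer order (the sorted
    order of node ids when ``node_index`` is not supplied); this ordering
    is the matching key used for cross-snapshot transition pairing.
    """
    _check_census_k(k)
    if node_index is None:
        node_index = {n: i for i, n in enumerate(sorted(snapshot.nodes))}
    inv = {i: n for n, i in node_index.items()}
    adj = snapshot.int_adjacency(node_index)
    for occ in _esu(adj, k):
        yield tuple(inv[i] for i in occ)


def occurrence_orbits(snapshot: Snapshot, catalog: GraphletCatalog,
                      node_index: dict) -> dict[tuple[int, ...], tuple[int, ...]]:
    """Index all occurrences of one snapshot by sorted integer node tuple,
    mapped to the global orbit id of each node (same order)."""
    adj = snapshot.int_adjacency(node_index)
    pairs = pair_order(catalog.k, catalog.directed)
    out: dict[tuple[int, ...], tuple[int, ...]] = {}
    for occ, mask in _occurrence_stream(adj, catalog.k, pairs):
        out[occ] = catalog.orbits_for_mask(mask)
    return out


def orbit_frequency_matrix(snapshot: Snapshot, catalog: GraphletCatalog,
                           node_index: dict | None = None) -> pd.DataFrame:
    """Node x orbit count matrix Fr: entry (u, j) is the number of induced
    occurrences in which node u sits in orbit j.  Rows are GDV(u)."""
    if node_index is None:
        node_index = {n: i for i, n in enumerate(sorted(snapshot.nodes))}
    adj = snapshot.int_adjacency(node_index)
    pairs = pair_order(catalog.k, catalog.directed)
    m = catalog.orbit_count
    counts = np.zeros((len(node_index), m), dtype=np.int64)
    for occ, mask in _occurrence_stream(adj, catalog.k, pairs):
        orbs = catalog.orbits_for_mask(mask)
        for v, o in zip(occ, orbs):
            counts[v, o - 1] += 1
    ids = sorted(node_index, key=node_index.get)
    return pd.DataFrame(counts, index=pd.Index(ids, name="node"),
                        columns=pd.Index(catalog.orbit_ids, name="orbit"))


def graphlet_frequencies(snapshot: Snapshot, catalog: GraphletCatalog) -> pd.Series:
    """Induced occurrence count per graphlet isomorphism class."""
    node_index = {n: i for i, n in enumerate(sorted(snapshot.nodes))}
    adj = snapshot.int_adjacency(node_index)
    pairs = pair_order(catalog.k, catalog.directed)
    counts = np.zeros(len(catalog.graphlets), dtype=np.int64)
    for _, mask in _occurrence_stream(adj, catalog.k, pairs):
        counts[catalog.graphlet_for_mask(mask)] += 1
    return pd.Series(counts, index=pd.RangeIndex(len(counts), name="graphlet"))


def gdd_from_fr(fr: pd.DataFrame) -> pd.DataFrame:
    """Graphlet degree distribution: GDD[j, p] = number of nodes appearing
    exactly p >= 1 times in orbit j."""
    values = fr.to_numpy()
    pmax = int(values.max()) if values.size else 0
    gdd = np.zeros((fr.shape[1], pmax), dtype=np.int64)
    for col in range(fr.shape[1]):
        bc = np.bincount(values[:, col], minlength=pmax + 1)
        gdd[col, :] = bc[1:pmax + 1]
    return pd.DataFrame(gdd, index=fr.columns.rename("orbit"),
                        columns=pd.RangeIndex(1, pmax + 1, name="p"))


def ndd(snapshot: Snapshot) -> pd.Series:
    """Node degree distribution: entry p is the number of nodes of degree p."""
    deg: dict = {n: 0 for n in snapshot.nodes}
    for u, v in snapshot.edges:
        deg[u] += 1
        deg[v] += 1
    dmax = max(deg.values(), default=0)
    counts = np.bincount(list(deg.values()), minlength=dmax + 1)
    return pd.Series(counts, index=pd.RangeIndex(0, dmax + 1, name="p"))
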