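"""Graphlet-orbit transition matrices.

For every pair of consecutive snapshots (t, t+1), every node set whose
induced subgraph is connected in *both* snapshots contributes one
transition per node: from its orbit at t to its orbit at t+1.  Node sets
connected in only one of the two snapshots contribute nothing — a group
that disconnects stops being a group.  Matching is by the sorted integer
node tuple, so nodes leaving the network simply never match.

The raw count matrix T is row-normalized (each row divided by its sum;
all-zero rows stay zero) before entering the orbit-transition-agreement
comparison, and can be discretized into rare / common / frequent bands
for visualization.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .catalog import GraphletCatalog
from .census import occurrence_orbits
from .netio import TemporalNetwork

__all__ = [
    "got_matrix",
    "row_normalize",
    "node_transition_vectors",
    "discretize",
]


def _orbit_frame(values: np.ndarray, catalog: GraphletCatalog) -> pd.DataFrame:
    ids = pd.Index(catalog.orbit_ids, name="orbit")
    return pd.DataFrame(values, index=ids.rename("from"), columns=ids.rename("to"))


def got_matrix(net: TemporalNetwork, catalog: GraphletCatalog) -> pd.DataFrame:
    """|O| x |O| orbit-transition count matrix of a temporal network.

    Occurrence indexes are buffered for two snapshots at a time only.
    """
    if net.n_snapshots < 2:
        raise ValueError("orbit transitions need at least 2 snapshots")
    node_index = net.node_index
    m = catalog.orbit_count
    t_mat = np.zeros((m, m), dtype=np.int64)
    prev = occurrence_orbits(net.snapshots[0], catalog, node_index)
    for snap in net.snapshots[1:]:
        cur = occurrence_orbits(snap, catalog, node_index)
        small, other, flip = (prev, cur, False) if len(prev) <= len(cur) else (cur, prev, True)
        for key, orbs_s in small.items():
            orbs_o = other.get(key)
            if orbs_o is None:
                continue
            a, b = (orbs_o, orbs_s) if flip else (orbs_s, orbs_o)
            for x, y in zip(a, b):
                t_mat[x - 1, y - 1] += 1
        prev = cur
    df = _orbit_frame(t_mat, catalog)
    df.attrs["name"] = net.name
    df.attrs["k"] = catalog.k
    return df


def node_transition_vectors(net: TemporalNetwork,
                            catalog: GraphletCatalog) -> pd.DataFrame:
    """Per-node flattened transition counts (node x |O|^2).

    Summing the rows over all nodes reproduces ``got_matrix`` exactly.
    """
    if net.n_snapshots < 2:
        raise ValueError("orbit transitions need at least 2 snapshots")
    node_index = net.node_index
    m = catalog.orbit_count
    vec = np.zeros((len(node_index), m * m), dtype=np.int64)
    prev = occurrence_orbits(net.snapshots[0], catalog, node_index)
    for snap in net.snapshots[1:]:
        cur = occurrence_orbits(snap, catalog, node_index)
        for key, orbs_a in prev.items():
            orbs_b = cur.get(key)
            if orbs_b is None:
                continue
            for v, x, y in zip(key, orbs_a, orbs_b):
                vec[v, (x - 1) * m + (y - 1)] += 1
        prev = cur
    ids = sorted(node_index, key=node_index.get)
    cols = pd.MultiIndex.from_product(
        [catalog.orbit_ids, catalog.orbit_ids], names=["from", "to"])
    return pd.DataFrame(vec, index=pd.Index(ids, name="node"), columns=cols)


def row_normalize(t: pd.DataFrame) -> pd.DataFrame:
    """Divide each row by its sum; all-zero rows remain all-zero."""
    values = t.to_numpy(dtype=float)
    sums = values.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(sums > 0, values / np.where(sums > 0, sums, 1.0), 0.0)
    df = pd.DataFrame(out, index=t.index, columns=t.columns)
    df.attrs.update(t.attrs)
    return df


_BANDS = ("rare", "common", "frequent")


def discretize(ntr: pd.DataFrame) -> pd.DataFrame:
    """Map normalized transition rates into three bands:
    rare [0, 1/3], common ]1/3, 2/3], frequent ]2/3, 1]."""
    values = ntr.to_numpy(dtype=float)
    if values.size and (values.min() < 0 or values.max() > 1):
        raise ValueError("normalized transition values must lie in [0, 1]")
    cats = np.full(values.shape, _BANDS[0], dtype=object)
    cats[values > 1 / 3] = _BANDS[1]
    cats[values > 2 / 3] = _BANDS[2]
    return pd.DataFrame(cats, index=ntr.index, columns=ntr.columns)
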