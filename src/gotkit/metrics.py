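"""Network-comparison metrics.

* OTA — orbit-transition agreement: mean elementwise agreement
  ``1 - |ntr_a - ntr_b|`` between two row-normalized transition matrices;
  nOTA rescales an OTA matrix affinely so the most similar off-diagonal
  pair scores 1 and the most different 0.
* GDA — graphlet-degree-distribution agreement between two networks'
  area-normalized GDD matrices.
* Motif fingerprints — per-graphlet over/under-representation scores
  against a degree-preserving randomized null ensemble, compared by
  Euclidean distance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .catalog import GraphletCatalog
from .census import graphlet_frequencies
from .netio import Snapshot

logger = logging.getLogger("gotkit")

__all__ = [
    "ota",
    "pairwise_ota",
    "nota",
    "gdd_normalize",
    "gda",
    "randomize_degree_preserving",
    "MotifFingerprint",
    "motif_fingerprint",
    "fingerprint_distance",
]


def _values(x) -> np.ndarray:
    return x.to_numpy(dtype=float) if isinstance(x, pd.DataFrame) else np.asarray(x, dtype=float)


def ota(a, b) -> float:
    """Orbit-transition agreement of two row-normalized |O| x |O| matrices:
    ``(1/|O|^2) * sum(1 - |a_ij - b_ij|)``; symmetric, in [0, 1]."""
    va, vb = _values(a), _values(b)
    if va.shape != vb.shape:
        raise ValueError(f"transition matrices differ in shape: {va.shape} vs {vb.shape}")
    return float(np.mean(1.0 - np.abs(va - vb)))


def pairwise_ota(matrices: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Symmetric OTA matrix over a named set of row-normalized transition
    matrices."""
    names = list(matrices)
    n = len(names)
    out = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = ota(matrices[names[i]], matrices[names[j]])
    df = pd.DataFrame(out, index=names, columns=names)
    df.attrs["kind"] = "OTA"
    return df


def nota(ota_matrix: pd.DataFrame) -> pd.DataFrame:
    """Relative agreement: min-max rescale OTA over off-diagonal pairs so
    the most similar pair maps to 1 and the most different to 0.  The
    diagonal (self-agreement) is set to 1.  A degenerate set where all
    pairs agree equally maps to all 1 with a warning."""
    v = ota_matrix.to_numpy(dtype=float)
    n = v.shape[0]
    if n < 2:
        raise ValueError("nOTA needs at least 2 networks")
    off = ~np.eye(n, dtype=bool)
    lo, hi = v[off].min(), v[off].max()
    if hi == lo:
        logger.warning("degenerate network set: all OTA values equal; nOTA set to 1")
        out = np.ones_like(v)
    else:
        out = (v - lo) / (hi - lo)
        np.fill_diagonal(out, 1.0)
    df = pd.DataFrame(out, index=ota_matrix.index, columns=ota_matrix.columns)
    df.attrs["kind"] = "nOTA"
    return df


def gdd_normalize(gdd: pd.DataFrame) -> pd.DataFrame:
    """Normalize a GDD by its total area (the grand sum of all cells)."""
    total = float(gdd.to_numpy().sum())
    if total == 0:
        raise ValueError("cannot normalize an all-zero GDD")
    return gdd / total


def _aligned(g: pd.DataFrame, h: pd.DataFrame):
    if not g.index.equals(h.index):
        raise ValueError("GDD matrices come from different orbit catalogs")
    pmax = max(g.shape[1], h.shape[1])
    cols = pd.RangeIndex(1, pmax + 1, name="p")
    return (g.reindex(columns=cols, fill_value=0),
            h.reindex(columns=cols, fill_value=0))


def gda(g: pd.DataFrame, h: pd.DataFrame) -> float:
    """Arithmetic-mean GDD-agreement between two networks.

    Per orbit j: ``1 - (1/sqrt(2)) * ||nG_j - nH_j||`` over the multiplicity
    axis (padded to the larger observed maximum); the final score is the
    mean over orbits, in [0, 1].
    """
    ga, ha = _aligned(g, h)
    ng = gdd_normalize(ga).to_numpy()
    nh = gdd_normalize(ha).to_numpy()
    per_orbit = 1.0 - np.sqrt(((ng - nh) ** 2).sum(axis=1)) / np.sqrt(2.0)
    return float(per_orbit.mean())


def randomize_degree_preserving(snapshot: Snapshot, swaps: int | None = None,
                                seed: int = 0) -> Snapshot:
    """Degree-preserving randomization by repeated double-edge swaps.

    Each attempt picks two distinct edges (a,b), (c,d) and proposes
    (a,d), (c,b); attempts creating self-loops or duplicate edges are
    skipped.  The default budget is 10 * |E| attempts.
    """
    edges = sorted(snapshot.edges)
    if len(edges) < 2:
        return snapshot
    if swaps is None:
        swaps = 10 * len(edges)
    rng = np.random.default_rng(seed)
    edge_set = set(edges)
    n_e = len(edges)
    for _ in range(swaps):
        i, j = rng.integers(0, n_e, size=2)
        if i == j:
            continue
        a, b = edges[i]
        c, d = edges[j]
        if rng.integers(0, 2):
            c, d = d, c
        if a == d or c == b:
            continue
        e1 = (a, d) if a <= d else (d, a)
        e2 = (c, b) if c <= b else (b, c)
        if e1 in edge_set or e2 in edge_set:
            continue
        edge_set.discard(edges[i])
        edge_set.discard(edges[j])
        edge_set.add(e1)
        edge_set.add(e2)
        edges[i], edges[j] = e1, e2
    return Snapshot(nodes=snapshot.nodes, edges=frozenset(edge_set))


@dataclass
class MotifFingerprint:
    """Per-graphlet motif scores of one network against its null ensemble.

    ``delta`` is the relative over/under-representation
    (Fr - <Fr_null>) / (Fr + <Fr_null>) in [-1, 1] (0 when both vanish);
    ``delta_norm`` is delta scaled to unit Euclidean norm.
    """
    frequency: pd.Series
    null_mean: pd.Series
    delta: pd.Series
    delta_norm: pd.Series


def motif_fingerprint(snapshot: Snapshot, catalog: GraphletCatalog,
                      n_random: int = 100, seed: int = 0,
                      swaps: int | None = None) -> MotifFingerprint:
    """Motif fingerprint: graphlet frequencies of ``snapshot`` versus the
    mean over ``n_random`` degree-preserving randomizations."""
    if n_random < 1:
        raise ValueError("need at least one randomized replicate")
    freq = graphlet_frequencies(snapshot, catalog).astype(float)
    null = np.zeros(len(freq))
    rng = np.random.default_rng(seed)
    for _ in range(n_random):
        rand = randomize_degree_preserving(
            snapshot, swaps=swaps, seed=int(rng.integers(0, 2**31 - 1)))
        null += graphlet_frequencies(rand, catalog).to_numpy()
    null /= n_random
    denom = freq.to_numpy() + null
    with np.errstate(invalid="ignore", divide="ignore"):
        delta = np.where(denom > 0, (freq.to_numpy() - null) / denom, 0.0)
    norm = np.sqrt((delta ** 2).sum())
    delta_norm = delta / norm if norm > 0 else np.zeros_like(delta)
    idx = freq.index
    return MotifFingerprint(
        frequency=freq,
        null_mean=pd.Series(null, index=idx),
        delta=pd.Series(delta, index=idx),
        delta_norm=pd.Series(delta_norm, index=idx),
    )


def fingerprint_distance(a, b) -> float:
    """Euclidean distance between two fingerprint vectors."""
    va = np.asarray(a, dtype=float).ravel()
    vb = np.asarray(b, dtype=float).ravel()
    if va.shape != vb.shape:
        raise ValueError(f"fingerprint lengths differ: {va.size} vs {vb.size}")
    return float(np.linalg.norm(va - vb))
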