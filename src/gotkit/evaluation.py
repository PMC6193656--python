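"""The model-grouping experiment.

Each temporal network is summarized by one feature row — a static motif
fingerprint (SM), aggregate orbit frequencies (SG), concatenated
per-snapshot orbit frequencies (STG) or the flattened orbit-transition
count matrix (GoT) — reduced by PCA keeping 99% of the variance.
Pairwise Euclidean distances, min-max rescaled to [0, 1], are swept by a
threshold ε in steps of 0.001: pairs at distance <= ε are "grouped", a
grouping is correct when both units carry the same model label, and the
precision-recall curve is integrated into the AUPR by step sums.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist, squareform
from sklearn.decomposition import PCA

from .catalog import GraphletCatalog
from .census import orbit_frequency_matrix
from .metrics import motif_fingerprint
from .netio import TemporalNetwork, aggregate
from .transitions import got_matrix, node_transition_vectors

logger = logging.getLogger("gotkit")

__all__ = [
    "FeatureMatrix",
    "PRCResult",
    "ClusterTree",
    "build_features",
    "pca_reduce",
    "distance_matrix",
    "precision_recall",
    "cluster_complete_linkage",
    "grouping_experiment",
]

METHODS = ("SM", "SG", "STG", "GoT")


@dataclass
class FeatureMatrix:
    """Unit x feature matrix with one true-category label per row."""
    X: pd.DataFrame
    labels: list[str]
    method: str


def _orbit_totals(net_snapshot, catalog) -> np.ndarray:
    fr = orbit_frequency_matrix(net_snapshot, catalog)
    return fr.to_numpy().sum(axis=0)


def build_features(networks: list[TemporalNetwork], method: str,
                   catalog: GraphletCatalog, n_random: int = 20,
                   seed: int = 0, node_level: bool = False) -> FeatureMatrix:
    """One feature row per network.

    SM: normalized motif-score vector on the aggregate network.
    SG: orbit-frequency totals on the aggregate network.
    STG: concatenated per-snapshot orbit-frequency totals.
    GoT: flattened |O|^2 orbit-transition count matrix (agreement metrics
    are not involved in this mode).

    ``node_level=True`` (SG / GoT only) summarizes a network by the mean of
    its per-node feature vectors (per-node GDV, or per-node transition
    vector) instead of by totals.
    """
    method = method.upper().replace("GOT", "GoT") if method.lower() == "got" else method
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    if node_level and method not in ("SG", "GoT"):
        raise ValueError("node-level features are offered for SG and GoT only")
    if method == "STG":
        lens = {n.n_snapshots for n in networks}
        if len(lens) > 1:
            raise ValueError(
                f"STG features need equal snapshot counts, got {sorted(lens)}")
    rows = []
    names = []
    labels = []
    for i, net in enumerate(networks):
        if method == "SM":
            fp = motif_fingerprint(aggregate(net), catalog,
                                   n_random=n_random, seed=seed + 7919 * i)
            row = fp.delta_norm.to_numpy()
        elif method == "SG":
            if node_level:
                fr = orbit_frequency_matrix(aggregate(net), catalog)
                row = fr.to_numpy().mean(axis=0)
            else:
                row = _orbit_totals(aggregate(net), catalog)
        elif method == "STG":
            row = np.concatenate(
                [_orbit_totals(s, catalog) for s in net.snapshots])
        else:  # GoT
            if node_level:
                row = node_transition_vectors(net, catalog).to_numpy().mean(axis=0)
            else:
                row = got_matrix(net, catalog).to_numpy().ravel()
        rows.append(row.astype(float))
        names.append(net.name or f"net{i}")
        labels.append(str(net.meta.get("model", net.name)))
    X = pd.DataFrame(np.vstack(rows), index=pd.Index(names, name="network"))
    return FeatureMatrix(X=X, labels=labels, method=method)


def pca_reduce(features: FeatureMatrix, variance: float = 0.99) -> FeatureMatrix:
    """Centered PCA keeping the smallest number of components whose
    cumulative explained variance reaches ``variance``; a constant matrix
    collapses to a single zero component."""
    X = features.X.to_numpy(dtype=float)
    if X.shape[0] < 2:
        raise ValueError("PCA needs at least 2 rows")
    centered = X - X.mean(axis=0)
    if not np.any(np.abs(centered) > 1e-12):
        Z = np.zeros((X.shape[0], 1))
    elif variance >= 1.0:
        pca = PCA(n_components=min(X.shape[0], X.shape[1]), svd_solver="full")
        Z = pca.fit_transform(X)
    else:
        pca = PCA(n_components=variance, svd_solver="full")
        Z = pca.fit_transform(X)
    Xr = pd.DataFrame(Z, index=features.X.index)
    return FeatureMatrix(X=Xr, labels=list(features.labels),
                         method=features.method)


def distance_matrix(features: FeatureMatrix) -> pd.DataFrame:
    """Pairwise Euclidean distances min-max rescaled to [0, 1] over the
    off-diagonal pairs (0 = most similar pair)."""
    X = features.X.to_numpy(dtype=float)
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least 2 units")
    d = pdist(X, metric="euclidean")
    lo, hi = d.min(), d.max()
    if hi == lo:
        logger.warning("all units are equidistant; distance matrix is all zero")
        scaled = np.zeros_like(d)
    else:
        scaled = (d - lo) / (hi - lo)
    out = pd.DataFrame(squareform(scaled), index=features.X.index,
                       columns=features.X.index)
    out.attrs["kind"] = "euclidean-distance"
    out.attrs["labels"] = list(features.labels)
    return out


@dataclass
class PRCResult:
    """Precision-recall sweep over the grouping threshold ε."""
    thresholds: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    aupr: float


def precision_recall(dist: pd.DataFrame, labels: list[str],
                     step: float = 0.001) -> PRCResult:
    """Threshold sweep: at each ε (0 to 1 in steps of ``step``) pairs with
    distance <= ε are grouped; precision is the fraction of grouped pairs
    sharing a label, recall the fraction of same-label pairs grouped, and
    AUPR the step sum of precision times recall increments.

    When no pair is grouped yet, precision is 1 (the curve starts at
    (0, 1)).
    """
    d = dist.to_numpy(dtype=float)
    n = d.shape[0]
    labels = list(labels)
    if len(labels) != n:
        raise ValueError("label count must match the distance matrix")
    if len(set(labels)) < 2:
        raise ValueError("precision-recall needs at least 2 classes")
    iu = np.triu_indices(n, k=1)
    pd_ = d[iu]
    same = np.array([labels[i] == labels[j] for i, j in zip(*iu)])
    total_correct = int(same.sum())
    if total_correct == 0:
        raise ValueError("no same-label pair exists")
    order = np.argsort(pd_, kind="stable")
    d_sorted = pd_[order]
    correct_cum = np.concatenate([[0], np.cumsum(same[order])])
    n_steps = int(round(1.0 / step))
    eps = np.arange(n_steps + 1) * step
    idx = np.searchsorted(d_sorted, eps, side="right")
    grouped = idx.astype(float)
    correct = correct_cum[idx].astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(grouped > 0, correct / np.where(grouped > 0, grouped, 1), 1.0)
    recall = correct / total_correct
    aupr = float(np.sum(precision[1:] * np.diff(recall)))
    return PRCResult(thresholds=eps, precision=precision, recall=recall,
                     aupr=aupr)


@dataclass
class ClusterTree:
    """Complete-linkage merge tree over a network set."""
    linkage: np.ndarray
    names: list[str]
    leaf_order: list[str]


def cluster_complete_linkage(sim: pd.DataFrame,
                             similarity: bool | None = None) -> ClusterTree:
    """Agglomerative complete-linkage clustering of a symmetric matrix.

    Agreement matrices (OTA/nOTA/GDA kinds, or ``similarity=True``) are
    converted to distances as 1 - value; distance matrices are used as-is.
    """
    v = sim.to_numpy(dtype=float)
    if not np.allclose(v, v.T, atol=1e-12):
        raise ValueError("similarity matrix must be symmetric")
    if similarity is None:
        similarity = sim.attrs.get("kind", "") in ("OTA", "nOTA", "GDA")
    d = 1.0 - v if similarity else v.copy()
    np.fill_diagonal(d, 0.0)
    z = linkage(squareform(d, checks=False), method="complete")
    names = [str(x) for x in sim.index]
    order = [names[i] for i in leaves_list(z)]
    return ClusterTree(linkage=z, names=names, leaf_order=order)


def grouping_experiment(networks: list[TemporalNetwork], method: str,
                        catalog: GraphletCatalog, variance: float = 0.99,
                        step: float = 0.001, n_random: int = 20,
                        seed: int = 0) -> PRCResult:
    """Full pipeline: features -> PCA -> normalized distances -> PR sweep."""
    fm = build_features(networks, method, catalog, n_random=n_random, seed=seed)
    red = pca_reduce(fm, variance=variance)
    dist = distance_matrix(red)
    return precision_recall(dist, red.labels, step=step)
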