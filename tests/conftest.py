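"""Shared fixtures: session-scoped catalogs and small example networks."""

import itertools

import networkx as nx
import pytest

from gotkit import Snapshot, TemporalNetwork, build_catalog


@pytest.fixture(scope="session")
def cat2():
    return build_catalog(2)


@pytest.fixture(scope="session")
def cat3():
    return build_catalog(3)


@pytest.fixture(scope="session")
def cat4():
    return build_catalog(4)


@pytest.fixture(scope="session")
def cat5():
    return build_catalog(5)


def snapshot(*edges, nodes=()):
    return Snapshot.from_edges(edges, nodes=nodes)


def temporal(*snapshot_edge_lists, name="toy"):
    return TemporalNetwork(
        snapshots=[Snapshot.from_edges(es) for es in snapshot_edge_lists],
        name=name)


def brute_force_connected_subsets(snap: Snapshot, k: int):
    """Oracle: scan all C(n, k) node subsets for connected induced subgraphs."""
    g = snap.to_networkx()
    out = set()
    for sub in itertools.combinations(sorted(snap.nodes), k):
        if nx.is_connected(g.subgraph(sub)):
            out.add(tuple(sub))
    return out


def random_snapshot(rng, n, p):
    """Erdős snapshot over string node ids, seeded."""
    edges = [(f"n{i:02d}", f"n{j:02d}")
             for i in range(n) for j in range(i + 1, n)
             if rng.random() < p]
    return Snapshot.from_edges(edges, nodes=(f"n{i:02d}" for i in range(n)))
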