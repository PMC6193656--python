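"""Graphlet catalogs: canonical codes and automorphism orbits.

A *graphlet* is a small connected induced subgraph considered up to
isomorphism; its *orbits* are the equivalence classes of its vertices under
the automorphism group — the distinct "roles" a node can play inside the
subgraph (e.g. the centre of a star versus its leaves).  A catalog
enumerates every non-isomorphic connected k-graphlet, partitions each one
into orbits, and assigns globally unique orbit ids that downstream census
and transition code refers to.

Canonicalization is done by exhaustive permutation search restricted to
colour classes produced by Weisfeiler–Lehman-style degree refinement: the
canonical code of a k-graph is the minimum adjacency bit string over all
refinement-compatible relabelings.  At k <= 6 (undirected) and k <= 4
(directed) this is exact and fast, and determinism matters more than raw
speed here.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "GraphletCatalog",
    "Graphlet",
    "canonical_code",
    "automorphism_orbits",
    "build_catalog",
    "orbit_lookup",
    "pair_order",
]

_MAX_K_UNDIRECTED = 6
_MAX_K_DIRECTED = 4


# ---------------------------------------------------------------------------
# bit layout shared by catalog, census and transitions
# ---------------------------------------------------------------------------

def pair_order(k: int, directed: bool) -> list[tuple[int, int]]:
    """Fixed ordering of vertex pairs defining the adjacency bit layout.

    Bit ``b`` of a graph mask corresponds to ``pair_order(k, directed)[b]``;
    undirected layouts list unordered pairs (i < j) lexicographically,
    directed layouts list all ordered pairs (i != j).
    """
    if directed:
        return [(i, j) for i in range(k) for j in range(k) if i != j]
    return [(i, j) for i in range(k) for j in range(i + 1, k)]


def n_bits(k: int, directed: bool) -> int:
    return k * (k - 1) if directed else k * (k - 1) // 2


def mask_to_rows(mask: int, k: int, directed: bool) -> tuple[int, ...]:
    """Expand a bit mask into adjacency bit-rows (rows[i] bit j == edge i->j)."""
    rows = [0] * k
    for b, (i, j) in enumerate(pair_order(k, directed)):
        if mask >> b & 1:
            rows[i] |= 1 << j
            if not directed:
                rows[j] |= 1 << i
    return tuple(rows)


def rows_to_mask(rows: Sequence[int], k: int, directed: bool) -> int:
    mask = 0
    for b, (i, j) in enumerate(pair_order(k, directed)):
        if rows[i] >> j & 1:
            mask |= 1 << b
    return mask


def _bits(x: int) -> Iterable[int]:
    while x:
        low = x & -x
        yield low.bit_length() - 1
        x ^= low


def _is_connected(rows: Sequence[int], k: int, directed: bool) -> bool:
    # weak connectivity for digraphs
    und = list(rows)
    if directed:
        for i in range(k):
            for j in _bits(rows[i]):
                und[j] |= 1 << i
    seen = 1
    frontier = [0]
    while frontier:
        v = frontier.pop()
        new = und[v] & ~seen
        seen |= und[v]
        frontier.extend(_bits(new))
    return seen == (1 << k) - 1


# ---------------------------------------------------------------------------
# canonical search
# ---------------------------------------------------------------------------

def _colour_classes(rows: Sequence[int], k: int, directed: bool) -> list[list[int]]:
    """Partition vertices by iterated neighbourhood-degree refinement.

    The resulting partition and its class order are isomorphism invariants,
    so restricting the canonical search to class-preserving relabelings is
    sound.  Automorphism classes are unions of orbit classes, never finer.
    """
    if directed:
        out = rows
        inn = [0] * k
        for i in range(k):
            for j in _bits(rows[i]):
                inn[j] |= 1 << i
        col: list = [
            (bin(out[v]).count("1"), bin(inn[v]).count("1"),
             bin(out[v] & inn[v]).count("1"))
            for v in range(k)
        ]
    else:
        col = [bin(rows[v]).count("1") for v in range(k)]
    n_classes = len(set(col))
    while True:
        if directed:
            sig = [
                (col[v],
                 tuple(sorted(col[u] for u in _bits(out[v] & ~inn[v]))),
                 tuple(sorted(col[u] for u in _bits(inn[v] & ~out[v]))),
                 tuple(sorted(col[u] for u in _bits(out[v] & inn[v]))))
                for v in range(k)
            ]
        else:
            sig = [
                (col[v], tuple(sorted(col[u] for u in _bits(rows[v]))))
                for v in range(k)
            ]
        ranking = {s: r for r, s in enumerate(sorted(set(sig)))}
        col = [ranking[s] for s in sig]
        if len(ranking) == n_classes:
            break
        n_classes = len(ranking)
    classes: dict[int, list[int]] = {}
    for v in range(k):
        classes.setdefault(col[v], []).append(v)
    return [classes[c] for c in sorted(classes)]


def _candidate_perms(classes: list[list[int]]) -> Iterable[tuple[int, ...]]:
    for parts in itertools.product(*(itertools.permutations(c) for c in classes)):
        yield tuple(itertools.chain.from_iterable(parts))


def _perm_code(rows: Sequence[int], perm: Sequence[int], pairs) -> int:
    code = 0
    for b, (i, j) in enumerate(pairs):
        if rows[perm[i]] >> perm[j] & 1:
            code |= 1 << b
    return code


def _canon_search(rows: Sequence[int], k: int, directed: bool):
    """Return (canonical code, minimizing permutation slot->vertex)."""
    pairs = pair_order(k, directed)
    classes = _colour_classes(rows, k, directed)
    best_code = None
    best_perm = None
    for perm in _candidate_perms(classes):
        code = _perm_code(rows, perm, pairs)
        if best_code is None or code < best_code:
            best_code, best_perm = code, perm
    return best_code, best_perm


def _class_preserving_perms(classes: list[list[int]], k: int) -> Iterable[tuple[int, ...]]:
    """Permutations mapping every colour class onto itself, in the original
    position order (automorphism candidates)."""
    for parts in itertools.product(*(itertools.permutations(c) for c in classes)):
        perm = [0] * k
        for cls, part in zip(classes, parts):
            for pos, v in zip(cls, part):
                perm[pos] = v
        yield tuple(perm)


def _automorphism_orbits_rows(rows: Sequence[int], k: int, directed: bool) -> list[list[int]]:
    """Orbit partition of vertex positions under the automorphism group."""
    pairs = pair_order(k, directed)
    classes = _colour_classes(rows, k, directed)
    ident = _perm_code(rows, tuple(range(k)), pairs)
    parent = list(range(k))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for perm in _class_preserving_perms(classes, k):
        if _perm_code(rows, perm, pairs) == ident:
            for i in range(k):
                ri, rp = find(i), find(perm[i])
                if ri != rp:
                    parent[rp] = ri
    blocks: dict[int, list[int]] = {}
    for v in range(k):
        blocks.setdefault(find(v), []).append(v)
    return sorted((sorted(b) for b in blocks.values()), key=lambda b: b[0])


# ---------------------------------------------------------------------------
# public adjacency-input helpers
# ---------------------------------------------------------------------------

def _to_rows(adjacency, directed: bool) -> tuple[tuple[int, ...], int]:
    """Coerce a k x k array-like or networkx graph to adjacency bit-rows."""
    try:
        import networkx as nx
        if isinstance(adjacency, (nx.Graph, nx.DiGraph)):
            adjacency = nx.to_numpy_array(
                adjacency, nodelist=sorted(adjacency.nodes()))
    except ImportError:  # pragma: no cover
        pass
    a = np.asarray(adjacency)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("adjacency must be a square matrix")
    k = a.shape[0]
    if np.any(np.diag(a) != 0):
        raise ValueError("self-loops are not allowed")
    if not directed and not np.array_equal(a, a.T):
        raise ValueError("undirected adjacency must be symmetric")
    rows = [0] * k
    for i in range(k):
        for j in range(k):
            if i != j and a[i, j]:
                rows[i] |= 1 << j
    return tuple(rows), k


def _check_k(k: int, directed: bool) -> None:
    hi = _MAX_K_DIRECTED if directed else _MAX_K_UNDIRECTED
    if not 2 <= k <= hi:
        kind = "directed" if directed else "undirected"
        raise ValueError(f"subgraph size k={k} outside supported {kind} range [2, {hi}]")


def canonical_code(adjacency, directed: bool = False) -> int:
    """Canonical code of a k-node graph: the minimum adjacency bit string
    over all refinement-compatible node relabelings.  Two graphs share a
    code iff they are isomorphic."""
    rows, k = _to_rows(adjacency, directed)
    _check_k(k, directed)
    code, _ = _canon_search(rows, k, directed)
    return code


def automorphism_orbits(adjacency, directed: bool = False) -> list[tuple[int, ...]]:
    """Partition the vertex positions of a connected k-graph into orbits:
    u and v share a block iff some automorphism maps u to v."""
    rows, k = _to_rows(adjacency, directed)
    _check_k(k, directed)
    if not _is_connected(rows, k, directed):
        raise ValueError("only connected graphlets have catalogued orbits")
    return [tuple(b) for b in _automorphism_orbits_rows(rows, k, directed)]


# ---------------------------------------------------------------------------
# catalog construction
# ---------------------------------------------------------------------------

@dataclass
class Graphlet:
    """One isomorphism class in canonical labeling."""
    code: int
    edges: list[tuple[int, int]]          # canonical-label edge list
    orbit_blocks: list[list[int]]         # orbit partition of positions
    orbit_ids: list[int]                  # global orbit id per block
    pos_orbit: tuple[int, ...]            # position -> global orbit id

    @property
    def n_edges(self) -> int:
        return len(self.edges)


# Fixed ordering of the six connected 4-node undirected graphlets, keyed by
# sorted degree sequence: star, path, cycle, paw (triangle + pendant),
# diamond, clique.  Star-centre is orbit 1, star-leaf 2, the cycle orbit 5
# and the clique orbit 11; high-degree orbits lead inside each graphlet, so
# a star-centre gaining one edge between leaves lands in orbit 6 (paw hub)
# and gaining two lands in orbit 9 (diamond hub).
_K4_RANK = {
    (3, 1, 1, 1): 0,  # star
    (2, 2, 1, 1): 1,  # path
    (2, 2, 2, 2): 2,  # cycle
    (3, 2, 2, 1): 3,  # paw
    (3, 3, 2, 2): 4,  # diamond
    (3, 3, 3, 3): 5,  # clique
}


@dataclass
class GraphletCatalog:
    """All non-isomorphic connected k-graphlets with global orbit ids."""
    k: int
    directed: bool
    graphlets: list[Graphlet]
    lookup: dict[int, int] = field(repr=False)          # code -> graphlet idx
    _mask_cache: dict[int, tuple[int, tuple[int, ...]]] = field(
        default_factory=dict, repr=False)               # mask -> (gidx, orbits)

    @property
    def orbit_count(self) -> int:
        return sum(len(g.orbit_blocks) for g in self.graphlets)

    @property
    def orbit_ids(self) -> list[int]:
        return list(range(1, self.orbit_count + 1))

    @property
    def n_transitions(self) -> int:
        """Size of the orbit-transition state space |O|^2."""
        return self.orbit_count ** 2

    # -- mask resolution ----------------------------------------------------

    def resolve_mask(self, mask: int) -> tuple[int, tuple[int, ...]]:
        """Map an adjacency mask of a connected induced k-subgraph to its
        (graphlet index, per-position global orbit ids)."""
        hit = self._mask_cache.get(mask)
        if hit is not None:
            return hit
        rows = mask_to_rows(mask, self.k, self.directed)
        if not _is_connected(rows, self.k, self.directed):
            raise ValueError("induced subgraph is disconnected")
        code, perm = _canon_search(rows, self.k, self.directed)
        gidx = self.lookup[code]
        pos_orbit = self.graphlets[gidx].pos_orbit
        inv = [0] * self.k
        for slot, v in enumerate(perm):
            inv[v] = slot
        orbits = tuple(pos_orbit[inv[v]] for v in range(self.k))
        self._mask_cache[mask] = (gidx, orbits)
        return gidx, orbits

    def orbits_for_mask(self, mask: int) -> tuple[int, ...]:
        return self.resolve_mask(mask)[1]

    def graphlet_for_mask(self, mask: int) -> int:
        return self.resolve_mask(mask)[0]

    # -- serialization ------------------------------------------------------

    def to_json(self) -> str:
        doc = {
            "k": self.k,
            "directed": self.directed,
            "orbit_count": self.orbit_count,
            "graphlets": [
                {
                    "code": g.code,
                    "edges": [list(e) for e in g.edges],
                    "orbit_blocks": g.orbit_blocks,
                    "orbit_ids": g.orbit_ids,
                }
                for g in self.graphlets
            ],
        }
        return json.dumps(doc, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "GraphletCatalog":
        doc = json.loads(text)
        k = doc["k"]
        graphlets = []
        for gd in doc["graphlets"]:
            pos_orbit = [0] * k
            for block, oid in zip(gd["orbit_blocks"], gd["orbit_ids"]):
                for p in block:
                    pos_orbit[p] = oid
            graphlets.append(Graphlet(
                code=gd["code"],
                edges=[tuple(e) for e in gd["edges"]],
                orbit_blocks=[list(b) for b in gd["orbit_blocks"]],
                orbit_ids=list(gd["orbit_ids"]),
                pos_orbit=tuple(pos_orbit),
            ))
        lookup = {g.code: i for i, g in enumerate(graphlets)}
        return cls(k=k, directed=doc["directed"], graphlets=graphlets,
                   lookup=lookup)


def _graphlet_sort_key(k: int, directed: bool):
    def key(item):
        code, rows = item
        n_edges = sum(bin(r).count("1") for r in rows)
        if not directed:
            n_edges //= 2
        if k == 4 and not directed:
            degs = tuple(sorted((bin(r).count("1") for r in rows), reverse=True))
            return (_K4_RANK[degs], code)
        return (n_edges, code)
    return key


def _order_blocks(blocks: list[list[int]], rows, k: int, directed: bool):
    if not directed:
        # high-degree orbits first (pins star-centre=1, paw hub=6, diamond
        # hub=9 at k=4, and chain-centre before periphery at k=3)
        return sorted(blocks, key=lambda b: (-bin(rows[b[0]]).count("1"), b[0]))
    return sorted(blocks, key=lambda b: b[0])


def build_catalog(k: int, directed: bool = False) -> GraphletCatalog:
    """Enumerate all labeled k-node (di)graphs, keep the connected ones,
    group them into isomorphism classes and assign deterministic global
    orbit ids.

    Orbit ids run 1..|O| over graphlets sorted by (edge count, canonical
    code); the undirected k=4 catalog is pinned to the conventional order
    star, path, cycle, paw, diamond, clique so that the star-centre is
    orbit 1, the cycle orbit is 5 and the clique orbit is 11.
    """
    _check_k(k, directed)
    nb = n_bits(k, directed)
    classes: dict[int, tuple[int, ...]] = {}
    mask_records: list[tuple[int, int, tuple[int, ...]]] = []
    for mask in range(1, 1 << nb):
        rows = mask_to_rows(mask, k, directed)
        if not _is_connected(rows, k, directed):
            continue
        code, perm = _canon_search(rows, k, directed)
        inv = [0] * k
        for slot, v in enumerate(perm):
            inv[v] = slot
        mask_records.append((mask, code, tuple(inv)))
        if code not in classes:
            # representative relabeled canonically
            rep = [0] * k
            for i in range(k):
                for j in _bits(rows[perm[i]]):
                    rep[i] |= 1 << inv[j]
            classes[code] = tuple(rep)

    ordered = sorted(classes.items(), key=_graphlet_sort_key(k, directed))
    graphlets: list[Graphlet] = []
    next_orbit = 1
    for code, rep_rows in ordered:
        blocks = _automorphism_orbits_rows(rep_rows, k, directed)
        blocks = _order_blocks(blocks, rep_rows, k, directed)
        orbit_ids = list(range(next_orbit, next_orbit + len(blocks)))
        next_orbit += len(blocks)
        pos_orbit = [0] * k
        for block, oid in zip(blocks, orbit_ids):
            for p in block:
                pos_orbit[p] = oid
        edges = [
            (i, j) for i, j in pair_order(k, directed) if rep_rows[i] >> j & 1
        ]
        graphlets.append(Graphlet(
            code=code, edges=edges, orbit_blocks=blocks,
            orbit_ids=orbit_ids, pos_orbit=tuple(pos_orbit)))

    lookup = {g.code: i for i, g in enumerate(graphlets)}
    catalog = GraphletCatalog(k=k, directed=directed, graphlets=graphlets,
                              lookup=lookup)
    # prefill the mask cache: the canonical searches were already paid for
    for mask, code, inv in mask_records:
        gidx = lookup[code]
        pos_orbit = graphlets[gidx].pos_orbit
        catalog._mask_cache[mask] = (
            gidx, tuple(pos_orbit[inv[v]] for v in range(k)))
    return catalog


def orbit_lookup(catalog: GraphletCatalog, adjacency) -> tuple[int, ...]:
    """Global orbit id of each node of a connected induced k-subgraph, in
    the node order of the given adjacency matrix."""
    rows, k = _to_rows(adjacency, catalog.directed)
    if k != catalog.k:
        raise ValueError(f"subgraph has {k} nodes, catalog expects {catalog.k}")
    mask = rows_to_mask(rows, k, catalog.directed)
    return catalog.orbits_for_mask(mask)
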