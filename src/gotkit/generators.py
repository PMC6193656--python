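"""Seeded generators for evolving random-graph models.

Six study conditions over three families — Erdős–Rényi, Barabási–Albert
and Watts–Strogatz — each producing a 5-snapshot temporal network that
starts with 250 nodes, grows by 10% per snapshot (floor rounding) and, for
the Erdős and Barabási families, holds the density E/N² at 0.01 exactly by
rounding.  Deletion noise removes each previous edge independently with
probability P(e−) ∈ {0, 0.5}; the Strogatz family instead starts from a
ring lattice of fixed even degree and rewires each edge with probability
β ∈ {0, 0.2} per snapshot (no deletion noise, density approximately
stable).  25 replicates of each model form the reference suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .netio import Snapshot, TemporalNetwork

__all__ = ["ModelSpec", "generate", "generate_suite", "table1_models"]

_MODELS = ("erdos", "barabasi", "strogatz")


@dataclass(frozen=True)
class ModelSpec:
    """Parameters of one evolving-model condition.

    density is the edge target E/N² (enforced per snapshot for erdos and
    barabasi); p_del is the per-edge survival noise P(e−); beta the
    per-edge per-snapshot rewiring probability of the Strogatz family.
    """
    model: str
    snapshots: int = 5
    n0: int = 250
    growth: float = 0.1
    density: float = 0.01
    p_del: float = 0.0
    beta: float = 0.0
    seed: int = 0
    name: str = ""

    def __post_init__(self):
        if self.model not in _MODELS:
            raise ValueError(f"unknown model {self.model!r}; expected one of {_MODELS}")
        if self.snapshots < 1:
            raise ValueError("need at least one snapshot")
        if self.growth < 0:
            raise ValueError("growth rate must be >= 0")
        if not 0 < self.density <= 0.5:
            raise ValueError("density must lie in (0, 0.5]")
        if not 0 <= self.p_del <= 1:
            raise ValueError("deletion probability must lie in [0, 1]")
        if not 0 <= self.beta <= 1:
            raise ValueError("rewiring probability must lie in [0, 1]")

    @property
    def label(self) -> str:
        if self.name:
            return self.name
        if self.model == "strogatz":
            return f"strogatz-beta{self.beta:g}"
        return f"{self.model}-pdel{self.p_del:g}"


def node_counts(spec: ModelSpec) -> list[int]:
    """Snapshot node counts: n_{i+1} = floor((1 + growth) * n_i)."""
    out = [spec.n0]
    for _ in range(spec.snapshots - 1):
        out.append(math.floor(out[-1] * (1 + spec.growth)))
    return out


def edge_counts(spec: ModelSpec) -> list[int]:
    """Per-snapshot edge targets round(density * n^2) (erdos/barabasi)."""
    return [int(round(spec.density * n * n)) for n in node_counts(spec)]


def _sample_uniform_edge(rng, n: int):
    u = int(rng.integers(0, n))
    v = int(rng.integers(0, n))
    return u, v


def _sample_pref_edge(rng, deg: np.ndarray):
    w = deg + 1.0
    p = w / w.sum()
    u = int(rng.choice(len(deg), p=p))
    v = int(rng.choice(len(deg), p=p))
    return u, v


def _fill_edges(rng, edges: set, n: int, target: int, deg: np.ndarray | None):
    """Add sampled edges (uniform, or degree+1 preferential when ``deg`` is
    given) until ``target`` edges exist; self-loops and duplicates are
    rejected and resampled."""
    if target > n * (n - 1) // 2:
        raise ValueError(f"edge target {target} exceeds C({n},2)")
    while len(edges) < target:
        if deg is None:
            u, v = _sample_uniform_edge(rng, n)
        else:
            u, v = _sample_pref_edge(rng, deg)
        if u == v:
            continue
        e = (u, v) if u < v else (v, u)
        if e in edges:
            continue
        edges.add(e)
        if deg is not None:
            deg[u] += 1
            deg[v] += 1


def _delete_edges(rng, edges: set, p_del: float, deg: np.ndarray | None):
    if p_del <= 0:
        return
    for e in list(edges):
        if rng.random() < p_del:
            edges.discard(e)
            if deg is not None:
                deg[e[0]] -= 1
                deg[e[1]] -= 1


def _ring_degree(spec: ModelSpec) -> int:
    # nearest even integer to 2 * density * n0, rounding half up, >= 2
    return max(2, 2 * int(spec.density * spec.n0 + 0.5))


def _ring_edges_for(ring: list[int], pos: int, r: int) -> list[tuple[int, int]]:
    n = len(ring)
    out = []
    v = ring[pos]
    for step in range(1, r // 2 + 1):
        for q in (pos - step, pos + step):
            u = ring[q % n]
            if u != v:
                out.append((v, u) if v < u else (u, v))
    return out


def generate(spec: ModelSpec) -> TemporalNetwork:
    """Generate one temporal network under the given model condition.

    The same spec (including seed) always produces the identical network.
    """
    rng = np.random.default_rng(spec.seed)
    ns = node_counts(spec)
    snapshots: list[Snapshot] = []

    if spec.model in ("erdos", "barabasi"):
        ms = edge_counts(spec)
        pref = spec.model == "barabasi"
        deg = np.zeros(ns[-1], dtype=float) if pref else None
        edges: set = set()
        for i, (n, m) in enumerate(zip(ns, ms)):
            if i > 0:
                _delete_edges(rng, edges, spec.p_del, deg)
            d = deg[:n] if pref else None
            _fill_edges(rng, edges, n, m, d)
            snapshots.append(_to_snapshot(edges, n))
    else:  # strogatz
        r = _ring_degree(spec)
        ring = list(range(ns[0]))
        edges = set()
        for pos in range(len(ring)):
            edges.update(_ring_edges_for(ring, pos, r))
        snapshots.append(_to_snapshot(edges, ns[0]))
        for n in ns[1:]:
            for new_v in range(len(ring), n):
                pos = int(rng.integers(0, len(ring) + 1))
                ring.insert(pos, new_v)
                edges.update(_ring_edges_for(ring, pos, r))
            if spec.beta > 0:
                _rewire(rng, edges, n, spec.beta)
            snapshots.append(_to_snapshot(edges, n))

    label = spec.label
    return TemporalNetwork(
        snapshots=snapshots,
        name=label,
        meta={"model": label, "spec": spec},
    )


def _rewire(rng, edges: set, n: int, beta: float, max_tries: int = 50):
    for e in list(edges):
        if rng.random() >= beta:
            continue
        keep = e[int(rng.integers(0, 2))]
        for _ in range(max_tries):
            other = int(rng.integers(0, n))
            if other == keep:
                continue
            new = (keep, other) if keep < other else (other, keep)
            if new in edges:
                continue
            edges.discard(e)
            edges.add(new)
            break


def _node_id(i: int) -> str:
    return f"v{i:05d}"


def _to_snapshot(edges: set, n: int) -> Snapshot:
    return Snapshot.from_edges(
        ((_node_id(u), _node_id(v)) for u, v in edges),
        nodes=(_node_id(i) for i in range(n)),
    )


def table1_models(snapshots: int = 5, n0: int = 250) -> list[ModelSpec]:
    """The six reference model conditions: Erdős and Barabási with
    P(e−) ∈ {0, 0.5}, Strogatz with β ∈ {0, 0.2}."""
    out = []
    for model in ("erdos", "barabasi"):
        for p_del in (0.0, 0.5):
            out.append(ModelSpec(model=model, snapshots=snapshots, n0=n0,
                                 p_del=p_del))
    for beta in (0.0, 0.2):
        out.append(ModelSpec(model="strogatz", snapshots=snapshots, n0=n0,
                             beta=beta))
    return out


def _derive_seed(master: int, model_idx: int, rep: int) -> int:
    return (master * 1_000_003 + model_idx * 8191 + rep * 131 + 17) % (2**31 - 1)


def generate_suite(models: list[ModelSpec], replicates: int,
                   seed: int = 0) -> list[TemporalNetwork]:
    """Generate ``replicates`` networks per model with derived per-network
    seeds; network names encode model label and replicate index."""
    if replicates < 1:
        raise ValueError("need at least one replicate")
    nets = []
    for mi, spec in enumerate(models):
        for rep in range(replicates):
            child = replace(spec, seed=_derive_seed(seed, mi, rep))
            net = generate(child)
            net.name = f"{spec.label}_r{rep:02d}"
            nets.append(net)
    return nets
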