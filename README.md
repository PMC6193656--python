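# gotkit

Graphlet-orbit transition fingerprints for temporal network comparison.

Given a set of temporal networks — sequences of snapshots `S_1 … S_s` over
a shared node universe, from biology, collaboration, communication or any
other domain — how can we say which networks evolve alike? Static
subgraph metrics (network motifs, graphlet degree distributions) compare
a single frozen picture of each network and miss the dynamics. `gotkit`
compares networks by how the *roles* of their nodes change through time.

## The method

A **graphlet** is a small connected induced subgraph considered up to
isomorphism; its **orbits** are the equivalence classes of its vertices
under the automorphism group — a 4-star has a centre orbit and a leaf
orbit, a 4-clique only one. For `k = 4` there are 6 undirected graphlets
with 11 orbits in total.

For every pair of consecutive snapshots `(S_t, S_{t+1})` and every k-node
set whose induced subgraph is connected in *both* snapshots, each of the
k nodes contributes one **orbit transition**: from its orbit `x` at `t`
to its orbit `y` at `t+1`. Counting all of them yields the `|O| × |O|`
transition matrix

    T[x, y](N) = #{ (node, t) : orbit x at t, orbit y at t+1 }.

Rows are normalized, `ntr[i, j] = tr[i, j] / Σ_k tr[i, k]`, so common and
rare orbits weigh equally, and two networks are compared by the
**orbit-transition agreement**

    OTA(N1, N2) = (1 / |O|²) · Σ_ij ( 1 − | ntr_ij(N1) − ntr_ij(N2) | ),

a symmetric score in [0, 1]; `nOTA` rescales an OTA matrix over a network
set so the most similar pair scores 1 and the most different 0.

Alongside the transition fingerprint the package implements the standard
static baselines behind the same interfaces: motif fingerprints `δ/Δ`
against a degree-preserving null ensemble, graphlet degree vectors
(GDV/Fr), graphlet degree distributions with GDD-agreement (GDA), node
degree distributions, seeded evolving-graph generators
(Erdős–Rényi / Barabási–Albert / Watts–Strogatz with growth, density
control, deletion noise and rewiring) and a model-grouping benchmark
(PCA → normalized Euclidean distances → precision-recall / AUPR by
threshold sweep → complete-linkage clustering).

## Worked example

```python
from gotkit import (build_catalog, generate, ModelSpec, got_matrix,
                    row_normalize, pairwise_ota, nota)

cat = build_catalog(4)
# -> 6 graphlets, 11 orbits, 121 possible transitions

nets = {
    "erdos-stable":    generate(ModelSpec(model="erdos",    p_del=0.0, n0=150, seed=7)),
    "erdos-noisy":     generate(ModelSpec(model="erdos",    p_del=0.5, n0=150, seed=7)),
    "barabasi-stable": generate(ModelSpec(model="barabasi", p_del=0.0, n0=150, seed=7)),
}
mats = {name: row_normalize(got_matrix(n, cat)) for name, n in nets.items()}
print(nota(pairwise_ota(mats)).round(3))
```

prints

```
                 erdos-stable  erdos-noisy  barabasi-stable
erdos-stable            1.000        0.074              1.0
erdos-noisy             0.074        1.000              0.0
barabasi-stable         1.000        0.000              1.0
```

The two stable models share almost all of their transition structure
(their groups persist, so the matrix diagonal dominates: raw OTA 0.988),
while the noisy model — half of its edges vanish at every step — is the
odd one out (OTA ≈ 0.90 against both). The raw transition totals tell the
same story: ≈ 94k counted transitions for the stable Erdős network,
≈ 309k for the denser-tailed Barabási one, but only ≈ 11k when deletion
noise keeps breaking groups apart.

The same pipeline is available from the shell:

```sh
gotkit simulate --model erdos --p-del 0.5 --n0 150 --reps 5 --seed 7 -o sims/
gotkit transitions -i sims/erdos-pdel0.5_r00.tsv --k 4 --normalized -o T.tsv
gotkit compare -i sims/ --method ota --k 4 -o sim.tsv
gotkit cluster -i sim.tsv -o tree.tsv
```

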