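"""Shared tree oracles for the structure and acceptance tests."""

import numpy as np


def random_additive_metric(n_taxa, rng):
    """Random tree-additive distance matrix built by iteratively joining
    subtrees with random positive edge lengths (independent of NJ)."""
    taxa = [f"t{i}" for i in range(n_taxa)]
    D = np.zeros((n_taxa, n_taxa))
    leafsets = {i: [i] for i in range(n_taxa)}
    leafdist = {i: {i: 0.0} for i in range(n_taxa)}
    active = list(range(n_taxa))
    nxt = n_taxa
    while len(active) > 1:
        i, j = rng.choice(active, 2, replace=False)
        li, lj = rng.uniform(0.1, 2.0, size=2)
        for a in leafsets[i]:
            for b in leafsets[j]:
                D[a, b] = D[b, a] = leafdist[i][a] + li + leafdist[j][b] + lj
        leafsets[nxt] = leafsets[i] + leafsets[j]
        leafdist[nxt] = {**{a: leafdist[i][a] + li for a in leafsets[i]},
                         **{b: leafdist[j][b] + lj for b in leafsets[j]}}
        active = [k for k in active if k not in (i, j)] + [nxt]
        nxt += 1
    return taxa, D


def patristic(tree, taxa):
    """Leaf-to-leaf path lengths of a pigdiv Tree, via dendropy."""
    dt = tree.as_dendropy()
    pdm = dt.phylogenetic_distance_matrix()
    tx = {t.label: t for t in dt.taxon_namespace}
    n = len(taxa)
    out = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            out[a, b] = out[b, a] = pdm.distance(tx[taxa[a]], tx[taxa[b]])
    return out
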