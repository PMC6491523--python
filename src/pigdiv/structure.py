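"""Population structure: additive relationship matrix, PCA with
reference-panel projection, and neighbour-joining trees with locus bootstrap.

The relationship matrix is VanRaden's: dosages centred by twice the allele
frequency (missing calls imputed to the locus mean), ``A = Z Z' / (2 sum
p(1-p))``.  Its eigendecomposition gives the PCA used to separate subspecies
clusters; new samples can be projected onto a reference basis (e.g. a
labelled reference panel) using the reference's own frequencies and loadings.

NJ is the classical Saitou–Nei agglomeration with deterministic tie-breaking
(smallest index pair), so it recovers any tree-additive metric exactly.
Bootstrap supports come from resampling loci with replacement, rebuilding the
tree from the recomputed IBS distances and counting bipartition recovery.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np

from .panel import MISSING, GenotypeMatrix
from .relatedness import ibs_distance_from_dosage


# ------------------------------------------------------- relationship matrix
@dataclass
class RelationshipMatrix:
    accession_ids: list[str]
    A: np.ndarray
    normalisation: float            # 2 * sum p(1-p)
    centred: np.ndarray             # Z, kept for PCA projection
    frequencies: np.ndarray
    marker_ids: list[str]


def relationship_matrix(gm: GenotypeMatrix) -> RelationshipMatrix:
    """VanRaden additive relationship matrix of a post-QC panel."""
    p = gm.alt_allele_frequency()
    usable = np.isfinite(p) & (p > 0) & (p < 1)
    if not usable.any():
        raise ValueError("panel is monomorphic; relationship matrix undefined")
    d = gm.dosage[:, usable].astype(float)
    p = p[usable]
    d = np.where(d == MISSING, 2.0 * p[None, :], d)   # mean imputation
    Z = d - 2.0 * p[None, :]
    c = float(2.0 * np.sum(p * (1.0 - p)))
    return RelationshipMatrix(
        list(gm.accession_ids), Z @ Z.T / c, c, Z, p,
        [m for m, u in zip(gm.marker_ids, usable) if u],
    )


# ----------------------------------------------------------------------- PCA
@dataclass
class PcaResult:
    accession_ids: list[str]
    eigenvalues: np.ndarray
    pct_variance: np.ndarray
    scores: np.ndarray
    # projection basis
    loadings: np.ndarray            # markers x PCs
    frequencies: np.ndarray
    marker_ids: list[str]
    normalisation: float


def pca(rm: RelationshipMatrix, n_pcs: int = 10) -> PcaResult:
    """Eigendecomposition of the relationship matrix.

    Scores are ``eigenvector * sqrt(eigenvalue)``; percent variance uses
    eigenvalue shares with negative eigenvalues floored at zero (they can
    arise from missing-data imputation and are logged).
    """
    A = (rm.A + rm.A.T) / 2.0
    vals, vecs = np.linalg.eigh(A)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    if (vals < -1e-10).any():
        warnings.warn("negative eigenvalues floored at 0 for variance percentages")
    rank = int((vals > 1e-10).sum())
    if n_pcs > rank:
        warnings.warn(f"n_pcs={n_pcs} exceeds rank {rank}; truncated")
        n_pcs = rank
    pos = np.maximum(vals, 0.0)
    pct = 100.0 * pos / pos.sum()
    lam = vals[:n_pcs]
    scores = vecs[:, :n_pcs] * np.sqrt(np.maximum(lam, 0.0))[None, :]
    # marker-space loadings W = Z' U lambda^{-1/2} / c, so new z -> z @ W
    with np.errstate(divide="ignore"):
        inv_sqrt = np.where(lam > 1e-10, 1.0 / np.sqrt(np.maximum(lam, 1e-300)), 0.0)
    loadings = rm.centred.T @ vecs[:, :n_pcs] * inv_sqrt[None, :] / rm.normalisation
    return PcaResult(list(rm.accession_ids), vals, pct, scores, loadings,
                     rm.frequencies, list(rm.marker_ids), rm.normalisation)


def project(reference: PcaResult, new_gm: GenotypeMatrix) -> np.ndarray:
    """Project new samples onto a reference PCA basis.

    Samples are centred with the *reference* panel's allele frequencies on
    the marker intersection (same allele orientation assumed) and multiplied
    by the reference loadings.  Projecting the reference panel onto itself
    reproduces its scores.
    """
    ref_idx = {m: i for i, m in enumerate(reference.marker_ids)}
    common = [m for m in new_gm.marker_ids if m in ref_idx]
    if not common:
        raise ValueError("no markers shared with the reference basis")
    if len(common) < 50:
        warnings.warn(f"only {len(common)} markers shared with the reference basis")
    cols_new = [new_gm.marker_ids.index(m) for m in common]
    cols_ref = [ref_idx[m] for m in common]
    p = reference.frequencies[cols_ref]
    d = new_gm.dosage[:, cols_new].astype(float)
    d = np.where(d == MISSING, 2.0 * p[None, :], d)
    Z = d - 2.0 * p[None, :]
    return Z @ reference.loadings[cols_ref, :]


# ------------------------------------------------------------ neighbour joining
@dataclass
class _Node:
    name: str | None = None
    children: list[tuple["_Node", float]] = field(default_factory=list)

    def leaves(self) -> set[str]:
        if not self.children:
            return {self.name}  # type: ignore[arg-type]
        out: set[str] = set()
        for child, _ in self.children:
            out |= child.leaves()
        return out

    def newick(self, support: dict[frozenset, float] | None = None) -> str:
        if not self.children:
            return self.name  # type: ignore[return-value]
        parts = []
        for child, length in self.children:
            label = ""
            if support is not None and child.children:
                key = frozenset(child.leaves())
                if key in support:
                    label = f"{support[key]:.0f}"
            parts.append(f"{child.newick(support)}{label}:{length:.10g}")
        return "(" + ",".join(parts) + ")"


@dataclass
class Tree:
    """Unrooted NJ tree with optional bootstrap supports per internal edge."""

    newick: str
    taxa: list[str]
    supports: dict[frozenset, float] | None = None

    def as_dendropy(self) -> dendropy.Tree:
        return dendropy.Tree.get(data=self.newick, schema="newick")

    def bipartitions(self) -> set[frozenset]:
        return _bipartitions_from_root(self._root)

    _root: _Node = None  # type: ignore[assignment]


def _nj_root(dist: np.ndarray, taxa: list[str]) -> _Node:
    n = len(taxa)
    nodes: list[_Node] = [_Node(name=t) for t in taxa]
    D = dist.astype(float).copy()
    active = list(range(n))
    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        # deterministic tie-break: smallest (i, j) index pair in active order
        flat = np.argmin(Q)
        qmin = Q.flat[flat]
        ties = np.argwhere(np.isclose(Q, qmin, rtol=0, atol=1e-12))
        i, j = min((int(a), int(b)) for a, b in ties if a < b)
        ai, aj = active[i], active[j]
        li = sub[i, j] / 2.0 + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = sub[i, j] - li
        new = _Node(children=[(nodes[ai], li), (nodes[aj], lj)])
        # distances from the new node to the rest
        dnew = (D[ai, :] + D[aj, :] - D[ai, aj]) / 2.0
        D = np.vstack([D, dnew[None, :]])
        D = np.hstack([D, np.append(dnew, 0.0)[:, None]])
        nodes.append(new)
        active = [a for a in active if a not in (ai, aj)] + [len(nodes) - 1]
    a, b, c = active
    la = (D[a, b] + D[a, c] - D[b, c]) / 2.0
    lb = (D[a, b] + D[b, c] - D[a, c]) / 2.0
    lc = (D[a, c] + D[b, c] - D[a, b]) / 2.0
    return _Node(children=[(nodes[a], la), (nodes[b], lb), (nodes[c], lc)])


def _bipartitions_from_root(root: _Node) -> set[frozenset]:
    """Non-trivial bipartitions, each encoded as the leaf set of the subtree."""
    all_leaves = root.leaves()
    out: set[frozenset] = set()

    def walk(node: _Node) -> None:
        for child, _ in node.children:
            if child.children:
                side = frozenset(child.leaves())
                if 1 < len(side) < len(all_leaves) - 1:
                    out.add(side)
            walk(child)

    walk(root)
    return out


def _canonical(biparts: set[frozenset], all_taxa: frozenset, anchor: str) -> set[frozenset]:
    # orient every split to the side NOT containing the anchor taxon
    return {b if anchor not in b else all_taxa - b for b in biparts}


def nj_tree(
    dist: np.ndarray,
    taxa: list[str],
    boot: tuple[GenotypeMatrix, int, int] | None = None,
) -> Tree:
    """Neighbour-joining tree from a complete distance matrix.

    ``boot = (gm, n_reps, seed)`` triggers bootstrap supports: loci of ``gm``
    are resampled with replacement, IBS distances recomputed, the tree
    rebuilt, and each internal edge of the main tree scored with the
    percentage of replicates containing the same bipartition.
    """
    dist = np.asarray(dist, dtype=float)
    if len(taxa) < 3:
        raise ValueError("need at least 3 taxa")
    if dist.shape != (len(taxa), len(taxa)):
        raise ValueError("distance matrix shape does not match taxa")
    if (dist < -1e-12).any():
        raise ValueError("distances must be non-negative")
    if not np.isfinite(dist).all():
        raise ValueError("distance matrix must be complete")
    root = _nj_root(dist, taxa)
    all_taxa = frozenset(taxa)
    main = _canonical(_bipartitions_from_root(root), all_taxa, taxa[0])

    supports: dict[frozenset, float] | None = None
    if boot is not None:
        gm, n_reps, seed = boot
        rng = np.random.default_rng(seed)
        hits: dict[frozenset, int] = {b: 0 for b in main}
        for _ in range(n_reps):
            cols = rng.integers(0, gm.n_markers, size=gm.n_markers)
            bd, _ = ibs_distance_from_dosage(gm.dosage[:, cols])
            rep = _canonical(_bipartitions_from_root(_nj_root(np.nan_to_num(bd), taxa)),
                             all_taxa, taxa[0])
            for b in main & rep:
                hits[b] += 1
        supports = {b: 100.0 * h / n_reps for b, h in hits.items()}
        # re-key supports on raw subtree leaf-sets so newick labelling finds them
        raw = _bipartitions_from_root(root)
        supports = {b: supports[b if taxa[0] not in b else all_taxa - b] for b in raw
                    if (b if taxa[0] not in b else all_taxa - b) in supports}

    tree = Tree(newick=root.newick(supports) + ";", taxa=list(taxa), supports=supports)
    tree._root = root
    return tree
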