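"""Pairwise relatedness: IBS distance, estimated probability of identity,
duplicate detection and core-collection selection.

Genebank collections accumulate duplicate seed lots; collapsing them into a
core collection is the first analytical step.  "Estimated PI" is implemented
as the PLINK-style method-of-moments PI-HAT: IBD coefficients (k0, k1, k2)
are solved from observed identity-by-state sharing counts and panel allele
frequencies, and ``PI = k2 + k1 / 2``.  The familiar relatedness tiers
(duplicate = 1, full sib >= 0.5, half sib 0.25-0.5) are exactly PI-HAT
semantics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .panel import MISSING, GenotypeMatrix


@dataclass
class RelatednessResult:
    """Symmetric pairwise matrices over a panel's accessions."""

    accession_ids: list[str]
    ibs_distance: np.ndarray      # in [0, 1]; nan where no co-called markers
    pi_hat: np.ndarray            # clamped to [0, 1]; diagonal = 1
    n_shared_calls: np.ndarray    # co-called marker counts


@dataclass
class CoreSelection:
    """Duplicate clusters and their representatives."""

    duplicate_clusters: list[set[str]]
    representatives: list[str]
    core_ids: list[str]


def _ibs_counts(d: np.ndarray) -> dict[str, np.ndarray]:
    """Pairwise IBS-class counts via indicator matmuls.

    Returns counts of co-called loci where the pair shares 2, 1 or 0 alleles.
    """
    ind = {g: (d == g).astype(np.float64) for g in (0, 1, 2)}
    c = {(a, b): ind[a] @ ind[b].T for a in (0, 1, 2) for b in (0, 1, 2) if a <= b}

    def sym(a, b):
        return c[(a, b)] if a <= b else c[(b, a)].T

    ibs0 = sym(0, 2) + sym(2, 0)
    ibs1 = sym(0, 1) + sym(1, 0) + sym(1, 2) + sym(2, 1)
    ibs2 = sym(0, 0) + sym(1, 1) + sym(2, 2)
    return {"ibs0": ibs0, "ibs1": ibs1, "ibs2": ibs2, "n": ibs0 + ibs1 + ibs2}


def ibs_distance(gm: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Mean identity-by-state distance per accession pair.

    Per pair, ``mean over co-called markers of |d_i - d_j| / 2`` — one minus
    the average fraction of shared alleles.  Pairs with zero co-called
    markers get ``nan`` (undefined, not zero).  Returns ``(distance,
    n_shared_calls)``.
    """
    if gm.n_accessions < 2:
        raise ValueError("need at least 2 accessions")
    return ibs_distance_from_dosage(gm.dosage)


def ibs_distance_from_dosage(dosage: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """IBS distance straight from a dosage array (rows = accessions)."""
    cnt = _ibs_counts(dosage)
    with np.errstate(invalid="ignore", divide="ignore"):
        dist = (cnt["ibs1"] * 0.5 + cnt["ibs0"]) / cnt["n"]
    dist = np.where(cnt["n"] > 0, dist, np.nan)
    np.fill_diagonal(dist, 0.0)
    return dist, cnt["n"].astype(np.int64)


def estimate_pi(gm: GenotypeMatrix) -> RelatednessResult:
    """Method-of-moments PI-HAT for every accession pair.

    Expected IBS-class probabilities conditional on IBD state are computed
    per locus from panel-wide alternate-allele frequencies and accumulated
    over each pair's co-called loci; (k0, k1, k2) are then solved in sequence
    from the observed IBS counts, constrained to [0, 1], and
    ``PI = k2 + k1 / 2``.  Raises on a panel with no polymorphic locus.
    """
    p = gm.alt_allele_frequency()
    usable = np.isfinite(p) & (p > 0) & (p < 1)
    if not usable.any():
        raise ValueError("panel has no polymorphic markers; frequencies uninformative")
    sub = gm.take_markers(np.asarray(gm.marker_ids)[usable])
    p = sub.alt_allele_frequency()
    q = 1.0 - p

    # P(IBS class | IBD state) per locus under HWE (Purcell et al. 2007 MoM)
    e_ibs0_ibd0 = 2 * p**2 * q**2
    e_ibs1_ibd0 = 4 * p**3 * q + 4 * p * q**3
    e_ibs2_ibd0 = 1.0 - e_ibs0_ibd0 - e_ibs1_ibd0
    e_ibs1_ibd1 = 2 * p**2 * q + 2 * p * q**2
    e_ibs2_ibd1 = 1.0 - e_ibs1_ibd1

    M = (sub.dosage != MISSING).astype(np.float64)
    # accumulate per-locus probabilities over each pair's co-called loci
    exp = {name: (M * vec) @ M.T
           for name, vec in [("e00", e_ibs0_ibd0), ("e10", e_ibs1_ibd0),
                             ("e20", e_ibs2_ibd0), ("e11", e_ibs1_ibd1),
                             ("e21", e_ibs2_ibd1)]}
    cnt = _ibs_counts(sub.dosage)
    n = cnt["n"]
    with np.errstate(invalid="ignore", divide="ignore"):
        k0 = cnt["ibs0"] / exp["e00"]
        k1 = (cnt["ibs1"] - k0 * exp["e10"]) / exp["e11"]
        k2 = (cnt["ibs2"] - k0 * exp["e20"] - k1 * exp["e21"]) / n
    k0, k1, k2 = (np.nan_to_num(k) for k in (k0, k1, k2))
    # PLINK-style bounding: a coefficient estimated above 1 pins the pair to
    # that pure IBD state; negatives are floored and the triple renormalised
    over0, over1, over2 = k0 > 1, k1 > 1, k2 > 1
    k0 = np.where(over0, 1.0, np.where(over1 | over2, 0.0, k0))
    k1 = np.where(over1, 1.0, np.where(over0 | over2, 0.0, k1))
    k2 = np.where(over2, 1.0, np.where(over0 | over1, 0.0, k2))
    k0, k1, k2 = (np.maximum(k, 0.0) for k in (k0, k1, k2))
    total = k0 + k1 + k2
    with np.errstate(invalid="ignore", divide="ignore"):
        k1 = np.where(total > 0, k1 / total, 0.0)
        k2 = np.where(total > 0, k2 / total, 0.0)
    pi = np.clip(k2 + 0.5 * k1, 0.0, 1.0)
    np.fill_diagonal(pi, 1.0)
    pi = (pi + pi.T) / 2.0

    dist, n_shared = ibs_distance(sub)
    return RelatednessResult(list(gm.accession_ids), dist, pi, n_shared)


def find_duplicates(
    rel: RelatednessResult,
    gm: GenotypeMatrix | None = None,
    pi_threshold: float = 0.99,
) -> CoreSelection:
    """Cluster duplicates by single-linkage closure over ``PI >= threshold``.

    The representative of each cluster is the member with the highest
    genotype call rate (when a panel is supplied), ties broken by
    lexicographically smallest accession id.  Deterministic and invariant to
    accession order.
    """
    if not (0.0 < pi_threshold <= 1.0):
        raise ValueError("pi_threshold must lie in (0, 1]")
    ids = rel.accession_ids
    n = len(ids)
    adj = (rel.pi_hat >= pi_threshold)
    np.fill_diagonal(adj, False)
    n_comp, labels = connected_components(csr_matrix(adj), directed=False)
    clusters: list[set[str]] = [set() for _ in range(n_comp)]
    for i in range(n):
        clusters[labels[i]].add(ids[i])
    clusters.sort(key=lambda c: min(c))

    call_rate = dict(zip(gm.accession_ids, gm.sample_call_rate())) if gm is not None else {}
    reps = [min(c, key=lambda a: (-call_rate.get(a, 0.0), a)) for c in clusters]
    return CoreSelection(clusters, reps, sorted(reps))
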