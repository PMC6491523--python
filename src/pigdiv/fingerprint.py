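"""Minimal fingerprinting SNP sets via a genetic algorithm.

The goal is a small subset of markers whose homozygous genotype profiles
uniquely identify every accession in a core collection.  Two accessions are
*distinguished* by a marker only when both carry homozygous calls there and
the calls differ — heterozygous and missing calls act as wildcards, so a
highly heterozygous accession can be indistinguishable by profile and is then
checked against the 0.05 identity-by-state distance rule instead.

Three strategies share one fitness function (the number of accessions
distinguished from *all* others):

* :func:`ga_select` — fixed-length index-vector GA with partially matched
  crossover (PMX, adapted to distinct-index vectors with a repair step),
  elitist truncation survival and optional mutation;
* :func:`brute_force_select` — exhaustive search, the optimality oracle;
* :func:`greedy_select` — forward selection, a fast feasibility bound.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from math import comb

import numpy as np

from .panel import GenotypeMatrix
from .relatedness import ibs_distance


@dataclass
class GaConfig:
    """GA parameters; defaults follow common practice for panel sizes of ~1.5k
    markers: very large population, PMX at 0.35, 30% truncation survival and
    no mutation."""

    k: int = 20
    population_size: int = 50_000
    crossover_rate: float = 0.35
    survival_rate: float = 0.30
    mutation_rate: float = 0.0
    max_generations: int = 200
    plateau_generations: int = 20
    min_ibs_distance: float = 0.05
    rng_seed: int = 0

    def validate(self, n_markers: int) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.k > n_markers:
            raise ValueError(f"k={self.k} exceeds {n_markers} markers")
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        for name in ("crossover_rate", "survival_rate", "mutation_rate"):
            if not (0.0 <= getattr(self, name) <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if max(2, int(self.survival_rate * self.population_size)) > self.population_size:
            raise ValueError("survivors exceed population size")


@dataclass
class FingerprintPanel:
    marker_ids: list[str]
    fitness: int
    generations_run: int
    fitness_trace: list[int] = field(default_factory=list)
    unresolved_pairs: list[tuple[str, str, float, bool]] = field(default_factory=list)


# --------------------------------------------------------------- pair coverage
class _PairCoverage:
    """Packed per-marker bitmaps over accession pairs.

    Bit (i, j) of marker m is set when m distinguishes the pair — both calls
    homozygous and different.  Subset fitness is then an OR over the subset's
    rows followed by a scan of uncovered pairs.
    """

    def __init__(self, gm: GenotypeMatrix):
        d = gm.dosage
        self.n = gm.n_accessions
        self.pi, self.pj = np.triu_indices(self.n, 1)
        h0 = d == 0
        h2 = d == 2
        # pairs x markers boolean, packed along pairs
        diff = (h0[self.pi] & h2[self.pj]) | (h2[self.pi] & h0[self.pj])
        self.packed = np.packbits(diff.T, axis=1)          # markers x packed-pairs
        self.n_pairs = self.pi.size

    def fitness_of(self, subset: np.ndarray) -> int:
        cov = np.bitwise_or.reduce(self.packed[subset], axis=0)
        covered = np.unpackbits(cov, count=self.n_pairs).astype(bool)
        uncovered = ~covered
        bad = np.zeros(self.n, dtype=bool)
        bad[self.pi[uncovered]] = True
        bad[self.pj[uncovered]] = True
        return int(self.n - bad.sum())

    def uncovered_pairs(self, subset: np.ndarray) -> list[tuple[int, int]]:
        cov = np.bitwise_or.reduce(self.packed[subset], axis=0)
        covered = np.unpackbits(cov, count=self.n_pairs).astype(bool)
        idx = np.nonzero(~covered)[0]
        return [(int(self.pi[t]), int(self.pj[t])) for t in idx]


def fitness(gm: GenotypeMatrix, marker_subset: list[str]) -> int:
    """Number of accessions uniquely identified by the subset's homozygous
    profiles (distinguished from every other accession)."""
    if not marker_subset:
        raise ValueError("marker subset must be non-empty")
    idx = [gm.marker_ids.index(m) for m in marker_subset]
    d = gm.dosage[:, idx]
    h0 = (d == 0).astype(np.float64)
    h2 = (d == 2).astype(np.float64)
    distinguished = (h0 @ h2.T + h2 @ h0.T) > 0
    np.fill_diagonal(distinguished, True)
    return int(distinguished.all(axis=1).sum())


def pairwise_polymorphic_counts(gm: GenotypeMatrix, marker_subset: list[str]) -> np.ndarray:
    """Symmetric matrix counting subset markers that distinguish each pair
    (both homozygous, different alleles)."""
    idx = [gm.marker_ids.index(m) for m in marker_subset]
    d = gm.dosage[:, idx]
    h0 = (d == 0).astype(np.float64)
    h2 = (d == 2).astype(np.float64)
    counts = h0 @ h2.T + h2 @ h0.T
    np.fill_diagonal(counts, 0)
    return counts.astype(np.int64)


def _unresolved(
    gm: GenotypeMatrix, cov: _PairCoverage, subset: np.ndarray, min_ibs: float
) -> list[tuple[str, str, float, bool]]:
    pairs = cov.uncovered_pairs(subset)
    if not pairs:
        return []
    dist, _ = ibs_distance(gm)
    ids = gm.accession_ids
    return [(ids[i], ids[j], float(dist[i, j]), bool(dist[i, j] >= min_ibs))
            for i, j in pairs]


# -------------------------------------------------------------------------- GA
def _pmx(p1: np.ndarray, p2: np.ndarray, n_markers: int, rng: np.random.Generator) -> np.ndarray:
    """Partially matched crossover on distinct-index vectors, with repair.

    The segment mapping resolves clashes like classical PMX on permutations;
    any index still duplicated afterwards (possible because the vectors are
    subsets, not permutations) is replaced by a random unused marker.
    """
    k = p1.size
    a, b = sorted(rng.choice(k + 1, size=2, replace=False))
    child = p1.copy()
    child[a:b] = p2[a:b]
    mapping = {int(p2[t]): int(p1[t]) for t in range(a, b)}
    for t in list(range(0, a)) + list(range(b, k)):
        v = int(child[t])
        seen = set()
        while v in mapping and v in child[a:b] and v not in seen:
            seen.add(v)
            v = mapping[v]
        child[t] = v
    # repair residual duplicates with random unused markers
    used = set()
    dup_pos = []
    for t in range(k):
        v = int(child[t])
        if v in used:
            dup_pos.append(t)
        used.add(v)
    if dup_pos:
        unused = np.setdiff1d(np.arange(n_markers), child)
        repl = rng.choice(unused, size=len(dup_pos), replace=False)
        for t, v in zip(dup_pos, repl):
            child[t] = v
    return child


def ga_select(gm: GenotypeMatrix, config: GaConfig | None = None) -> FingerprintPanel:
    """Genetic-algorithm search for a k-marker fingerprint panel.

    Individuals are vectors of ``k`` distinct marker indices.  Each
    generation keeps the top ``survival_rate`` fraction by fitness (elitist
    truncation) and refills the population with PMX offspring of random
    survivor pairs (at ``crossover_rate``; otherwise a parent is cloned).
    Stops when every accession is identified, at ``max_generations``, or
    after ``plateau_generations`` without improvement.  Fully reproducible
    from ``config.rng_seed``.
    """
    config = config or GaConfig()
    config.validate(gm.n_markers)
    rng = np.random.default_rng(config.rng_seed)
    cov = _PairCoverage(gm)
    n_markers, k, pop_n = gm.n_markers, config.k, config.population_size

    pop = np.array([rng.choice(n_markers, size=k, replace=False) for _ in range(pop_n)])
    fits = np.array([cov.fitness_of(ind) for ind in pop])
    n_survive = max(2, int(round(config.survival_rate * pop_n)))
    best_trace: list[int] = []
    best_fit, stagnant, gen = int(fits.max()), 0, 0

    for gen in range(1, config.max_generations + 1):
        order = np.argsort(-fits, kind="stable")
        pop, fits = pop[order], fits[order]
        best_trace.append(int(fits[0]))
        if fits[0] >= gm.n_accessions:
            break
        survivors = pop[:n_survive]
        children = []
        while len(children) < pop_n - n_survive:
            i, j = rng.integers(0, n_survive, size=2)
            if rng.random() < config.crossover_rate:
                child = _pmx(survivors[i], survivors[j], n_markers, rng)
            else:
                child = survivors[i].copy()
            if config.mutation_rate > 0:
                mut = rng.random(k) < config.mutation_rate
                if mut.any():
                    unused = np.setdiff1d(np.arange(n_markers), child)
                    child[mut] = rng.choice(unused, size=int(mut.sum()), replace=False)
            children.append(child)
        pop = np.vstack([survivors, np.array(children)])
        fits = np.concatenate([fits[:n_survive],
                               [cov.fitness_of(c) for c in children]])
        new_best = int(fits.max())
        if new_best > best_fit:
            best_fit, stagnant = new_best, 0
        else:
            stagnant += 1
            if stagnant >= config.plateau_generations:
                break

    order = np.argsort(-fits, kind="stable")
    best = pop[order[0]]
    best_f = int(fits[order[0]])
    if not best_trace or best_trace[-1] != best_f:
        best_trace.append(best_f)
    return FingerprintPanel(
        marker_ids=[gm.marker_ids[t] for t in np.sort(best)],
        fitness=best_f,
        generations_run=gen,
        fitness_trace=best_trace,
        unresolved_pairs=_unresolved(gm, cov, best, config.min_ibs_distance),
    )


# ----------------------------------------------------------------------- oracles
def brute_force_select(
    gm: GenotypeMatrix, k: int, limit: int = 1_000_000, min_ibs_distance: float = 0.05
) -> FingerprintPanel:
    """Exhaustive fitness maximisation over all k-subsets.

    Deterministic: ties resolved by lexicographic subset order.  Refuses
    instances with more than ``limit`` subsets — use the greedy or GA search
    there.
    """
    n = gm.n_markers
    if comb(n, k) > limit:
        raise ValueError(f"C({n},{k}) exceeds {limit}; use greedy_select or ga_select")
    cov = _PairCoverage(gm)
    best, best_f = None, -1
    for subset in itertools.combinations(range(n), k):
        f = cov.fitness_of(np.array(subset))
        if f > best_f:
            best, best_f = subset, f
            if best_f == gm.n_accessions:
                break
    arr = np.array(best)
    return FingerprintPanel(
        marker_ids=[gm.marker_ids[t] for t in arr],
        fitness=best_f,
        generations_run=0,
        unresolved_pairs=_unresolved(gm, cov, arr, min_ibs_distance),
    )


def greedy_select(gm: GenotypeMatrix, k: int, min_ibs_distance: float = 0.05) -> FingerprintPanel:
    """Greedy forward selection on distinguished-pair coverage.

    At each step adds the marker covering the most still-uncovered pairs
    (ties to the lowest marker index) — a fast lower-bound oracle for the GA.
    """
    cov = _PairCoverage(gm)
    chosen: list[int] = []
    covered = np.zeros(cov.n_pairs, dtype=bool)
    unpacked = np.unpackbits(cov.packed, axis=1, count=cov.n_pairs).astype(bool)
    for _ in range(k):
        gains = (unpacked & ~covered[None, :]).sum(axis=1)
        gains[chosen] = -1
        pick = int(np.argmax(gains))
        chosen.append(pick)
        covered |= unpacked[pick]
    arr = np.array(chosen)
    return FingerprintPanel(
        marker_ids=[gm.marker_ids[t] for t in np.sort(arr)],
        fitness=cov.fitness_of(arr),
        generations_run=0,
        unresolved_pairs=_unresolved(gm, cov, arr, min_ibs_distance),
    )
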