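"""Population differentiation: Weir–Cockerham FST and hierarchical AMOVA.

The multilocus theta estimator follows Weir & Cockerham (1984): per-locus
variance components *a* (among populations), *b* (among individuals within
populations) and *c* (within individuals) are summed over loci and
``theta = sum(a) / sum(a + b + c)``.  Moment estimators can legitimately go
slightly negative when true differentiation is near zero; values are reported
raw, never clamped.

AMOVA is the distance-based (Excoffier-style) three-stratum decomposition on
allele-copy data — between groups, among accessions within groups, and
within accessions (residual heterozygosity) — with method-of-moments variance
components from the expected mean squares.  The within-accession stratum is
what makes the total degrees of freedom ``2N - 1`` for N diploid accessions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import MISSING, GenotypeMatrix


# --------------------------------------------------------------- Weir-Cockerham
def _wc_components(
    dosage: np.ndarray, labels: np.ndarray, groups: list
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-locus Weir & Cockerham (1984) a, b, c for ``r`` populations.

    Returns ``(a, b, c, usable)`` arrays over loci; loci where any population
    has < 2 genotyped samples, or where the denominator is undefined, are
    flagged unusable.
    """
    r = len(groups)
    n_i, p_i, h_i = [], [], []
    for g in groups:
        d = dosage[np.asarray(labels) == g]
        called = d != MISSING
        n = called.sum(axis=0).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(called, d, 0).sum(axis=0) / (2.0 * n)
            h = (d == 1).sum(axis=0) / n
        n_i.append(n)
        p_i.append(p)
        h_i.append(h)
    n_i = np.array(n_i)            # r x loci
    p_i = np.array(p_i)
    h_i = np.array(h_i)

    usable = (n_i >= 2).all(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        nbar = n_i.mean(axis=0)
        nc = (r * nbar - (n_i**2).sum(axis=0) / (r * nbar)) / (r - 1.0)
        pbar = (n_i * p_i).sum(axis=0) / (r * nbar)
        s2 = (n_i * (p_i - pbar) ** 2).sum(axis=0) / ((r - 1.0) * nbar)
        hbar = (n_i * h_i).sum(axis=0) / (r * nbar)

        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1.0) / r * s2 - hbar / 4.0) / (nbar - 1.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1 - pbar) - (r - 1.0) / r * s2 - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar
        )
        c = hbar / 2.0
    usable &= np.isfinite(a) & np.isfinite(b) & np.isfinite(c)
    return a, b, c, usable


def wc_fst(
    gm: GenotypeMatrix, group_labels: np.ndarray, pair: tuple | None = None
) -> tuple[float, int]:
    """Multilocus Weir–Cockerham theta for a pair (or all) of groups.

    Returns ``(theta, n_loci_used)``.  Monomorphic loci contribute zero to
    both numerator and denominator; loci with an undefined denominator are
    skipped and not counted.
    """
    labels = np.asarray(group_labels)
    groups = list(pair) if pair is not None else list(pd.unique(pd.Series(labels)))
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    a, b, c, usable = _wc_components(gm.dosage, labels, groups)
    denom_ok = usable & ((a + b + c) != 0)
    # loci monomorphic across all groups have a=b=c=0: usable but uninformative
    a, b, c = a[usable], b[usable], c[usable]
    if usable.sum() < 2:
        raise ValueError("fewer than 2 usable loci")
    denom = (a + b + c).sum()
    if denom == 0:
        raise ValueError("all usable loci monomorphic; theta undefined")
    return float(a.sum() / denom), int(denom_ok.sum())


@dataclass
class FstMatrix:
    group_ids: list[str]
    theta: np.ndarray          # symmetric, nan diagonal, NOT clamped
    n_loci: np.ndarray
    mean_offdiagonal: float


def fst_matrix(gm: GenotypeMatrix, group_labels: np.ndarray) -> FstMatrix:
    """Pairwise Weir–Cockerham theta over all group pairs.

    Groups with fewer than 2 members are skipped with a warning.  The mean
    off-diagonal value is reported as the average differentiation across
    groups.
    """
    labels = np.asarray(group_labels)
    counts = pd.Series(labels).value_counts()
    groups = [g for g in pd.unique(pd.Series(labels)) if counts[g] >= 2]
    for g in counts.index.difference(groups):
        warnings.warn(f"group {g!r} has < 2 members, skipped")
    k = len(groups)
    theta = np.full((k, k), np.nan)
    n_loci = np.zeros((k, k), dtype=int)
    for i in range(k):
        for j in range(i + 1, k):
            t, n = wc_fst(gm, labels, (groups[i], groups[j]))
            theta[i, j] = theta[j, i] = t
            n_loci[i, j] = n_loci[j, i] = n
    off = theta[np.triu_indices(k, 1)]
    return FstMatrix([str(g) for g in groups], theta, n_loci,
                     float(np.nanmean(off)) if off.size else np.nan)


# ----------------------------------------------------------------------- AMOVA
@dataclass
class AmovaTable:
    """Three-stratum AMOVA table plus derived quantities."""

    table: pd.DataFrame      # rows: between_groups / among_within / within / total
    phi_st: float            # between-group component share (can be negative)
    n_accessions: int
    n_groups: int

    @property
    def percentages(self) -> np.ndarray:
        return self.table["pct_of_total"].to_numpy()[:3]


def amova_df(n_accessions: int, n_groups: int) -> tuple[int, int, int, int]:
    """Degrees of freedom for the three strata and their total.

    ``(G - 1, N - G, N, 2N - 1)`` — the within-accession stratum has one df
    per diploid accession, which is what makes the total ``2N - 1``.
    """
    N, G = n_accessions, n_groups
    return (G - 1, N - G, N, 2 * N - 1)


def amova_percentages(components: tuple[float, float, float]) -> np.ndarray:
    """Percent of total variance per stratum from raw variance components.

    Negative components are retained (not truncated), as moment estimators
    can produce them; the percentages still sum to 100.
    """
    comp = np.asarray(components, dtype=float)
    return 100.0 * comp / comp.sum()


def amova(
    gm: GenotypeMatrix,
    group_labels: np.ndarray,
    n_permutations: int = 0,
    rng_seed: int = 0,
    strict: bool = False,
) -> AmovaTable:
    """Hierarchical AMOVA on allele-copy data.

    Each diploid accession contributes two allele copies per locus (an
    unphased heterozygote contributes one of each allele); sums of squares
    are the classical nested-ANOVA sums on the alternate-allele indicator,
    accumulated over loci, which equals the squared-difference distance
    formulation.  Missing calls are mean-imputed per locus (they contribute
    no within-accession variance).  Variance components come from the
    expected mean squares with the unequal-group-size coefficient
    ``n0 = (N - sum(n_g^2) / N) / (G - 1)``; negative components are retained.

    Optional permutation p-values (accession labels permuted across groups)
    are attached to the table when ``n_permutations > 0``.
    """
    labels = np.asarray(group_labels)
    counts = pd.Series(labels).value_counts()
    if strict and (counts < 2).any():
        raise ValueError(f"groups of size 1: {list(counts.index[counts < 2])}")
    if (counts < 2).any():
        singles = counts.index[counts < 2]
        warnings.warn(f"groups of size 1 merged into 'unassigned': {list(singles)}")
        labels = np.where(np.isin(labels, singles), "unassigned", labels)
    groups = list(pd.unique(pd.Series(labels)))
    if len(groups) < 2:
        raise ValueError("need at least two groups of >= 2 accessions")

    def strata_ss(lbl: np.ndarray) -> tuple[float, float, float]:
        d = gm.dosage.astype(float)
        called = d != MISSING
        with np.errstate(invalid="ignore", divide="ignore"):
            locus_mean = np.where(called, d, 0).sum(axis=0) / called.sum(axis=0)
        d = np.where(called, d, locus_mean[None, :])          # mean imputation
        ind_mean = d / 2.0                                     # per-copy mean per accession
        # within accessions: het call => copies (0,1) around mean 0.5 => SS 0.5
        ss_within = 0.5 * float(((d == 1) & called).sum())
        grand = ind_mean.mean(axis=0)
        ss_among, ss_between = 0.0, 0.0
        for g in np.unique(lbl):
            rows = ind_mean[lbl == g]
            gmean = rows.mean(axis=0)
            ss_among += 2.0 * float(((rows - gmean[None, :]) ** 2).sum())
            ss_between += 2.0 * len(rows) * float(((gmean - grand) ** 2).sum())
        return ss_between, ss_among, ss_within

    N = gm.n_accessions
    G = len(groups)
    df_b, df_a, df_w, df_t = amova_df(N, G)
    ss_b, ss_a, ss_w = strata_ss(labels)
    ms_b, ms_a, ms_w = ss_b / df_b, ss_a / df_a, ss_w / df_w

    sizes = pd.Series(labels).value_counts().reindex(groups).to_numpy(dtype=float)
    n0 = (N - (sizes**2).sum() / N) / (G - 1.0)
    sigma_w = ms_w
    sigma_a = (ms_a - ms_w) / 2.0
    sigma_b = (ms_b - ms_a) / (2.0 * n0)
    comps = np.array([sigma_b, sigma_a, sigma_w])
    pct = amova_percentages(tuple(comps))

    table = pd.DataFrame(
        {
            "df": [df_b, df_a, df_w, df_t],
            "SS": [ss_b, ss_a, ss_w, ss_b + ss_a + ss_w],
            "MS": [ms_b, ms_a, ms_w, (ss_b + ss_a + ss_w) / df_t],
            "variance_component": [*comps, comps.sum()],
            "pct_of_total": [*pct, 100.0],
        },
        index=["between_groups", "among_accessions_within_groups",
               "within_accessions", "total"],
    )
    if (comps < 0).any():
        warnings.warn("negative variance component(s) retained (moment estimator)")

    if n_permutations > 0:
        rng = np.random.default_rng(rng_seed)
        obs = ss_b
        hits = 0
        for _ in range(n_permutations):
            perm = rng.permutation(labels)
            if strata_ss(perm)[0] >= obs:
                hits += 1
        table.attrs["p_between_groups"] = (hits + 1) / (n_permutations + 1)

    return AmovaTable(table, float(comps[0] / comps.sum()), N, G)
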