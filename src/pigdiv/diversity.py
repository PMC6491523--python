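"""Group-wise genetic diversity: allele counts, rarefied allelic richness,
observed/expected heterozygosity, FIS with bootstrap confidence intervals.

All statistics are biallelic-SNP statistics.  He carries Nei's unbiased
small-sample correction ``2n / (2n - 1)`` alongside the raw ``2p(1-p)``
value; multilocus FIS is the ratio-of-averages ``1 - mean(Ho) / mean(He)``
with a percentile CI from bootstrapping loci.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .panel import MISSING, GenotypeMatrix


@dataclass
class DiversitySummary:
    """One row of a diversity table for a single group."""

    group_id: str
    n_accessions: int
    A: int                      # total alleles observed across loci (<= 2 per locus)
    pct_alleles: float          # A as % of 2 x n_loci
    Ar_mean: float
    Ar_sd: float
    Ho_mean: float
    Ho_sd: float
    He_mean: float
    He_sd: float
    FIS: float
    FIS_low: float
    FIS_high: float


def locus_stats(gm: GenotypeMatrix, group_mask: np.ndarray) -> pd.DataFrame:
    """Per-locus allele frequency, sample size, Ho and He within one group.

    ``He_unbiased = 2p(1-p) * 2n/(2n-1)`` (Nei's correction); loci with fewer
    than 2 genotyped samples in the group are returned with ``nan`` and are
    skipped by downstream averages.
    """
    d = gm.dosage[group_mask]
    called = d != MISSING
    n = called.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(called, d, 0).sum(axis=0) / (2.0 * n)
        ho = (d == 1).sum(axis=0) / n
        he_raw = 2.0 * p * (1.0 - p)
        he_unb = he_raw * (2.0 * n) / (2.0 * n - 1.0)
    ok = n >= 2
    out = pd.DataFrame(
        {"p": p, "n": n, "Ho": ho, "He_raw": he_raw, "He_unbiased": he_unb},
        index=pd.Index(gm.marker_ids, name="marker_id"),
    )
    out.loc[~ok, ["p", "Ho", "He_raw", "He_unbiased"]] = np.nan
    return out


def allelic_richness(
    gm: GenotypeMatrix, group_labels: np.ndarray, rarefaction_g: int | None = None
) -> pd.DataFrame:
    """Rarefied allelic richness per group.

    Per locus, the expected number of distinct alleles in a random draw of
    ``2 * rarefaction_g`` allele copies (hypergeometric rarefaction):
    ``Ar = sum_alleles [1 - C(2n - count, g) / C(2n, g)]``.  ``rarefaction_g``
    defaults to the smallest group's minimum per-locus genotyped count, so the
    statistic is comparable across unequal group sizes.
    """
    groups = pd.unique(pd.Series(group_labels))
    masks = {g: np.asarray(group_labels) == g for g in groups}
    min_n = min(int(np.min((gm.dosage[m] != MISSING).sum(axis=0))) for m in masks.values())
    g = rarefaction_g if rarefaction_g is not None else min_n
    if g < 1:
        raise ValueError("rarefaction size must be >= 1 genotyped sample")
    if g > min_n:
        raise ValueError(f"rarefaction size {g} exceeds smallest per-locus "
                         f"genotyped count {min_n}")
    copies = 2 * g

    def log_comb(a, b):
        return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)

    rows = {}
    for gid, mask in masks.items():
        d = gm.dosage[mask]
        called = d != MISSING
        n2 = 2.0 * called.sum(axis=0)
        alt = np.where(called, d, 0).sum(axis=0).astype(float)
        ref = n2 - alt
        ar = np.zeros(gm.n_markers)
        for count in (ref, alt):
            # P(allele absent from the rarefied draw) = C(2n - count, copies)/C(2n, copies)
            with np.errstate(invalid="ignore"):
                absent = np.where(
                    n2 - count >= copies,
                    np.exp(log_comb(n2 - count, copies) - log_comb(n2, copies)),
                    0.0,
                )
            ar += np.where(count > 0, 1.0 - absent, 0.0)
        rows[gid] = ar
    return pd.DataFrame(rows, index=pd.Index(gm.marker_ids, name="marker_id"))


def fis(
    gm: GenotypeMatrix,
    group_mask: np.ndarray,
    n_boot: int = 1000,
    ci: float = 0.95,
    rng_seed: int = 0,
) -> tuple[float, float, float]:
    """Multilocus FIS with a loci-bootstrap percentile confidence interval.

    ``FIS = 1 - mean_loci(Ho) / mean_loci(He_unbiased)`` over loci polymorphic
    in the group.  Returns ``(FIS, low, high)``; ``nan`` everywhere if mean He
    is zero (statistic undefined).
    """
    ls = locus_stats(gm, group_mask)
    use = ls["He_unbiased"].to_numpy() > 0
    ho = ls["Ho"].to_numpy()[use]
    he = ls["He_unbiased"].to_numpy()[use]
    if ho.size < 2:
        raise ValueError("need >= 2 polymorphic loci in the group")
    if he.mean() == 0:
        return (np.nan, np.nan, np.nan)
    point = 1.0 - ho.mean() / he.mean()
    rng = np.random.default_rng(rng_seed)
    idx = rng.integers(0, ho.size, size=(n_boot, ho.size))
    boots = 1.0 - ho[idx].mean(axis=1) / he[idx].mean(axis=1)
    alpha = (1.0 - ci) / 2.0
    low, high = np.quantile(boots, [alpha, 1.0 - alpha])
    return (float(point), float(low), float(high))


def per_accession_het(gm: GenotypeMatrix) -> pd.Series:
    """Heterozygous fraction of non-missing calls, per accession.

    Accessions with no calls at all are ``nan`` (undefined, flagged by the
    caller rather than silently zero).
    """
    called = gm.dosage != MISSING
    n = called.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        het = (gm.dosage == 1).sum(axis=1) / n
    return pd.Series(np.where(n > 0, het, np.nan),
                     index=pd.Index(gm.accession_ids, name="accession_id"))


def diversity_table(
    gm: GenotypeMatrix,
    group_labels: np.ndarray,
    n_boot: int = 1000,
    rng_seed: int = 0,
    rarefaction_g: int | None = None,
) -> pd.DataFrame:
    """Per-group diversity summary (the familiar one-row-per-group table).

    Columns: A (total observed alleles across loci), % (A over the biallelic
    maximum ``2 x n_loci``), Ar +/- SD, Ho +/- SD, He +/- SD, FIS with 95% CI.
    """
    group_labels = np.asarray(group_labels)
    ar = allelic_richness(gm, group_labels, rarefaction_g)
    rows = []
    for k, gid in enumerate(pd.unique(pd.Series(group_labels))):
        mask = group_labels == gid
        ls = locus_stats(gm, mask)
        poly = ls["p"].notna()
        a_total = int(((ls["p"] > 0) & (ls["p"] < 1)).sum() * 2
                      + ((ls["p"] == 0) | (ls["p"] == 1)).sum())
        f, lo, hi = fis(gm, mask, n_boot=n_boot, rng_seed=rng_seed + k)
        rows.append(DiversitySummary(
            group_id=str(gid),
            n_accessions=int(mask.sum()),
            A=a_total,
            pct_alleles=100.0 * a_total / (2.0 * gm.n_markers),
            Ar_mean=float(ar[gid].mean()), Ar_sd=float(ar[gid].std(ddof=1)),
            Ho_mean=float(ls.loc[poly, "Ho"].mean()),
            Ho_sd=float(ls.loc[poly, "Ho"].std(ddof=1)),
            He_mean=float(ls.loc[poly, "He_unbiased"].mean()),
            He_sd=float(ls.loc[poly, "He_unbiased"].std(ddof=1)),
            FIS=f, FIS_low=lo, FIS_high=hi,
        ))
    return pd.DataFrame([r.__dict__ for r in rows]).set_index("group_id")
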