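"""Rc-indel scoring against pericarp colour, and seed-trait statistics.

The Rc locus controls red pericarp pigmentation; a 14-bp exon-6 deletion
(the *rc* allele) abolishes it, so deletion calls (scored 0 = deletion
present, 1 = absent) should track the white colour class — discordant
accessions (pigmented with the deletion, or white without it) are the
biologically interesting residue and are listed explicitly.

Seed traits come in as per-accession means of multi-spectral measurements
(geometry: area, length, width, roundness; colour appearance: CIE L*, a*,
b*, hue, saturation, intensity).  The statistics stage provides descriptive
summaries with normality flags, Pearson correlations, a standardized-trait
PCA, and one-way ANOVA across colour classes with Bartlett homoscedasticity
gating (log transform on failure; traits still heterogeneous afterwards are
excluded from Tukey testing and reported as precluded).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


# ------------------------------------------------------------------ Rc crosstab
@dataclass
class RcCrosstab:
    table: pd.DataFrame                 # colour class x rc_score counts
    pct_within_score: pd.DataFrame      # column percentages within each score
    discordant: list[str]               # pigmented with deletion / white without
    ambiguous: list[str]
    unmatched: list[str]


def rc_crosstab(calls: pd.DataFrame, colours: pd.Series) -> RcCrosstab:
    """Cross-tabulate binary Rc deletion scores against colour classes.

    ``calls`` must carry an ``rc_score`` column (0 = deletion present,
    1 = absent, anything else treated as ambiguous and excluded from the
    percentage columns).  Accessions present in only one input are listed as
    unmatched, never silently dropped.
    """
    colours = colours.astype(str)
    common = calls.index.intersection(colours.index)
    unmatched = sorted(set(calls.index).symmetric_difference(colours.index))
    sub = calls.loc[common]
    ambiguous = sorted(sub.index[~sub["rc_score"].isin([0, 1])])
    clean = sub[sub["rc_score"].isin([0, 1])]
    col = colours.loc[clean.index]
    table = pd.crosstab(col, clean["rc_score"]).reindex(
        columns=[0, 1], fill_value=0)
    # zero rows for colour classes absent from the matched set
    for cls in colours.unique():
        if cls not in table.index:
            table.loc[cls] = 0
    table = table.sort_index()
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = 100.0 * table / table.sum(axis=0)
    pigmented = col != "white"
    has_del = clean["rc_score"] == 0
    discordant = sorted(clean.index[(pigmented & has_del) | (~pigmented & ~has_del)])
    return RcCrosstab(table, pct.fillna(0.0), discordant, ambiguous, unmatched)


# ------------------------------------------------------------------ descriptives
def _trait_columns(tt: pd.DataFrame) -> list[str]:
    return [c for c in tt.columns if c != "colour_class"]


def describe_traits(tt: pd.DataFrame) -> pd.DataFrame:
    """Descriptive statistics per trait, with a Shapiro–Wilk normality flag.

    Columns: min, max, range, median, variance, SD, CV (= SD / mean), plus
    ``shapiro_p`` and ``normal`` at alpha = 0.05.  Constant traits get CV = 0
    and the normality test is skipped (flagged with ``nan`` p).
    """
    if len(tt) < 3:
        raise ValueError("need at least 3 accessions")
    rows = {}
    for c in _trait_columns(tt):
        x = tt[c].to_numpy(dtype=float)
        sd = float(np.std(x, ddof=1))
        mean = float(np.mean(x))
        if sd == 0.0:
            sw_p, normal = np.nan, True
        else:
            sw_p = float(stats.shapiro(x).pvalue)
            normal = sw_p > 0.05
        rows[c] = {
            "min": float(np.min(x)), "max": float(np.max(x)),
            "range": float(np.ptp(x)), "median": float(np.median(x)),
            "variance": sd**2, "SD": sd,
            "CV": 0.0 if sd == 0.0 else sd / mean,
            "shapiro_p": sw_p, "normal": normal,
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def trait_correlations(tt: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson r and two-sided p-values for every trait pair.

    Zero-variance traits give ``nan`` (undefined correlation, flagged by the
    nan rather than a bogus number).
    """
    cols = _trait_columns(tt)
    k = len(cols)
    r = np.eye(k)
    p = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            x, y = tt[cols[i]], tt[cols[j]]
            both = x.notna() & y.notna()
            if both.sum() < 3 or x[both].std() == 0 or y[both].std() == 0:
                r[i, j] = r[j, i] = np.nan
                p[i, j] = p[j, i] = np.nan
                continue
            res = stats.pearsonr(x[both], y[both])
            r[i, j] = r[j, i] = res.statistic
            p[i, j] = p[j, i] = res.pvalue
    return (pd.DataFrame(r, index=cols, columns=cols),
            pd.DataFrame(p, index=cols, columns=cols))


# -------------------------------------------------------------------- trait PCA
@dataclass
class TraitPca:
    eigenvalues: np.ndarray
    pct_variance: np.ndarray
    scores: pd.DataFrame            # indexed by accession, colour_class column kept
    loadings: pd.DataFrame          # traits x PCs


def trait_pca(tt: pd.DataFrame) -> TraitPca:
    """PCA of standardized traits (unit variance), scores labelled by colour.

    Constant traits are dropped with a warning.
    """
    cols = _trait_columns(tt)
    if len(cols) < 2 or len(tt) < 3:
        raise ValueError("need >= 2 traits and >= 3 accessions")
    X = tt[cols].to_numpy(dtype=float)
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.all():
        warnings.warn(f"constant traits dropped: {[c for c, k in zip(cols, keep) if not k]}")
        cols = [c for c, k in zip(cols, keep) if k]
        X, sd = X[:, keep], sd[keep]
    Z = (X - X.mean(axis=0)) / sd
    cov = np.cov(Z, rowvar=False)
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1]
    vals, vecs = np.maximum(vals[order], 0.0), vecs[:, order]
    scores = pd.DataFrame(Z @ vecs, index=tt.index,
                          columns=[f"PC{i+1}" for i in range(len(cols))])
    if "colour_class" in tt.columns:
        scores.insert(0, "colour_class", tt["colour_class"])
    return TraitPca(vals, 100.0 * vals / vals.sum(), scores,
                    pd.DataFrame(vecs, index=cols,
                                 columns=[f"PC{i+1}" for i in range(len(cols))]))


# ------------------------------------------------------------------ gated ANOVA
@dataclass
class AnovaResult:
    trait: str
    F: float
    df: tuple[int, int]
    p_value: float
    transform: str | None            # None, "log", ...
    precluded: bool                  # heterogeneous even after transform
    bartlett_p: float
    shapiro_p: float
    tukey: pd.DataFrame | None = None
    dropped_classes: list[str] = field(default_factory=list)


def colour_anova(
    tt: pd.DataFrame,
    trait: str,
    alpha: float = 0.05,
    transform: str = "log",
) -> AnovaResult:
    """One-way ANOVA of a trait across colour classes with assumption gating.

    Residuals are checked with Shapiro–Wilk (normality) and the class
    variances with Bartlett's test.  If Bartlett fails at ``alpha`` the trait
    is transformed (natural log by default, Box–Cox as an option) and
    retested; if still heterogeneous the trait is marked *precluded* and no
    Tukey table is produced.  Otherwise Tukey HSD pairwise comparisons are
    computed on the (possibly transformed) scale.  Classes with a single
    member are dropped with a warning.
    """
    counts = tt["colour_class"].value_counts()
    dropped = sorted(counts.index[counts < 2])
    if dropped:
        warnings.warn(f"classes with one member dropped: {dropped}")
    data = tt[~tt["colour_class"].isin(dropped)]
    classes = sorted(data["colour_class"].unique())
    if len(classes) < 2:
        raise ValueError("need >= 2 colour classes with >= 2 members")
    y = data[trait].to_numpy(dtype=float)
    labels = data["colour_class"].to_numpy()

    def run(values: np.ndarray) -> tuple:
        groups = [values[labels == c] for c in classes]
        F, p = stats.f_oneway(*groups)
        bart_p = stats.bartlett(*groups).pvalue
        resid = np.concatenate([g - g.mean() for g in groups])
        sw_p = stats.shapiro(resid).pvalue if resid.std() > 0 else np.nan
        return groups, float(F), float(p), float(bart_p), float(sw_p)

    groups, F, p, bart_p, sw_p = run(y)
    used_transform: str | None = None
    if bart_p <= alpha:
        if transform == "log":
            shiftv = 1.0 - y.min() if y.min() <= 0 else 0.0
            yt = np.log(y + shiftv)
        elif transform == "boxcox":
            shiftv = 1e-9 - y.min() if y.min() <= 0 else 0.0
            yt, _ = stats.boxcox(y + shiftv)
        else:
            raise ValueError(f"unknown transform {transform!r}")
        groups, F, p, bart_p, sw_p = run(yt)
        used_transform = transform

    precluded = bart_p <= alpha
    n = sum(len(g) for g in groups)
    df = (len(classes) - 1, n - len(classes))

    tukey = None
    if not precluded and p <= alpha:
        res = stats.tukey_hsd(*groups)
        ci = res.confidence_interval()
        rows = []
        for i in range(len(classes)):
            for j in range(i + 1, len(classes)):
                rows.append({
                    "class_a": classes[i], "class_b": classes[j],
                    "mean_diff": float(np.mean(groups[i]) - np.mean(groups[j])),
                    "p_adj": float(res.pvalue[i, j]),
                    "ci_low": float(ci.low[i, j]), "ci_high": float(ci.high[i, j]),
                    "significant": bool(res.pvalue[i, j] <= alpha),
                })
        tukey = pd.DataFrame(rows)

    return AnovaResult(trait, F, df, p, used_transform, precluded,
                       bart_p, sw_p, tukey, dropped)
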