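"""Synthetic genotype panels, passport data, indel calls and seed traits.

Every downstream stage of the pipeline (QC, duplicate collapsing, diversity,
differentiation, structure, fingerprinting, phenotype statistics) is testable
without external data because this module generates panels with the
statistical structure the analysis assumes:

* **Population structure** via the Balding–Nichols model: each group's
  per-locus allele frequency is a Beta draw around a shared ancestral
  frequency, parameterised directly by a divergence ``F`` — so Weir–Cockerham
  FST recovery is a quantitative test, not a qualitative one.
* **Inbreeding** via explicit selfing rounds: each round halves the expected
  heterozygosity, so after ``t`` rounds FIS has the closed-form expectation
  ``1 - (1/2)**t``, matching the near-complete inbreeding of a rice landrace
  collection.
* **Genebank redundancy** via exact duplicate accessions injected *before*
  missingness, so duplicate pairs may disagree at missing calls — this
  deliberately stresses the probability-of-identity threshold downstream.

Defaults emulate a pigmented-rice array panel: 1536 biallelic markers across
12 chromosomes, two diverged subspecies groups (F = 0.5 each, giving pairwise
FST near 0.5), four selfing generations (FIS expectation 0.9375) and 5%
missingness.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import MISSING, MAP_COLUMNS, GenotypeMatrix

DEFAULT_GROUP_SPEC: tuple[tuple[str, int, float], ...] = (
    ("indica", 150, 0.5),
    ("japonica", 150, 0.5),
)

#: Seed colour classes in the order used for default trait means.
COLOUR_CLASSES = ("red", "purple", "variable purple", "white", "mixed")

TRAIT_NAMES = ("area", "length", "width", "roundness",
               "lightness", "a_star", "b_star", "hue", "saturation", "intensity")


@dataclass
class PanelConfig:
    """Configuration of a synthetic genotype panel.

    ``group_spec`` lists ``(group_id, n_accessions, divergence_F)`` triples;
    ``divergence_F`` is the Balding–Nichols parameter in ``[0, 1)`` (0 means
    the group sits at the ancestral frequency).  ``n_duplicates`` extra
    accessions are appended as exact copies of randomly chosen originals.
    ``sample_missing_multiplier`` maps accession id -> multiplier on the
    missing rate, to plant samples that fail the 0.95 call-rate filter.
    """

    n_markers: int = 1536
    n_chromosomes: int = 12
    group_spec: tuple[tuple[str, int, float], ...] = DEFAULT_GROUP_SPEC
    selfing_generations: int = 4
    n_duplicates: int = 0
    missing_rate: float = 0.05
    ancestral_maf_range: tuple[float, float] = (0.1, 0.5)
    rng_seed: int = 0
    sample_missing_multiplier: dict[str, float] = field(default_factory=dict)

    def validate(self) -> None:
        total = sum(n for _, n, _ in self.group_spec)
        if total < 2:
            raise ValueError("sum of group sizes must be >= 2")
        if any(not (0 <= F < 1) for _, _, F in self.group_spec):
            raise ValueError("divergence F must lie in [0, 1)")
        if self.n_duplicates < 0 or self.n_duplicates >= total + self.n_duplicates + 1:
            raise ValueError("n_duplicates must be a count below total accessions")
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must lie in [0, 1)")
        lo, hi = self.ancestral_maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("ancestral_maf_range must lie in (0, 0.5]")
        if self.selfing_generations < 0:
            raise ValueError("selfing_generations must be >= 0")


@dataclass
class SyntheticTruth:
    """Ground truth recorded alongside a simulated panel."""

    group_of: dict[str, str]
    duplicate_pairs: list[tuple[str, str]]
    divergence_F: dict[str, float]
    allele_frequencies: pd.DataFrame  # loci x groups realized frequencies
    colour_of: dict[str, str] = field(default_factory=dict)
    discordant_indel_accessions: list[str] = field(default_factory=list)
    trait_class_means: pd.DataFrame | None = None

    def duplicate_clusters(self) -> list[set[str]]:
        """Planted duplicate clusters (each original with its copies)."""
        clusters: dict[str, set[str]] = {}
        for src, dup in self.duplicate_pairs:
            root = next((k for k, v in clusters.items() if src in v or dup in v), src)
            clusters.setdefault(root, {root}).update({src, dup})
        return list(clusters.values())


def _selfing(genotypes: np.ndarray, rounds: int, rng: np.random.Generator) -> np.ndarray:
    # selfing a heterozygote yields 1/4 AA, 1/2 Aa, 1/4 aa per round, so
    # heterozygosity halves each generation (FIS -> 1 - 2^-t)
    for _ in range(rounds):
        het = genotypes == 1
        draw = rng.random(genotypes.shape)
        resolved = np.where(draw < 0.25, 0, np.where(draw < 0.5, 2, 1))
        genotypes = np.where(het, resolved, genotypes).astype(np.int8)
    return genotypes


def simulate_panel(config: PanelConfig) -> tuple[GenotypeMatrix, SyntheticTruth]:
    """Simulate a structured, inbred, partially duplicated genotype panel.

    Per locus an ancestral frequency ``p0`` is drawn uniformly in
    ``ancestral_maf_range``; each group's frequency is Beta-distributed with
    mean ``p0`` and variance ``F * p0 * (1 - p0)`` (for ``F = 0`` the group
    uses ``p0`` directly).  Genotypes start at Hardy–Weinberg proportions and
    are pushed toward homozygosity by the selfing rounds.  Fully reproducible
    from ``config.rng_seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.rng_seed)
    m = config.n_markers

    p0 = rng.uniform(*config.ancestral_maf_range, size=m)
    group_ids = [g for g, _, _ in config.group_spec]
    freqs = {}
    for gid, _, F in config.group_spec:
        if F == 0.0:
            freqs[gid] = p0.copy()
        else:
            a = p0 * (1 - F) / F
            b = (1 - p0) * (1 - F) / F
            freqs[gid] = rng.beta(a, b)

    acc_ids: list[str] = []
    group_of: dict[str, str] = {}
    blocks = []
    for gid, n_acc, _ in config.group_spec:
        p = freqs[gid]
        geno = rng.binomial(2, p, size=(n_acc, m)).astype(np.int8)
        geno = _selfing(geno, config.selfing_generations, rng)
        blocks.append(geno)
        for k in range(n_acc):
            aid = f"{gid}_{k:04d}"
            acc_ids.append(aid)
            group_of[aid] = gid
    geno = np.vstack(blocks)

    # duplicates: exact copies appended before missingness; sources drawn with
    # replacement so clusters of size > 2 can occur
    duplicate_pairs: list[tuple[str, str]] = []
    if config.n_duplicates:
        src_idx = rng.integers(0, len(acc_ids), size=config.n_duplicates)
        dup_rows = geno[src_idx]
        for i, s in enumerate(src_idx):
            dup_id = f"dup_{i:04d}_of_{acc_ids[s]}"
            duplicate_pairs.append((acc_ids[s], dup_id))
            group_of[dup_id] = group_of[acc_ids[s]]
            acc_ids.append(dup_id)
        geno = np.vstack([geno, dup_rows])

    if config.missing_rate > 0 or config.sample_missing_multiplier:
        rates = np.full(len(acc_ids), config.missing_rate)
        for aid, mult in config.sample_missing_multiplier.items():
            rates[acc_ids.index(aid)] = min(config.missing_rate * mult, 0.999)
        miss = rng.random(geno.shape) < rates[:, None]
        geno = np.where(miss, MISSING, geno).astype(np.int8)

    # evenly spaced markers across chromosomes
    per_chrom = np.array_split(np.arange(m), config.n_chromosomes)
    map_rows, marker_ids = [], []
    for c, idxs in enumerate(per_chrom, start=1):
        for k, j in enumerate(idxs):
            marker_ids.append(f"snp_{j:05d}")
            map_rows.append((f"chr{c:02d}", (k + 1) * 100_000, "A", "G"))
    marker_map = pd.DataFrame(map_rows, columns=MAP_COLUMNS,
                              index=pd.Index(marker_ids, name="marker_id"))
    passport = pd.DataFrame(
        {"subspecies": [group_of[a] for a in acc_ids]},
        index=pd.Index(acc_ids, name="accession_id"),
    )
    gm = GenotypeMatrix(acc_ids, marker_ids, geno, marker_map, passport)
    truth = SyntheticTruth(
        group_of=group_of,
        duplicate_pairs=duplicate_pairs,
        divergence_F={g: F for g, _, F in config.group_spec},
        allele_frequencies=pd.DataFrame(freqs, index=marker_ids),
    )
    return gm, truth


def simulate_sib_families(
    n_pairs: int,
    n_markers: int = 1000,
    maf_range: tuple[float, float] = (0.1, 0.5),
    rng_seed: int = 0,
) -> tuple[GenotypeMatrix, list[tuple[str, str]]]:
    """Simulate full-sib pairs from random outbred parents in one population.

    Each pair shares two parents; offspring genotypes follow Mendelian
    transmission, so the expected kinship-style identity (PI-HAT) between sibs
    is 0.5.  Used as the simulation oracle for the method-of-moments
    relatedness estimator.
    """
    rng = np.random.default_rng(rng_seed)
    p = rng.uniform(*maf_range, size=n_markers)
    ids, rows, pairs = [], [], []
    for k in range(n_pairs):
        parents = rng.binomial(1, p, size=(2, 2, n_markers))  # 2 parents x 2 haplotypes
        for o in range(2):
            gametes = parents[:, 0, :] * (1 - (pick := rng.integers(0, 2, (2, n_markers)))) \
                + parents[:, 1, :] * pick
            rows.append((gametes[0] + gametes[1]).astype(np.int8))
            ids.append(f"fam{k:03d}_sib{o}")
        pairs.append((ids[-2], ids[-1]))
    marker_ids = [f"snp_{j:05d}" for j in range(n_markers)]
    marker_map = pd.DataFrame(
        {"chromosome": "chr01", "position": np.arange(1, n_markers + 1) * 1000,
         "ref_allele": "A", "alt_allele": "G"},
        index=pd.Index(marker_ids, name="marker_id"),
    )
    gm = GenotypeMatrix(ids, marker_ids, np.vstack(rows), marker_map)
    return gm, pairs


# ------------------------------------------------------------------ seed traits
def default_trait_model() -> tuple[pd.DataFrame, np.ndarray]:
    """Default per-class trait means and shared trait covariance.

    Means are ordered so red accessions score highest on lightness, a* and
    intensity and purple lowest, as multi-spectral imaging of pigmented rice
    shows.  The covariance comes from a two-factor model (a colour-appearance
    factor and a seed-geometry factor), which is positive semi-definite by
    construction and induces the hallmark correlations: intensity–lightness
    near 0.99, strongly negative roundness–width, negative hue–a*.
    """
    base = pd.Series(
        {"area": 12.0, "length": 6.5, "width": 2.6, "roundness": 0.45,
         "lightness": 38.0, "a_star": 9.0, "b_star": 14.0, "hue": 62.0,
         "saturation": 20.0, "intensity": 30.0})
    shift = {  # colour-trait offsets per class, geometry left untouched
        "red": {"lightness": +8, "a_star": +4, "b_star": +3, "intensity": +8,
                "saturation": +6, "hue": -4},
        "purple": {"lightness": -10, "a_star": -4, "b_star": -6, "intensity": -10,
                   "saturation": -8, "hue": +4},
        "variable purple": {"lightness": -7, "a_star": -3, "b_star": -7,
                            "intensity": -7, "saturation": -10, "hue": +3},
        "white": {"lightness": +6, "a_star": -1, "b_star": +2, "intensity": +6,
                  "saturation": +2, "hue": +2},
        "mixed": {"lightness": +2, "a_star": +1, "b_star": +1, "intensity": +2,
                  "saturation": +1, "hue": 0},
    }
    means = pd.DataFrame({cls: base.add(pd.Series(off), fill_value=0.0)
                          for cls, off in shift.items()}).T[list(TRAIT_NAMES)]

    # factor loadings (colour factor, geometry factor) per trait, unit-diagonal
    # correlation completed with idiosyncratic noise
    load = pd.DataFrame(
        {"colour": {"area": 0.0, "length": 0.0, "width": 0.0, "roundness": 0.0,
                    "lightness": 0.995, "a_star": 0.70, "b_star": 0.92, "hue": -0.80,
                    "saturation": 0.95, "intensity": 0.995},
         "geometry": {"area": 0.80, "length": 0.60, "width": 0.90, "roundness": -0.78,
                      "lightness": 0.0, "a_star": 0.0, "b_star": 0.0, "hue": 0.0,
                      "saturation": 0.0, "intensity": 0.0}}
    ).loc[list(TRAIT_NAMES)]
    L = load.to_numpy()
    corr = L @ L.T
    np.fill_diagonal(corr, 1.0)
    # SDs chosen so hue is the least dispersed trait and saturation the most
    sd = np.array([1.8, 0.55, 0.28, 0.05, 4.5, 2.2, 3.0, 4.2, 8.0, 4.0])
    cov = corr * np.outer(sd, sd)
    return means, cov


def simulate_traits(
    truth: SyntheticTruth,
    class_means: pd.DataFrame | None = None,
    class_cov: np.ndarray | None = None,
    rng_seed: int = 0,
    colour_of: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Draw multivariate-normal seed traits per colour class.

    Returns a TraitTable: a DataFrame indexed by accession id with a
    ``colour_class`` column and one column per trait.  Colour classes come
    from ``colour_of`` (or ``truth.colour_of``); if absent, classes are
    assigned round-robin over the default classes and recorded in the truth.
    """
    if class_means is None or class_cov is None:
        d_means, d_cov = default_trait_model()
        class_means = d_means if class_means is None else class_means
        class_cov = d_cov if class_cov is None else class_cov
    class_cov = np.asarray(class_cov, dtype=float)
    eig = np.linalg.eigvalsh((class_cov + class_cov.T) / 2)
    if eig.min() < -1e-8 * max(eig.max(), 1.0):
        raise ValueError("class covariance must be positive semi-definite")

    colour_of = colour_of or truth.colour_of
    if not colour_of:
        classes = list(class_means.index)
        colour_of = {a: classes[i % len(classes)]
                     for i, a in enumerate(sorted(truth.group_of))}
        truth.colour_of = colour_of
    truth.trait_class_means = class_means

    rng = np.random.default_rng(rng_seed)
    acc = sorted(colour_of)
    rows = np.empty((len(acc), class_means.shape[1]))
    for i, a in enumerate(acc):
        mu = class_means.loc[colour_of[a]].to_numpy(dtype=float)
        rows[i] = rng.multivariate_normal(mu, class_cov, method="cholesky") \
            if eig.min() > 1e-10 else rng.multivariate_normal(mu, class_cov)
    tt = pd.DataFrame(rows, index=pd.Index(acc, name="accession_id"),
                      columns=list(class_means.columns))
    tt.insert(0, "colour_class", [colour_of[a] for a in acc])
    return tt


# ------------------------------------------------------------------- Rc indel
def simulate_indel_calls(
    truth: SyntheticTruth, concordance: float = 1.0, rng_seed: int = 0
) -> pd.DataFrame:
    """Simulate binary calls for the 14-bp Rc deletion.

    The deletion abolishes red pigmentation, so under perfect concordance
    white accessions score 0 (deletion present) and pigmented accessions
    score 1.  With ``concordance < 1`` each accession independently flips to
    the discordant state with probability ``1 - concordance``; the realised
    discordant set is recorded in ``truth.discordant_indel_accessions``.
    """
    if not (0.0 <= concordance <= 1.0):
        raise ValueError("concordance must lie in [0, 1]")
    if not truth.colour_of:
        raise ValueError("truth carries no colour classes; simulate traits first "
                         "or set truth.colour_of")
    rng = np.random.default_rng(rng_seed)
    acc = sorted(truth.colour_of)
    concordant = rng.random(len(acc)) < concordance
    scores, discordant = [], []
    for a, ok in zip(acc, concordant):
        white = truth.colour_of[a] == "white"
        has_deletion = white if ok else not white
        scores.append(0 if has_deletion else 1)
        if not ok:
            discordant.append(a)
    truth.discordant_indel_accessions = discordant
    return pd.DataFrame({"rc_score": scores},
                        index=pd.Index(acc, name="accession_id"))
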