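# Methods

This note documents the statistical models behind `pigdiv`, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical conventions that pin down otherwise ambiguous
choices.

## Genotype model and containers

Genotypes are diploid biallelic SNP calls stored as a dosage matrix
(0 = homozygous reference, 1 = heterozygous, 2 = homozygous alternate,
−1 = missing), with a marker map sorted by (chromosome, position) and an
optional passport table per accession.  Polyploid and multiallelic data are
out of scope; a HapMap marker showing more than two alleles is dropped on
read with a warning.  When a HapMap `alleles` column does not name two
distinct nucleotides, alleles are inferred from the observed calls with the
major allele as reference.

## Synthetic panels

The generator states the world the estimators are tested against:

* **Structure — Balding–Nichols.**  Per locus an ancestral frequency `p0`
  is drawn uniformly (default range 0.1–0.5); each group's frequency is
  `Beta(p0(1−F)/F, (1−p0)(1−F)/F)`, whose variance is `F·p0(1−p0)`.  The
  divergence `F` of this model is exactly the coancestry parameter the
  Weir–Cockerham estimator targets, so FST recovery is a quantitative test
  with a known truth.  `F = 0` short-circuits to the shared ancestral
  frequency (no Beta draw); `F ≥ 1` is rejected.
* **Inbreeding — explicit selfing.**  Genotypes start at Hardy–Weinberg
  proportions; each selfing round resolves a heterozygote to 1/4 AA, 1/2
  Aa, 1/4 aa, halving heterozygosity, so after `t` rounds
  `FIS = 1 − (1/2)^t` in expectation.  The default `t = 4` (FIS 0.9375)
  matches the near-complete inbreeding of rice landrace collections
  (observed FIS ≈ 0.9–0.95).  Selfing rounds rather than an
  FIS-parameterised genotype draw were chosen because they mirror the
  biology and give a closed-form expectation to test against.
* **Redundancy.**  `n_duplicates` accessions are appended as exact copies
  of originals drawn *with* replacement (so clusters larger than two
  occur), **before** missingness is applied — duplicate pairs can therefore
  disagree at missing calls, deliberately stressing the PI threshold.
* **Missingness** is i.i.d. (default 5%); a per-sample multiplier exists to
  plant accessions that fail the 0.95 sample call-rate filter.  There is no
  simulated LD beyond what structure and finite sampling induce, and no
  recombination/coalescent model: a green LD-pruning test shows the pruning
  rule is implemented correctly, not that the generator has realistic
  haplotype structure.
* **Defaults** (1536 markers over 12 chromosomes, two subspecies groups at
  `F = 0.5`) emulate the scale and the deep indica/japonica split of a rice
  array panel.  Two groups each at divergence `F` from the common ancestor
  give a pairwise Weir–Cockerham θ that converges to `F`.

Seed traits are multivariate normal per colour class.  The default
covariance comes from a two-factor model (a colour-appearance factor
loading on lightness/intensity/saturation/b\*/a\*/−hue, and a geometry
factor on area/length/width/−roundness), which is PSD by construction and
induces the hallmark correlations of multi-spectral rice imaging:
intensity–lightness ≈ 0.99, strongly negative roundness–width, negative
hue–a\*.  Default class means put red highest and purple lowest on
lightness, a\* and intensity.  Trait SDs make hue the least and saturation
the most dispersed colour trait.  These means/SDs are plausibility-based
(no published per-class values exist to fit) and are fixed once.  Rc indel
calls are binary (0 = 14-bp deletion present): white accessions carry the
deletion with probability `concordance`, pigmented ones with
`1 − concordance`, and the realised discordant set is recorded as truth.

## QC

Filter order is sample call rate → marker call rate → MAF → LD pruning,
following the narrative order of a typical array QC; the order matters
(MAF after sample removal differs from before) and is recorded in the
report.  Filters are idempotent and raise rather than silently returning an
empty panel.

**Composite LD.**  The windowed pruning r² is the squared Pearson
correlation of dosage vectors over jointly-called samples ("composite" /
Burrows-type genotypic disequilibrium normalised to an r² analogue).
Haplotype r² is ill-posed for unphased, highly inbred panels; the exact
formula used by commercial tools is unpublished, so this definition is
declared here and pinned by tests, not claimed identical.  Within each
sliding window markers are scanned in map order and a marker is removed
when its r² with any *retained upstream* marker exceeds the threshold
(downstream-of-the-pair removal): deterministic, order-independent given a
sorted map, and identical to all-pairs pruning when the window covers the
panel.  Monomorphic pairs count r² = 0.

## Relatedness and the core collection

IBS distance is `mean over co-called loci of |d_i − d_j|/2`; a pair with no
co-called loci is `nan` (undefined, never 0).  "Estimated PI" is the
PLINK-style method-of-moments PI-HAT: per-locus IBS-class probabilities
conditional on IBD state are computed from panel-wide allele frequencies
(full post-QC panel, not per group — deterministic and matching a
single-cohort run), accumulated over each pair's co-called loci, and
(k0, k1, k2) solved in sequence from the observed IBS counts.  Bounding
follows the MoM convention: a coefficient above 1 pins the pair to that
pure IBD state (in an inbred panel the HWE-based expectation of opposite
homozygotes is exceeded for *unrelated* pairs, driving k0 > 1 and hence
PI → 0, which is the desired behaviour); negatives are floored and the
triple renormalised.  `PI = k2 + k1/2`: 1 for duplicates, ≈ 0.5 for full
sibs, ≈ 0.25 for half sibs.

Duplicates are the single-linkage transitive closure of pairs with
`PI ≥ 0.99`.  The threshold defaults to 0.99 rather than a literal 1
because missing calls and genotyping error make exact unity fragile; it is
a parameter, so 1.0 is reproducible.  The representative of each cluster is
the member with the highest call rate, ties broken by lexicographically
smallest accession id — the choice is a convention (no published rule
exists) but is deterministic and permutation-invariant.

## Diversity

* `He_raw = 2p(1−p)`, `He_unbiased = He_raw · 2n/(2n−1)` (Nei); both are
  emitted because common software defaults differ by exactly this flag.
* Allelic richness uses hypergeometric rarefaction to `2g` allele copies,
  `Ar = Σ_alleles [1 − C(2n−count, 2g)/C(2n, 2g)]`, with `g` defaulting to
  the smallest per-locus genotyped count across groups so groups of unequal
  size are comparable.
* Multilocus `FIS = 1 − mean(Ho)/mean(He_unbiased)` — ratio of averages,
  not average of ratios, which is the standard stabilisation when per-locus
  He is tiny.  The bootstrap resamples **loci** (the CI of a multilocus
  ratio statistic), 1000 replicates, percentile interval, seeded.
* The per-group allele total `A` counts 2 for a polymorphic and 1 for a
  monomorphic locus; the `%` column is `A/(2·n_loci)·100` — the wording of
  this statistic is ambiguous in the field's tables, so the definition is
  fixed here.

## Differentiation

**Weir–Cockerham θ (1984).**  Per-locus components for `r` populations:

    a = (n̄/nc)[s² − (p̄(1−p̄) − ((r−1)/r)s² − h̄/4)/(n̄−1)]
    b = (n̄/(n̄−1))[p̄(1−p̄) − ((r−1)/r)s² − ((2n̄−1)/(4n̄))h̄]
    c = h̄/2

with sample-size-weighted means and `nc` the usual unequal-sample
correction; multilocus `θ = Σa/Σ(a+b+c)`.  Loci with any group under 2
genotyped samples, or an undefined denominator, are skipped and counted.
θ is *not* clamped: slightly negative estimates are informative (they mean
"no detectable differentiation") and moment estimators are shown raw.

**AMOVA.**  Distance-based three-stratum decomposition on allele copies:
each diploid accession contributes two copies per locus (an unphased het
contributes one of each allele, i.e. within-accession SS = 0.5 per het
call), which is equivalent to squared allele-count differences and makes
the within-accession stratum well-defined for unphased diploids.  Missing
calls are mean-imputed per locus and contribute no within-accession
variance.  df are `(G−1, N−G, N, 2N−1)` — the within-accession df of `N`
is what the diploid copy level implies, and is the choice pinned by the
df identities of published AMOVA tables.  Variance components come from
expected mean squares with `n0 = (N − Σn_g²/N)/(G−1)`; negative components
are retained and flagged.  Permutation p-values (accession labels shuffled
across groups) are available but off by default.

## Structure

The relationship matrix is VanRaden's `A = ZZᵀ/2Σp(1−p)` with dosages
centred by `2p` and missing calls imputed to the locus mean.  PCA scores
are `eigenvector·√eigenvalue`; small negative eigenvalues (from
imputation) are floored at zero for the variance percentages and logged.
Projection of new samples uses the *reference* panel's frequencies and the
marker-space loadings `W = Zᵀ U Λ^{−1/2}/c`, so projecting the reference
onto itself reproduces its scores to numerical precision (tested at
1e−8).

NJ is the classical Saitou–Nei agglomeration.  Q-matrix ties are broken by
the smallest index pair, making the tree deterministic; branch lengths are
not clamped at zero so tree-additive metrics are recovered exactly
(property-tested against random additive trees, and cross-checked against
an independent NJ implementation).  Bootstrap supports resample loci with
replacement, rebuild the tree from recomputed IBS distances and count
bipartition recovery; 100 replicates by default (no published count to
follow — flag-controlled).

## Fingerprinting

Accessions are compared only at markers where **both** calls are
homozygous; het and missing calls are wildcards (the alternative — het as
a third profile state — would let genotyping noise fake distinctions).
Fitness of a subset is the number of accessions distinguished from all
others.  Pairs no subset can resolve (e.g. exact duplicates, highly
heterozygous accessions) are reported with their IBS distance and checked
against the 0.05-IBS rule as a post-hoc identifiability criterion, not a
GA constraint.

The GA encodes an individual as a fixed-length vector of `k` distinct
marker indices.  PMX (which presumes an ordered representation) is adapted
with a repair step that replaces residual duplicate indices by random
unused markers, preserving set semantics.  Survival is elitist truncation
to the top 30%, refilled by crossover among survivors at rate 0.35, no
mutation — the simplest faithful reading of a "survival rate".  Stopping:
full identification, `max_generations`, or 20 stagnant generations
(configurable).  Same seed + config ⇒ identical panel.  Exhaustive search
(≤ 10⁶ subsets, lexicographic tie-break) certifies optimality on small
instances; greedy forward selection gives a fast coverage bound.  Whether
fitness should count uniquely identified accessions or distinguished pairs
is resolved as the former; the pair-count matrix is available as a
diagnostic.

## Phenotype statistics

`describe_traits` reports min/max/range/median/variance/SD/CV (SD/mean)
with a Shapiro–Wilk flag at α = 0.05 (skipped for constant traits).
Correlations are Pearson with two-sided p on pairwise-complete
observations; zero-variance traits yield `nan`.  Trait PCA standardizes to
unit variance first and drops constant traits with a warning.

The gated one-way ANOVA tests each trait across colour classes: residual
normality by Shapiro–Wilk, homoscedasticity by Bartlett at α = 0.05.  On
Bartlett failure the trait is transformed (natural log by default — the
variance-stabilising transform is otherwise unspecified in practice —
Box–Cox as an option, both shifted when the minimum is ≤ 0) and retested;
a trait still heterogeneous is marked *precluded* and excluded from Tukey
testing rather than reported with invalid intervals.  Tukey HSD uses the
studentized range on the analysis scale.  Classes with one member are
dropped with a warning.  The pipeline's empirical type-I error is checked
at 2000 null simulations of an unbalanced 5-class design.

Ambiguous Rc profiles (more than one band) are excluded from the cross-tab
percentages and counted separately, since there is no defensible way to
fold them into either score class.

## Known limitations

* PI-HAT assumes HWE allele-frequency expectations; in highly inbred
  panels intermediate relatedness tiers (sib/half-sib) are not calibrated —
  only the duplicate end (PI → 1) and the unrelated end are used here.
* AMOVA mean-imputation slightly shrinks within-accession variance when
  missingness is high.
* The GA provides no optimality guarantee beyond the tested regime; on
  paper-scale panels its answer is a lower bound certified only by the
  greedy/exhaustive oracles at reduced size.
* Synthetic panels have no linkage disequilibrium beyond structure-induced
  correlation, no genotyping error model, and no real passport geography.
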