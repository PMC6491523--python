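"""Panel I/O and quality control.

Readers/writers for HapMap text, a plain dosage-CSV dialect (with marker-map
and passport sidecars) and biallelic VCF, plus the QC stages applied to array
genotypes before any diversity analysis: marker call-rate and MAF filters,
sample call-rate filter, and windowed LD pruning on a composite (genotypic,
unphased) r-squared.

The composite r-squared is the squared Pearson correlation of dosage vectors
over jointly-called samples.  Haplotype-based r2 is ill-posed for a highly
inbred, unphased panel; the dosage correlation is the standard composite
surrogate and is pinned by tests rather than claimed identical to any
commercial tool's variant.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .panel import MISSING, MAP_COLUMNS, GenotypeMatrix

HAPMAP_META = [
    "rs#", "alleles", "chrom", "pos", "strand", "assembly#",
    "center", "protLSID", "assayLSID", "panelLSID", "QCcode",
]
_MISSING_CALLS = {"NN", "--", "N", "-"}


@dataclass
class QCReport:
    """Record of what each QC stage removed, and the thresholds used."""

    samples_removed: list[str] = field(default_factory=list)
    markers_removed_by_callrate: list[str] = field(default_factory=list)
    markers_removed_by_maf: list[str] = field(default_factory=list)
    markers_removed_by_ld: list[str] = field(default_factory=list)
    thresholds: dict = field(default_factory=dict)

    def merged(self, other: "QCReport") -> "QCReport":
        return QCReport(
            samples_removed=self.samples_removed + other.samples_removed,
            markers_removed_by_callrate=self.markers_removed_by_callrate
            + other.markers_removed_by_callrate,
            markers_removed_by_maf=self.markers_removed_by_maf + other.markers_removed_by_maf,
            markers_removed_by_ld=self.markers_removed_by_ld + other.markers_removed_by_ld,
            thresholds={**self.thresholds, **other.thresholds},
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2))


# --------------------------------------------------------------------- HapMap
def read_hapmap(path: str | Path) -> GenotypeMatrix:
    """Read a tab-separated HapMap genotype file.

    Diploid genotype strings (``AA``, ``AG``, ``NN``, ...) are mapped to
    dosages using the marker's allele pair.  When the ``alleles`` column does
    not name two distinct nucleotides, alleles are inferred from the observed
    calls with the major allele taken as reference.  Markers showing more than
    two alleles are dropped with a warning; malformed rows raise with the
    offending line number.
    """
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < len(HAPMAP_META) + 1:
            raise ValueError(f"{path}: malformed HapMap header")
        sample_ids = header[len(HAPMAP_META):]
        marker_ids: list[str] = []
        rows: list[np.ndarray] = []
        map_rows: list[tuple] = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(HAPMAP_META) + len(sample_ids):
                raise ValueError(f"{path}: line {lineno}: expected "
                                 f"{len(HAPMAP_META) + len(sample_ids)} fields, got {len(parts)}")
            rs, alleles, chrom, pos = parts[0], parts[1], parts[2], parts[3]
            calls = parts[len(HAPMAP_META):]
            observed = sorted({a for c in calls if c not in _MISSING_CALLS for a in c})
            if len(observed) > 2:
                warnings.warn(f"{path}: marker {rs} has >2 alleles, dropped")
                continue
            declared = [a for a in alleles.split("/") if a in "ACGT"]
            if len(declared) == 2 and declared[0] != declared[1]:
                ref, alt = declared
            else:
                # infer: major allele (by count) = ref; ties broken alphabetically
                counts: dict[str, int] = {}
                for c in calls:
                    if c not in _MISSING_CALLS:
                        for a in c:
                            counts[a] = counts.get(a, 0) + 1
                ranked = sorted(counts, key=lambda a: (-counts[a], a))
                if not ranked:
                    ref, alt = "N", "N"
                elif len(ranked) == 1:
                    ref, alt = ranked[0], "N"
                else:
                    ref, alt = ranked[0], ranked[1]
            dose = np.full(len(calls), MISSING, dtype=np.int8)
            for i, call in enumerate(calls):
                if call in _MISSING_CALLS:
                    continue
                if len(call) != 2:
                    raise ValueError(f"{path}: line {lineno}: bad genotype {call!r}")
                dose[i] = (call[0] == alt) + (call[1] == alt)
            marker_ids.append(rs)
            rows.append(dose)
            try:
                map_rows.append((chrom, int(pos), ref, alt))
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: bad position {pos!r}") from exc
    marker_map = pd.DataFrame(map_rows, columns=MAP_COLUMNS,
                              index=pd.Index(marker_ids, name="marker_id"))
    dosage = np.vstack(rows).T if rows else np.zeros((len(sample_ids), 0), dtype=np.int8)
    order = marker_map.sort_values(["chromosome", "position"], kind="stable").index
    gm = GenotypeMatrix(sample_ids, marker_ids, dosage, marker_map)
    return gm.take_markers(order) if list(order) != marker_ids else gm


def write_hapmap(gm: GenotypeMatrix, path: str | Path) -> None:
    """Write the panel as HapMap text (inverse of :func:`read_hapmap`)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("\t".join(HAPMAP_META + gm.accession_ids) + "\n")
        for j, mid in enumerate(gm.marker_ids):
            row = gm.marker_map.iloc[j]
            ref, alt = row["ref_allele"], row["alt_allele"]
            code = {0: ref + ref, 1: ref + alt, 2: alt + alt, MISSING: "NN"}
            meta = [mid, f"{ref}/{alt}", str(row["chromosome"]), str(row["position"]),
                    "+", "NA", "NA", "NA", "NA", "NA", "NA"]
            fh.write("\t".join(meta + [code[int(d)] for d in gm.dosage[:, j]]) + "\n")


# ------------------------------------------------------------------ CSV dialect
def write_csv(gm: GenotypeMatrix, prefix: str | Path) -> None:
    """Write dosage CSV plus ``.markers.csv`` / ``.passport.csv`` sidecars.

    One row per accession, one column per marker, dosage integers with ``NA``
    for missing calls — trivially diffable fixtures.
    """
    prefix = Path(prefix)
    df = pd.DataFrame(gm.dosage, index=gm.accession_ids, columns=gm.marker_ids, dtype="object")
    df = df.mask(df == MISSING, "NA")
    df.index.name = "accession_id"
    df.to_csv(prefix.with_suffix(".genotypes.csv"))
    gm.marker_map.to_csv(prefix.with_suffix(".markers.csv"))
    gm.passport.to_csv(prefix.with_suffix(".passport.csv"))


def read_csv(prefix: str | Path) -> GenotypeMatrix:
    """Read the dosage-CSV dialect written by :func:`write_csv`."""
    prefix = Path(prefix)
    df = pd.read_csv(prefix.with_suffix(".genotypes.csv"), index_col=0)
    marker_map = pd.read_csv(prefix.with_suffix(".markers.csv"), index_col=0)
    marker_map.index = marker_map.index.astype(str)
    marker_map.index.name = "marker_id"
    passport_path = prefix.with_suffix(".passport.csv")
    passport = None
    if passport_path.exists():
        passport = pd.read_csv(passport_path, index_col=0)
        passport.index = passport.index.astype(str)
    dosage = df.to_numpy(dtype=float)
    dosage = np.where(np.isnan(dosage), MISSING, dosage).astype(np.int8)
    return GenotypeMatrix(list(df.index.astype(str)), [str(c) for c in df.columns],
                          dosage, marker_map, passport)


# ------------------------------------------------------------------------- VCF
def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read biallelic SNP records from a VCF (GT field only)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    marker_ids, map_rows, rows = [], [], []
    for i, rec in enumerate(vcf):
        if len(rec.ALT) != 1:
            warnings.warn(f"{path}: non-biallelic record at {rec.CHROM}:{rec.POS} skipped")
            continue
        gts = rec.genotype.array()[:, :2]
        dose = np.where((gts < 0).any(axis=1), MISSING, gts.clip(0).sum(axis=1))
        marker_ids.append(rec.ID or f"{rec.CHROM}_{rec.POS}")
        map_rows.append((rec.CHROM, rec.POS, rec.REF, rec.ALT[0]))
        rows.append(dose.astype(np.int8))
    marker_map = pd.DataFrame(map_rows, columns=MAP_COLUMNS,
                              index=pd.Index(marker_ids, name="marker_id"))
    return GenotypeMatrix(sample_ids, marker_ids, np.vstack(rows).T, marker_map)


# ---------------------------------------------------------------------- filters
def filter_markers(
    gm: GenotypeMatrix, min_call_rate: float = 0.95, min_maf: float = 0.05
) -> tuple[GenotypeMatrix, QCReport]:
    """Drop markers with call rate < ``min_call_rate``, then MAF < ``min_maf``.

    The call-rate filter is applied first; MAF is computed from allele counts
    on the survivors, ignoring missing calls.  Raises if nothing survives.
    """
    if gm.n_markers == 0:
        raise ValueError("empty panel")
    ids = np.asarray(gm.marker_ids)
    low_cr = gm.marker_call_rate() < min_call_rate
    gm2 = gm.take_markers(ids[~low_cr])
    low_maf = gm2.minor_allele_frequency() < min_maf
    out = gm2.take_markers(np.asarray(gm2.marker_ids)[~low_maf])
    if out.n_markers == 0:
        raise ValueError("all markers removed by QC filters")
    report = QCReport(
        markers_removed_by_callrate=list(ids[low_cr]),
        markers_removed_by_maf=list(np.asarray(gm2.marker_ids)[low_maf]),
        thresholds={"marker_min_call_rate": min_call_rate, "min_maf": min_maf},
    )
    return out, report


def filter_samples(
    gm: GenotypeMatrix, min_call_rate: float = 0.95
) -> tuple[GenotypeMatrix, QCReport]:
    """Drop accessions whose genotype call rate is below ``min_call_rate``."""
    if gm.n_accessions == 0:
        raise ValueError("empty panel")
    low = gm.sample_call_rate() < min_call_rate
    ids = np.asarray(gm.accession_ids)
    out = gm.take_accessions(ids[~low])
    if out.n_accessions == 0:
        raise ValueError("all samples removed by call-rate filter")
    report = QCReport(samples_removed=list(ids[low]),
                      thresholds={"sample_min_call_rate": min_call_rate})
    return out, report


# -------------------------------------------------------------------- LD prune
def composite_r2(gm: GenotypeMatrix, idx: np.ndarray | None = None) -> np.ndarray:
    """Composite LD r2 matrix: squared dosage correlation on co-called samples.

    Pairwise-complete — each pair uses only samples called at both markers.
    Monomorphic pairs yield r2 = 0.
    """
    X = gm.dosage.astype(float)
    if idx is not None:
        X = X[:, idx]
    M = (X != MISSING).astype(float)
    Xz = np.where(M > 0, X, 0.0)
    n = M.T @ M
    sx = Xz.T @ M          # sum of x over jointly called samples (rows = x marker)
    sxx = (Xz * Xz).T @ M
    sxy = Xz.T @ Xz
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = sx / n
        cov = sxy / n - mean * mean.T
        var = sxx / n - mean**2
        r2 = cov**2 / (var * var.T)
    r2 = np.where(np.isfinite(r2), r2, 0.0)
    np.fill_diagonal(r2, 1.0)
    return r2


def ld_prune(
    gm: GenotypeMatrix,
    window: int = 2921,
    increment: int = 5,
    r2_threshold: float = 0.8,
) -> tuple[GenotypeMatrix, QCReport]:
    """Windowed LD pruning on composite r2.

    Within each sliding window of ``window`` markers (advanced by
    ``increment``), markers are scanned in map order and a marker is removed
    when its r2 with any retained upstream marker in the window exceeds the
    threshold — i.e. the downstream member of an offending pair is dropped.
    Windows are re-scanned until no retained within-window pair exceeds the
    threshold, which makes the result identical to all-pairs pruning when the
    window covers the panel.
    """
    if window < 2:
        raise ValueError("window must be >= 2 markers")
    if increment < 1:
        raise ValueError("increment must be >= 1")
    n = gm.n_markers
    keep = np.ones(n, dtype=bool)
    changed = True
    while changed:
        changed = False
        starts = range(0, max(n - 1, 1), increment) if window < n else [0]
        for start in starts:
            win = np.nonzero(keep[start:start + window])[0] + start
            if win.size < 2:
                continue
            r2 = composite_r2(gm, win)
            # greedy keep-first scan in map order
            kept_local: list[int] = []
            for a in range(win.size):
                if any(r2[a, b] > r2_threshold for b in kept_local):
                    keep[win[a]] = False
                    changed = True
                else:
                    kept_local.append(a)
    ids = np.asarray(gm.marker_ids)
    out = gm.take_markers(ids[keep])
    report = QCReport(markers_removed_by_ld=list(ids[~keep]),
                      thresholds={"ld_window": window, "ld_increment": increment,
                                  "ld_r2_threshold": r2_threshold})
    return out, report


def run_qc(
    gm: GenotypeMatrix,
    sample_min_call_rate: float = 0.95,
    marker_min_call_rate: float = 0.95,
    min_maf: float = 0.05,
    ld_window: int = 2921,
    ld_increment: int = 5,
    ld_r2_threshold: float = 0.8,
) -> tuple[GenotypeMatrix, QCReport]:
    """Full QC chain: sample call rate -> marker call rate -> MAF -> LD prune.

    The order matters (MAF after sample removal differs from before) and is
    recorded in the report thresholds.
    """
    gm1, r1 = filter_samples(gm, sample_min_call_rate)
    gm2, r2 = filter_markers(gm1, marker_min_call_rate, min_maf)
    gm3, r3 = ld_prune(gm2, ld_window, ld_increment, ld_r2_threshold)
    return gm3, r1.merged(r2).merged(r3)
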