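"""Core genotype-panel container.

A :class:`GenotypeMatrix` holds diploid biallelic SNP calls for a set of
genebank accessions as an accessions x markers dosage matrix (0 = homozygous
reference, 1 = heterozygous, 2 = homozygous alternate, ``MISSING`` = no call),
together with a marker map (chromosome, 1-based position, alleles) and an
optional passport table (region, colour class, country per accession).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

#: Sentinel for a missing genotype call in the dosage matrix.
MISSING: int = -1

MAP_COLUMNS = ["chromosome", "position", "ref_allele", "alt_allele"]


@dataclass
class GenotypeMatrix:
    """Accessions x markers dosage matrix with marker map and passport data.

    Parameters
    ----------
    accession_ids
        Unique accession identifiers (rows).
    marker_ids
        Unique marker identifiers (columns), sorted by map position.
    dosage
        Integer matrix of shape ``(n_accessions, n_markers)`` with values in
        ``{0, 1, 2, MISSING}``.
    marker_map
        DataFrame indexed by marker id with columns ``chromosome``,
        ``position`` (1-based), ``ref_allele``, ``alt_allele``.
    passport
        Optional DataFrame indexed by accession id; free-form columns such as
        ``region``, ``merged_region``, ``colour_class``, ``country``.
    """

    accession_ids: list[str]
    marker_ids: list[str]
    dosage: np.ndarray
    marker_map: pd.DataFrame
    passport: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.accession_ids = [str(a) for a in self.accession_ids]
        self.marker_ids = [str(m) for m in self.marker_ids]
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.dosage.shape != (len(self.accession_ids), len(self.marker_ids)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.accession_ids)} accessions x {len(self.marker_ids)} markers"
            )
        bad = ~np.isin(self.dosage, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("dosage values must be 0, 1, 2 or MISSING")
        if len(set(self.accession_ids)) != len(self.accession_ids):
            raise ValueError("accession ids must be unique")
        if len(set(self.marker_ids)) != len(self.marker_ids):
            raise ValueError("marker ids must be unique")
        self.marker_map = self.marker_map.loc[self.marker_ids]
        pos = self.marker_map[["chromosome", "position"]]
        if (pos["position"] < 1).any():
            raise ValueError("marker positions must be >= 1")
        order = pos.sort_values(["chromosome", "position"], kind="stable").index
        if list(order) != self.marker_ids:
            raise ValueError("markers must be sorted by (chromosome, position)")
        if self.passport is None:
            self.passport = pd.DataFrame(index=pd.Index(self.accession_ids, name="accession_id"))
        else:
            self.passport = self.passport.loc[self.accession_ids]

    # ------------------------------------------------------------------ shape
    @property
    def n_accessions(self) -> int:
        return len(self.accession_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    # ------------------------------------------------------------ basic stats
    def called(self) -> np.ndarray:
        """Boolean mask of non-missing calls."""
        return self.dosage != MISSING

    def marker_call_rate(self) -> np.ndarray:
        """Fraction of accessions called, per marker."""
        return self.called().mean(axis=0)

    def sample_call_rate(self) -> np.ndarray:
        """Fraction of markers called, per accession."""
        return self.called().mean(axis=1)

    def alt_allele_frequency(self) -> np.ndarray:
        """Alternate-allele frequency per marker on non-missing calls.

        Markers with no calls at all yield ``nan``.
        """
        called = self.called()
        dose = np.where(called, self.dosage, 0).astype(float)
        n = called.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n > 0, dose.sum(axis=0) / (2.0 * n), np.nan)

    def minor_allele_frequency(self) -> np.ndarray:
        p = self.alt_allele_frequency()
        return np.minimum(p, 1.0 - p)

    # -------------------------------------------------------------- subsetting
    def take_markers(self, keep: Sequence[str] | np.ndarray) -> "GenotypeMatrix":
        """Return a panel restricted to the given marker ids (map order kept)."""
        keep_set = set(map(str, keep))
        idx = [i for i, m in enumerate(self.marker_ids) if m in keep_set]
        return GenotypeMatrix(
            accession_ids=list(self.accession_ids),
            marker_ids=[self.marker_ids[i] for i in idx],
            dosage=self.dosage[:, idx],
            marker_map=self.marker_map.iloc[idx],
            passport=self.passport,
        )

    def take_accessions(self, keep: Sequence[str]) -> "GenotypeMatrix":
        """Return a panel restricted to the given accession ids (input order kept)."""
        keep_set = set(map(str, keep))
        idx = [i for i, a in enumerate(self.accession_ids) if a in keep_set]
        return GenotypeMatrix(
            accession_ids=[self.accession_ids[i] for i in idx],
            marker_ids=list(self.marker_ids),
            dosage=self.dosage[idx],
            marker_map=self.marker_map,
            passport=self.passport.iloc[idx],
        )

    def group_labels(self, column: str) -> np.ndarray:
        """Per-accession labels from a passport column, in panel row order."""
        if column not in self.passport.columns:
            raise KeyError(f"passport has no column {column!r}")
        return self.passport[column].to_numpy()

    def __eq__(self, other: object) -> bool:  # value equality, used in round-trip tests
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.accession_ids == other.accession_ids
            and self.marker_ids == other.marker_ids
            and np.array_equal(self.dosage, other.dosage)
            and self.marker_map[MAP_COLUMNS].equals(other.marker_map[MAP_COLUMNS])
        )
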