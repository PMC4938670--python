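"""Core genotype container shared by every pipeline stage.

A :class:`GenotypeMatrix` holds biallelic SNP calls for a pedigreed
population: a marker table, an individual table carrying the pedigree
(sire, dam, sex), and an ``individuals x markers`` call matrix coded as
0 = hom-ref, 1 = het, 2 = hom-alt, -1 = missing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

MISSING = -1

#: column order expected in a pedigree table
PED_COLUMNS = ("id", "sire", "dam", "sex")


@dataclass
class Family:
    """One nuclear family: indices into the individual table."""

    sire: int
    dam: int
    offspring: np.ndarray  # row indices of the full sibs


@dataclass
class GenotypeMatrix:
    markers: pd.DataFrame        # index marker_id; columns: chrom, pos, ref, alt
    individuals: pd.DataFrame    # index ind_id; columns: sire, dam, sex, role
    calls: np.ndarray            # int8, shape (n_individuals, n_markers)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.individuals), len(self.markers)):
            raise ValueError(
                f"call matrix shape {self.calls.shape} does not match "
                f"{len(self.individuals)} individuals x {len(self.markers)} markers"
            )
        ind = set(self.individuals.index)
        off = self.offspring_mask()
        for col in ("sire", "dam"):
            parents = self.individuals.loc[off, col]
            missing = parents[~parents.isin(ind)]
            if len(missing):
                raise ValueError(
                    f"offspring {missing.index[0]!r} has {col} "
                    f"{missing.iloc[0]!r} absent from the individual table"
                )

    # -- basic views ------------------------------------------------------

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    def offspring_mask(self) -> np.ndarray:
        """Boolean mask of individuals that have both parents recorded."""
        return (
            self.individuals["sire"].notna() & (self.individuals["sire"] != "0")
        ).to_numpy() & (
            self.individuals["dam"].notna() & (self.individuals["dam"] != "0")
        ).to_numpy()

    def marker_index(self, marker_ids) -> np.ndarray:
        return self.markers.index.get_indexer(list(marker_ids))

    # -- pedigree ---------------------------------------------------------

    def families(self) -> list[Family]:
        """Nuclear families (unique sire x dam pairs with >=1 offspring)."""
        cached = getattr(self, "_families", None)
        if cached is not None:
            return cached
        row_of = {iid: k for k, iid in enumerate(self.individuals.index)}
        off = np.flatnonzero(self.offspring_mask())
        groups: dict[tuple[str, str], list[int]] = {}
        for k in off:
            key = (self.individuals["sire"].iloc[k], self.individuals["dam"].iloc[k])
            groups.setdefault(key, []).append(k)
        fams = [
            Family(sire=row_of[s], dam=row_of[d], offspring=np.array(kids, dtype=np.intp))
            for (s, d), kids in groups.items()
        ]
        self._families = fams
        return fams

    # -- subsetting -------------------------------------------------------

    def subset(self, marker_ids=None, individual_ids=None) -> "GenotypeMatrix":
        mk = self.markers if marker_ids is None else self.markers.loc[list(marker_ids)]
        iv = (
            self.individuals
            if individual_ids is None
            else self.individuals.loc[list(individual_ids)]
        )
        rows = self.individuals.index.get_indexer(iv.index)
        cols = self.markers.index.get_indexer(mk.index)
        return GenotypeMatrix(mk.copy(), iv.copy(), self.calls[np.ix_(rows, cols)].copy())

    def allele_frequencies(self) -> np.ndarray:
        """Alt-allele frequency per marker over all non-missing calls."""
        valid = self.calls >= 0
        alt = np.where(valid, self.calls, 0).sum(axis=0)
        n = valid.sum(axis=0)
        with np.errstate(invalid="ignore"):
            return np.where(n > 0, alt / (2.0 * n), np.nan)

    def minor_allele_frequencies(self) -> np.ndarray:
        p = self.allele_frequencies()
        return np.minimum(p, 1.0 - p)


def make_individual_table(records) -> pd.DataFrame:
    """Build the individual table from ``(id, sire, dam, sex)`` records.

    Founders use ``"0"`` for unknown parents, mirroring the 4-column
    pedigree TSV convention.
    """
    df = pd.DataFrame(records, columns=list(PED_COLUMNS)).set_index("id")
    df["sire"] = df["sire"].astype(object)
    df["dam"] = df["dam"].astype(object)
    founder = (df["sire"] == "0") & (df["dam"] == "0")
    df["role"] = np.where(founder, "founder", "offspring")
    return df
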