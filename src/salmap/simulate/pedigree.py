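"""Multi-family pedigree layout with shared sires.

Nuclear families: each dam founds exactly one full-sib family; sires are
assigned round-robin so a sire may serve several dams, mirroring the
shared-sire structure of commercial salmon breeding designs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..genotypes import make_individual_table


@dataclass
class PedigreeSpec:
    sires: int = 10
    dams: int = 20
    offspring_per_family: int = 8
    #: dam index -> sire index; default round-robin
    sire_of_dam: list[int] = field(default_factory=list)

    def __post_init__(self):
        if self.offspring_per_family < 1:
            raise ValueError("offspring_per_family must be >= 1")
        if self.dams < self.sires:
            raise ValueError("need at least one dam per sire")
        if not self.sire_of_dam:
            self.sire_of_dam = [d % self.sires for d in range(self.dams)]
        if len(self.sire_of_dam) != self.dams or any(
            not 0 <= s < self.sires for s in self.sire_of_dam
        ):
            raise ValueError("sire_of_dam must map every dam to a valid sire")

    @property
    def n_families(self) -> int:
        return self.dams

    @property
    def n_offspring(self) -> int:
        return self.dams * self.offspring_per_family

    def sire_id(self, k: int) -> str:
        return f"S{k + 1:03d}"

    def dam_id(self, k: int) -> str:
        return f"D{k + 1:03d}"

    def individual_table(self, rng: np.random.Generator | None = None) -> pd.DataFrame:
        """4-column pedigree (id, sire, dam, sex) as an individual table."""
        rng = rng or np.random.default_rng(0)
        rows = [(self.sire_id(k), "0", "0", "M") for k in range(self.sires)]
        rows += [(self.dam_id(k), "0", "0", "F") for k in range(self.dams)]
        for d in range(self.dams):
            s = self.sire_of_dam[d]
            for j in range(self.offspring_per_family):
                rows.append(
                    (
                        f"F{d + 1:03d}_{j + 1:03d}",
                        self.sire_id(s),
                        self.dam_id(d),
                        "M" if rng.integers(2) else "F",
                    )
                )
        return make_individual_table(rows)
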