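"""Pre-mapping genotype QC: Mendelian-error exclusion, MAF filtering and
segregation-distortion removal.

A trio (offspring, sire, dam) at a marker is *checked* iff all three
calls are non-missing, and is an *error* iff the offspring genotype is
impossible under Mendelian transmission from the parental genotypes.
Rates are errors / checked.  Individuals are filtered before markers so
one bad sample cannot inflate many marker rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import GenotypeMatrix


def _legal_table() -> np.ndarray:
    """legal[gs, gd, go]: offspring genotype possible given parents,
    enumerated from transmissible alleles."""
    alleles = {0: (0,), 1: (0, 1), 2: (1,)}
    legal = np.zeros((3, 3, 3), dtype=bool)
    for gs in range(3):
        for gd in range(3):
            for a in alleles[gs]:
                for b in alleles[gd]:
                    legal[gs, gd, a + b] = True
    return legal


LEGAL = _legal_table()


@dataclass
class QCReport:
    marker_rates: pd.DataFrame | None = None       # mendel_rate, n_checked, no_data flag
    individual_rates: pd.DataFrame | None = None
    maf: pd.Series | None = None
    distortion: pd.DataFrame | None = None         # chi2, df, p, n_families
    removed_markers: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["reason"])
    )
    removed_individuals: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["reason"])
    )
    stage_counts: list[tuple[str, int, int]] = field(default_factory=list)

    def log(self, stage: str, n_markers: int, n_individuals: int) -> None:
        self.stage_counts.append((stage, n_markers, n_individuals))

    def drop_markers(self, ids, reason: str) -> None:
        add = pd.DataFrame({"reason": reason}, index=pd.Index(ids, name="marker_id"))
        self.removed_markers = pd.concat([self.removed_markers, add])

    def drop_individuals(self, ids, reason: str) -> None:
        add = pd.DataFrame({"reason": reason}, index=pd.Index(ids, name="id"))
        self.removed_individuals = pd.concat([self.removed_individuals, add])


def mendelian_error_rates(gm: GenotypeMatrix) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-marker and per-individual Mendelian error rates.

    Each trio error is attributed to the marker, the offspring and both
    parents.  Markers/individuals with zero checked trios get rate 0 and a
    ``no_data`` flag.
    """
    n_ind, n_mk = gm.calls.shape
    mk_err = np.zeros(n_mk)
    mk_chk = np.zeros(n_mk)
    ind_err = np.zeros(n_ind)
    ind_chk = np.zeros(n_ind)
    for fam in gm.families():
        gs, gd = gm.calls[fam.sire], gm.calls[fam.dam]
        go = gm.calls[fam.offspring]
        checked = (gs >= 0) & (gd >= 0) & (go >= 0)
        err = np.zeros_like(checked)
        c = checked
        err[c] = ~LEGAL[
            np.broadcast_to(gs, go.shape)[c],
            np.broadcast_to(gd, go.shape)[c],
            go[c],
        ]
        mk_err += err.sum(axis=0)
        mk_chk += checked.sum(axis=0)
        ind_err[fam.offspring] += err.sum(axis=1)
        ind_chk[fam.offspring] += checked.sum(axis=1)
        for p in (fam.sire, fam.dam):
            ind_err[p] += err.sum()
            ind_chk[p] += checked.sum()
    with np.errstate(invalid="ignore"):
        mk_rate = np.where(mk_chk > 0, mk_err / np.maximum(mk_chk, 1), 0.0)
        ind_rate = np.where(ind_chk > 0, ind_err / np.maximum(ind_chk, 1), 0.0)
    markers = pd.DataFrame(
        {
            "mendel_rate": mk_rate,
            "n_checked": mk_chk.astype(int),
            "no_data": mk_chk == 0,
        },
        index=gm.markers.index,
    )
    individuals = pd.DataFrame(
        {
            "mendel_rate": ind_rate,
            "n_checked": ind_chk.astype(int),
            "no_data": ind_chk == 0,
        },
        index=gm.individuals.index,
    )
    return markers, individuals


def filter_mendelian(
    gm: GenotypeMatrix, threshold: float = 0.01, report: QCReport | None = None
) -> tuple[GenotypeMatrix, QCReport]:
    """Remove individuals, then markers, with Mendelian error rate strictly
    above ``threshold``.

    Offspring above threshold are dropped individually; a parent above
    threshold removes the parent together with its nuclear families (the
    pedigree must stay resolvable).
    """
    report = report or QCReport()
    mk, ind = mendelian_error_rates(gm)
    report.marker_rates, report.individual_rates = mk, ind

    bad = set(ind.index[ind["mendel_rate"] > threshold])
    drop: set[str] = set()
    for iid in bad:
        drop.add(iid)
        if gm.individuals.loc[iid, "role"] == "founder":
            fam_members = gm.individuals.index[
                (gm.individuals["sire"] == iid) | (gm.individuals["dam"] == iid)
            ]
            drop.update(fam_members)
    keep_ind = [i for i in gm.individuals.index if i not in drop]
    if drop:
        report.drop_individuals(sorted(drop), "mendel_rate")
    gm = gm.subset(individual_ids=keep_ind)

    mk2, _ = mendelian_error_rates(gm)  # recompute after individual removal
    bad_mk = mk2.index[mk2["mendel_rate"] > threshold]
    if len(bad_mk):
        report.drop_markers(bad_mk, "mendel_rate")
    gm = gm.subset(marker_ids=[m for m in gm.markers.index if m not in set(bad_mk)])
    report.log("mendel", gm.n_markers, gm.n_individuals)
    return gm, report


def maf_filter(
    gm: GenotypeMatrix, maf_limit: float = 0.05, report: QCReport | None = None
) -> tuple[GenotypeMatrix, QCReport]:
    """Remove markers with minor allele frequency strictly below
    ``maf_limit`` (computed over all non-missing calls of all individuals).
    Monomorphic markers have MAF 0 and are removed."""
    report = report or QCReport()
    maf = pd.Series(gm.minor_allele_frequencies(), index=gm.markers.index, name="maf")
    report.maf = maf
    bad = maf.index[maf.fillna(0.0) < maf_limit]
    if len(bad):
        report.drop_markers(bad, "maf")
    gm = gm.subset(marker_ids=[m for m in gm.markers.index if m not in set(bad)])
    report.log("maf", gm.n_markers, gm.n_individuals)
    return gm, report


def segregation_distortion(
    gm: GenotypeMatrix, min_informative: int = 2
) -> pd.DataFrame:
    """Per-marker segregation-distortion test.

    Within each family where at least one parent is heterozygous, offspring
    genotype counts are tested against Mendelian expectations (1:1 for
    backcross-type matings, 1:2:1 for intercross-type); the per-marker
    statistic sums family chi-squares, df sums family df.  Families with
    fewer than ``min_informative`` non-missing offspring at the marker are
    skipped.
    """
    n_mk = gm.n_markers
    chi2 = np.zeros(n_mk)
    df = np.zeros(n_mk, dtype=int)
    n_fam = np.zeros(n_mk, dtype=int)
    for fam in gm.families():
        gs, gd = gm.calls[fam.sire], gm.calls[fam.dam]
        go = gm.calls[fam.offspring]
        valid = go >= 0
        n = valid.sum(axis=0)
        counts = np.stack([((go == g) & valid).sum(axis=0) for g in range(3)])

        hh = (gs == 1) & (gd == 1) & (n >= min_informative)  # intercross 1:2:1
        if hh.any():
            exp = np.stack([n[hh] * 0.25, n[hh] * 0.5, n[hh] * 0.25])
            chi2[hh] += (np.square(counts[:, hh] - exp) / exp).sum(axis=0)
            df[hh] += 2
            n_fam[hh] += 1

        for het_parent, hom_parent in ((gs, gd), (gd, gs)):
            # backcross 1:1 between het and the matching hom class
            for hom, classes in ((0, (0, 1)), (2, (1, 2))):
                bc = (
                    (het_parent == 1)
                    & (hom_parent == hom)
                    & (n >= min_informative)
                )
                if not bc.any():
                    continue
                obs = counts[list(classes)][:, bc]
                tot = obs.sum(axis=0)
                use = tot >= min_informative
                idx = np.flatnonzero(bc)[use]
                exp = tot[use] * 0.5
                chi2[idx] += (np.square(obs[:, use] - exp) / exp).sum(axis=0)
                df[idx] += 1
                n_fam[idx] += 1
    with np.errstate(invalid="ignore"):
        p = np.where(df > 0, stats.chi2.sf(chi2, np.maximum(df, 1)), 1.0)
    return pd.DataFrame(
        {"chi2": chi2, "df": df, "p": p, "n_families": n_fam}, index=gm.markers.index
    )


def distortion_filter(
    gm: GenotypeMatrix, tolerance: float = 0.001, report: QCReport | None = None
) -> tuple[GenotypeMatrix, QCReport]:
    """Remove markers whose pooled distortion p-value is below ``tolerance``."""
    report = report or QCReport()
    dist = segregation_distortion(gm)
    report.distortion = dist
    bad = dist.index[dist["p"] < tolerance]
    if len(bad):
        report.drop_markers(bad, "distortion")
    gm = gm.subset(marker_ids=[m for m in gm.markers.index if m not in set(bad)])
    report.log("distortion", gm.n_markers, gm.n_individuals)
    return gm, report


def run_qc(
    gm: GenotypeMatrix,
    mendel_threshold: float = 0.01,
    maf_limit: float = 0.05,
    distortion_tolerance: float = 0.001,
) -> tuple[GenotypeMatrix, QCReport]:
    """Full QC pipeline: Mendelian filter, MAF filter, distortion filter."""
    report = QCReport()
    report.log("input", gm.n_markers, gm.n_individuals)
    gm, report = filter_mendelian(gm, mendel_threshold, report)
    gm, report = maf_filter(gm, maf_limit, report)
    gm, report = distortion_filter(gm, distortion_tolerance, report)
    return gm, report
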