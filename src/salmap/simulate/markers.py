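"""Marker placement, founder haplotypes and pedigree genotype simulation.

Markers are placed uniformly at random along chromosome coordinates; a
marker whose site falls inside an excised span belongs to that unplaced
contig (its flank is read from the contig record) while its inheritance is
still simulated at its true chromosomal position.  Flanks are exact
71-mers centred on the SNP site.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..genotypes import GenotypeMatrix
from .crossovers import FEMALE, MALE, RecombinationLandscape, gamete, sample_crossovers
from .genome import BASES, N_CODE, SimulatedGenome, decode
from .pedigree import PedigreeSpec

FLANK = 35  # bases either side of the SNP site


@dataclass
class CrossoverRecord:
    offspring: str
    parent: str
    sex: str
    chrom: str
    positions: np.ndarray


@dataclass
class TruthSet:
    """Generation-time ground truth; read only by tests, never by pipeline stages."""

    markers: pd.DataFrame          # index marker_id: chrom, chrom_pos, record, record_pos,
    #                                ref, alt, alt_freq, cM_male, cM_female, [effect, gene]
    crossovers: list[CrossoverRecord] = field(default_factory=list)
    genetic_lengths: pd.DataFrame | None = None  # per chrom: male_cM, female_cM
    genes: object | None = None

    def order_on(self, chrom: str) -> list[str]:
        sub = self.markers[self.markers["chrom"] == chrom]
        return list(sub.sort_values("chrom_pos").index)

    def total_length(self, sex: str) -> float:
        col = "male_cM" if sex == MALE else "female_cM"
        return float(
            sum(
                self.markers[self.markers["chrom"] == c][col].max()
                - self.markers[self.markers["chrom"] == c][col].min()
                for c in self.markers["chrom"].unique()
            )
        )


def _valid_flank(seq: np.ndarray, pos: int) -> bool:
    if pos < FLANK or pos > len(seq) - FLANK - 1:
        return False
    window = seq[pos - FLANK : pos + FLANK + 1]
    return not (window == N_CODE).any()


def sample_marker_sites(
    genome: SimulatedGenome,
    n_markers: int,
    rng: np.random.Generator,
    include_contigs: bool = True,
) -> pd.DataFrame:
    """Uniform marker sites with full-length, N-free flanks.

    Returns a frame sorted by (chrom, chrom_pos) with the assembly record
    (chromosome or contig) each marker's flank is read from.
    """
    chroms = list(genome.chromosomes)
    lengths = np.array([len(genome.chromosomes[c]) for c in chroms], dtype=float)
    weights = lengths / lengths.sum()
    spans = {c: genome.contig_spans(c) for c in chroms}

    rows, seen = [], set()
    attempts = 0
    while len(rows) < n_markers:
        attempts += 1
        if attempts > 200 * n_markers:
            raise RuntimeError("unable to place the requested number of markers")
        ci = rng.choice(len(chroms), p=weights)
        chrom = chroms[ci]
        pos = int(rng.integers(0, lengths[ci]))
        if (chrom, pos) in seen:
            continue
        record, rpos = chrom, pos
        for s, e, name in spans[chrom]:
            if s <= pos < e:
                record, rpos = name, pos - s
                break
        if record != chrom and not include_contigs:
            continue
        if not _valid_flank(genome.record(record), rpos):
            continue
        seen.add((chrom, pos))
        rows.append((chrom, pos, record, rpos))

    df = pd.DataFrame(rows, columns=["chrom", "chrom_pos", "record", "record_pos"])
    df = df.sort_values(["chrom", "chrom_pos"]).reset_index(drop=True)
    ids = np.array([f"snp_{k + 1:05d}" for k in range(len(df))])
    df.index = pd.Index(ids[rng.permutation(len(df))], name="marker_id")
    return df


def extract_flanks(genome: SimulatedGenome, sites: pd.DataFrame) -> pd.DataFrame:
    """71-mer flank per marker (SNP at 0-based offset 35) from its record."""
    seqs = []
    for _, row in sites.iterrows():
        seq = genome.record(row["record"])
        p = int(row["record_pos"])
        seqs.append(decode(seq[p - FLANK : p + FLANK + 1]))
    return pd.DataFrame(
        {"flank": seqs, "snp_offset": FLANK}, index=sites.index.copy()
    )


def simulate_genotypes(
    genome: SimulatedGenome,
    landscape: RecombinationLandscape,
    pedigree: PedigreeSpec,
    n_markers: int = 2000,
    maf_distribution=(0.05, 0.5),
    genotyping_error_rate: float = 0.005,
    missing_rate: float = 0.01,
    seed: int = 0,
    include_contigs: bool = True,
) -> tuple[GenotypeMatrix, pd.DataFrame, TruthSet]:
    """Simulate pedigree genotypes at random marker sites.

    Founder genotypes are drawn from per-marker allele frequencies (MAF
    from ``maf_distribution``: a (lo, hi) uniform range, a fixed float, or
    a callable ``f(rng, n)``); offspring genotypes arise from simulated
    meioses under the sex-specific landscapes; genotyping errors flip the
    call to one of the other two states.
    """
    rng = np.random.default_rng(seed)
    sites = sample_marker_sites(genome, n_markers, rng, include_contigs)
    flanks = extract_flanks(genome, sites)

    # alleles: ref is the assembly base, alt a random different base
    refc = np.array(
        [genome.record(r)[p] for r, p in zip(sites["record"], sites["record_pos"])],
        dtype=np.uint8,
    )
    altc = (refc + rng.integers(1, 4, size=len(sites)).astype(np.uint8)) % 4
    if callable(maf_distribution):
        maf = np.asarray(maf_distribution(rng, len(sites)), dtype=float)
    elif np.isscalar(maf_distribution):
        maf = np.full(len(sites), float(maf_distribution))
    else:
        lo, hi = maf_distribution
        maf = rng.uniform(lo, hi, size=len(sites))
    alt_freq = np.where(rng.random(len(sites)) < 0.5, maf, 1.0 - maf)

    individuals = pedigree.individual_table(rng)
    founder_ids = [i for i in individuals.index if individuals.loc[i, "role"] == "founder"]
    n_ind = len(individuals)
    calls = np.zeros((n_ind, len(sites)), dtype=np.int8)
    row_of = {iid: k for k, iid in enumerate(individuals.index)}

    chrom_cols = {c: np.flatnonzero((sites["chrom"] == c).to_numpy()) for c in genome.chromosomes}
    chrom_bp = {c: sites["chrom_pos"].to_numpy()[cols] for c, cols in chrom_cols.items()}

    # phased founder haplotypes per chromosome
    haplotypes: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = {}
    for fid in founder_ids:
        for c, cols in chrom_cols.items():
            p = alt_freq[cols]
            haplotypes[(fid, c)] = (
                (rng.random(len(cols)) < p).astype(np.int8),
                (rng.random(len(cols)) < p).astype(np.int8),
            )
        calls[row_of[fid]] = np.concatenate(
            [haplotypes[(fid, c)][0] + haplotypes[(fid, c)][1] for c in chrom_cols]
        )[_restore_order(chrom_cols)]

    truth_xo: list[CrossoverRecord] = []
    for d in range(pedigree.dams):
        sire = pedigree.sire_id(pedigree.sire_of_dam[d])
        dam = pedigree.dam_id(d)
        for j in range(pedigree.offspring_per_family):
            off = f"F{d + 1:03d}_{j + 1:03d}"
            geno = np.zeros(len(sites), dtype=np.int8)
            for parent, sex in ((sire, MALE), (dam, FEMALE)):
                for c, cols in chrom_cols.items():
                    track = landscape.track(c, sex)
                    xo = sample_crossovers(track, rng)
                    al = gamete(
                        haplotypes[(parent, c)], chrom_bp[c], xo, int(rng.integers(2))
                    )
                    geno[cols] += al
                    truth_xo.append(CrossoverRecord(off, parent, sex, c, xo))
            calls[row_of[off]] = geno

    # genotyping error: symmetric flip to one of the other two states
    if genotyping_error_rate > 0:
        err = rng.random(calls.shape) < genotyping_error_rate
        shift = rng.integers(1, 3, size=calls.shape)
        calls = np.where(err, (calls + shift) % 3, calls).astype(np.int8)
    if missing_rate > 0:
        calls[rng.random(calls.shape) < missing_rate] = -1

    markers = pd.DataFrame(
        {
            "chrom": sites["record"],  # assembly record the marker is observed on
            "pos": sites["record_pos"],
            "ref": [chr(BASES[c]) for c in refc],
            "alt": [chr(BASES[c]) for c in altc],
        },
        index=sites.index.copy(),
    )
    gm = GenotypeMatrix(markers, individuals, calls)

    truth_markers = sites.copy()
    truth_markers["ref"] = markers["ref"]
    truth_markers["alt"] = markers["alt"]
    truth_markers["alt_freq"] = alt_freq
    truth_markers["cM_male"] = np.concatenate(
        [landscape.track(c, MALE).cum_cM(chrom_bp[c]) for c in chrom_cols]
    )[_restore_order(chrom_cols)]
    truth_markers["cM_female"] = np.concatenate(
        [landscape.track(c, FEMALE).cum_cM(chrom_bp[c]) for c in chrom_cols]
    )[_restore_order(chrom_cols)]
    lengths = pd.DataFrame(
        {
            "male_cM": {c: landscape.genetic_length(c, MALE) for c in genome.chromosomes},
            "female_cM": {c: landscape.genetic_length(c, FEMALE) for c in genome.chromosomes},
        }
    )
    truth = TruthSet(markers=truth_markers, crossovers=truth_xo, genetic_lengths=lengths)
    return gm, flanks, truth


def _restore_order(chrom_cols: dict[str, np.ndarray]) -> np.ndarray:
    """Inverse permutation mapping concatenated per-chromosome blocks back
    to the original marker order."""
    order = np.concatenate(list(chrom_cols.values()))
    inv = np.empty_like(order)
    inv[order] = np.arange(len(order))
    return inv
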