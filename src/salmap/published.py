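"""Published per-chromosome map characteristics of the Atlantic salmon
(Salmo salar) high-density SNP linkage map, and the printed annotation
counts, used as inputs for summary arithmetic.

Columns: SNPs per chromosome, physical length (Mb) of the assembly
(GCA_000233375.4), physical length (Mb) of previously unassigned contigs
anchored by the map, male and female map lengths (max cM) and the
cM-vs-bp correlations.
"""

from __future__ import annotations

import pandas as pd
from scipy import stats

_ROWS = [
    # chrom, snps, phys_mb, unassigned_mb, male_max, male_r, female_max, female_r
    (1, 6080, 159, 1.6, 428.8, 0.97, 551.3, 0.98),
    (2, 3506, 73, 3.1, 173.5, 0.80, 404.4, 0.85),
    (3, 4013, 93, 2.2, 332.2, 0.84, 467.7, 0.96),
    (4, 4173, 82, 1.1, 156.6, 0.82, 183.6, 0.95),
    (5, 3916, 81, 1.9, 274.4, 0.91, 529.9, 0.93),
    (6, 4073, 87, 2.3, 264.2, 0.88, 689.1, 0.89),
    (7, 2875, 59, 1.2, 183.7, 0.85, 249.0, 0.97),
    (8, 1128, 26, 0.6, 181.6, 0.87, 326.4, 0.97),
    (9, 4774, 142, 1.7, 278.8, 0.77, 392.2, 0.81),
    (10, 4146, 116, 0.9, 82.8, 0.79, 166.8, 0.97),
    (11, 3953, 94, 2.8, 166.2, 0.79, 291.0, 0.81),
    (12, 4321, 92, 2.6, 95.7, 0.80, 239.5, 0.80),
    (13, 4472, 108, 1.3, 178.0, 0.62, 213.8, 0.91),
    (14, 3878, 94, 1.4, 96.4, 0.73, 123.5, 0.92),
    (15, 4335, 104, 1.9, 77.3, 0.64, 136.9, 0.91),
    (16, 3316, 88, 2.3, 141.9, 0.80, 137.7, 0.90),
    (17, 2607, 58, 2.0, 171.2, 0.90, 307.2, 0.96),
    (18, 3196, 71, 1.4, 91.7, 0.85, 105.9, 0.92),
    (19, 3210, 83, 1.5, 74.5, 0.76, 103.2, 0.90),
    (20, 3687, 87, 1.5, 96.5, 0.82, 112.5, 0.93),
    (21, 2355, 58, 0.7, 93.2, 0.80, 159.1, 0.84),
    (22, 2634, 63, 0.4, 73.6, 0.74, 78.0, 0.88),
    (23, 2670, 50, 0.6, 77.5, 0.65, 84.4, 0.96),
    (24, 2538, 49, 0.3, 379.0, 0.91, 458.2, 0.97),
    (25, 2332, 51, 0.7, 147.0, 0.92, 175.3, 0.96),
    (26, 2063, 48, 2.2, 166.2, 0.92, 161.8, 0.95),
    (27, 2458, 44, 0.4, 73.3, 0.72, 72.6, 0.91),
    (28, 1878, 40, 0.7, 143.1, 0.94, 156.0, 0.99),
    (29, 1809, 42, 0.6, 70.2, 0.73, 76.4, 0.88),
]

MAP_TABLE = pd.DataFrame(
    _ROWS,
    columns=[
        "chrom", "snps", "phys_mb", "unassigned_mb",
        "male_max_cM", "male_r", "female_max_cM", "female_r",
    ],
).set_index("chrom")

#: Mb of assembly contigs not assigned to any chromosome
UNPLACED_TOTAL_MB = 647.0
#: Mb of assembly contigs anchored to chromosomes
ASSEMBLED_TOTAL_MB = 2240.0

# printed SNP annotation counts (uniquely placed SNPs)
UNIQUE_SNPS = 106_424
GENIC_SNPS = 48_842
INTRONIC_SNPS = 34_534
UTR_SNPS = 8_091
UTR5_SNPS = 1_867
UTR3_SNPS = 6_224
EXONIC_SNPS = 5_856
SYNONYMOUS_SNPS = 3_352
NONSYNONYMOUS_SNPS = 2_465
START_STOP_SNPS = 39
SPLICE_REGION_SNPS = 483


def map_summary() -> dict:
    """Genome-wide summary arithmetic from the per-chromosome table:
    per-sex totals, female:male ratio, SNP-count vs physical-length
    correlation, and SNP densities."""
    t = MAP_TABLE
    total_snps = int(t["snps"].sum())
    total_m = float(t["male_max_cM"].sum())
    total_f = float(t["female_max_cM"].sum())
    phys_mb = float(t["phys_mb"].sum())
    return {
        "n_chromosomes": len(t),
        "total_snps": total_snps,
        "male_total_cM": total_m,
        "female_total_cM": total_f,
        "female_male_ratio": total_f / total_m,
        "snps_vs_length_r": float(stats.pearsonr(t["snps"], t["phys_mb"])[0]),
        "assembled_mb": phys_mb,
        "kb_per_snp": phys_mb * 1e3 / total_snps,
        "male_cM_per_snp": total_m / total_snps,
        "female_cM_per_snp": total_f / total_snps,
        "anchored_unassigned_mb": float(t["unassigned_mb"].sum()),
    }


def anchored_fraction_pct(
    anchored_mb: float | None = None, unplaced_mb: float = UNPLACED_TOTAL_MB
) -> float:
    """Percentage of the previously unassigned assembly anchored to
    chromosomes by the linkage map."""
    if anchored_mb is None:
        anchored_mb = float(MAP_TABLE["unassigned_mb"].sum())
    return 100.0 * anchored_mb / unplaced_mb


def annotation_summary() -> dict:
    """Genic fraction and intronic share from the printed counts."""
    return {
        "unique_snps": UNIQUE_SNPS,
        "genic_pct": 100.0 * GENIC_SNPS / UNIQUE_SNPS,
        "intronic_share_of_genic_pct": 100.0 * INTRONIC_SNPS / GENIC_SNPS,
        "exon_component_sum": SYNONYMOUS_SNPS + NONSYNONYMOUS_SNPS + START_STOP_SNPS,
        "utr_component_sum": UTR5_SNPS + UTR3_SNPS,
    }
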