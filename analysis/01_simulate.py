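"""Generate the two synthetic study fixtures.

* mapping study: 5 chromosomes x 20 Mb with the default heterochiasmic
  landscape (flat female track; male interior 1 cM/Mb elevated 10-fold
  over the outer 10% of each end), 10% of sequence held out as unplaced
  contigs, 250 array-like SNPs (MAF 0.3-0.5), and a 28-sire / 60-dam /
  90-offspring pedigree.  Two-point interval estimation needs many more
  meioses than the multipoint analyses such maps are usually built with,
  hence the deep families.
* annotation study: a small gene-dense genome (2 x ~450 kb, 60 genes)
  with 600 SNPs, used to exercise ORF prediction and effect
  classification against generation-time truth.

Fixture files (FASTA/VCF/TSV/GFF3/JSON) go to scratch/ (they are large
and regenerable); a summary of what was simulated goes to results/.
"""

import json
from pathlib import Path

from salmap.io import write_fixture
from salmap.simulate import PedigreeSpec, StudyConfig, simulate_study

ROOT = Path(__file__).resolve().parents[1]
SEED = 1

MAPPING_CONFIG = StudyConfig(
    n_chrom=5,
    length_range=(20_000_000, 20_000_000),
    unplaced_fraction=0.1,
    n_markers=250,
    n_genes=0,
    maf_distribution=(0.3, 0.5),
    pedigree=PedigreeSpec(28, 60, 90),
)

ANNOTATION_CONFIG = StudyConfig(
    n_chrom=2,
    length_range=(400_000, 500_000),
    unplaced_fraction=0.0,
    n_markers=600,
    n_genes=60,
    pedigree=PedigreeSpec(4, 8, 6),
)


def main() -> None:
    summary = {}
    for name, cfg in (("mapping", MAPPING_CONFIG), ("annotation", ANNOTATION_CONFIG)):
        fx = simulate_study(cfg, seed=SEED)
        outdir = ROOT / "scratch" / f"study_{name}"
        paths = write_fixture(fx, outdir)
        summary[name] = {
            "chromosomes": len(fx.genome.chromosomes),
            "total_bp": fx.genome.total_length(),
            "unplaced_bp": fx.genome.unplaced_length(),
            "contigs": len(fx.genome.contigs),
            "markers": fx.gm.n_markers,
            "individuals": fx.gm.n_individuals,
            "families": len(fx.gm.families()),
            "genes": len(fx.genes.genes),
            "female_total_cM": fx.landscape.total_length("F"),
            "male_total_cM": fx.landscape.total_length("M"),
            "files": {k: str(p) for k, p in paths.items()},
        }
        print(
            f"{name}: {summary[name]['markers']} markers, "
            f"{summary[name]['individuals']} fish in {summary[name]['families']} "
            f"families, {summary[name]['genes']} genes -> {outdir}"
        )
    res = ROOT / "results"
    res.mkdir(exist_ok=True)
    (res / "simulation_summary.json").write_text(json.dumps(summary, indent=2))
    print(f"wrote {res / 'simulation_summary.json'}")


if __name__ == "__main__":
    main()
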