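"""Genotype QC on the mapping study: Mendelian-error exclusion (>1% for
individuals then markers), MAF < 0.05 removal, and segregation-distortion
removal at p < 0.001.  Writes the filtered VCF next to the fixture and a
per-stage summary under results/."""

from pathlib import Path

from salmap.io import read_vcf, write_vcf
from salmap.qc import run_qc

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    study = ROOT / "scratch" / "study_mapping"
    gm = read_vcf(study / "genotypes.vcf", study / "pedigree.tsv")
    filtered, report = run_qc(gm)
    write_vcf(filtered, study / "genotypes.qc.vcf")

    res = ROOT / "results"
    res.mkdir(exist_ok=True)
    with open(res / "qc_summary.tsv", "w") as fh:
        fh.write("stage\tmarkers\tindividuals\n")
        for stage, n_mk, n_ind in report.stage_counts:
            fh.write(f"{stage}\t{n_mk}\t{n_ind}\n")
            print(f"{stage}: {n_mk} markers, {n_ind} individuals")
    report.removed_markers.to_csv(res / "qc_removed_markers.tsv", sep="\t")
    reasons = report.removed_markers["reason"].value_counts().to_dict()
    print(f"marker removals by reason: {reasons}")
    print(f"individual removals: {len(report.removed_individuals)}")


if __name__ == "__main__":
    main()
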