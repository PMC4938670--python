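"""Summary arithmetic over the published per-chromosome map table of the
Atlantic salmon high-density SNP linkage map: per-sex totals and their
ratio, the SNP-count vs chromosome-length correlation, SNP densities,
and the anchored fraction of the previously unassigned assembly, plus
the genic/intronic shares from the printed annotation counts."""

import json
from pathlib import Path

from salmap.published import anchored_fraction_pct, annotation_summary, map_summary

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    m = map_summary()
    a = annotation_summary()
    out = {
        "map": m,
        "anchored_pct_of_unplaced": anchored_fraction_pct(),
        "annotation": a,
    }
    res = ROOT / "results"
    res.mkdir(exist_ok=True)
    (res / "published_summary.json").write_text(json.dumps(out, indent=2))

    print(
        f"map totals: male {m['male_total_cM']:.1f} cM, female "
        f"{m['female_total_cM']:.1f} cM, ratio {m['female_male_ratio']:.2f}"
    )
    print(
        f"SNPs vs physical length: r = {m['snps_vs_length_r']:.3f}; "
        f"1 SNP per {m['kb_per_snp']:.1f} kb and per "
        f"{m['male_cM_per_snp']:.3f} cM (male)"
    )
    print(
        f"anchored {m['anchored_unassigned_mb']:.1f} Mb of previously "
        f"unassigned sequence = {anchored_fraction_pct():.1f}% of the "
        f"unplaced assembly"
    )
    print(
        f"annotation: genic {a['genic_pct']:.1f}%, intronic share "
        f"{a['intronic_share_of_genic_pct']:.1f}%"
    )


if __name__ == "__main__":
    main()
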