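"""Readers and writers for the standard file formats the pipeline touches.

All emitted coordinates follow the format conventions (VCF and GFF3
1-based inclusive); everything in memory is 0-based half-open.  Reading
uses the field-standard libraries (cyvcf2, pyfaidx, gffutils); the writers
emit plain text.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix, make_individual_table

# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def write_fasta(genome, path, width: int = 80) -> None:
    """Write a :class:`~salmap.simulate.SimulatedGenome` (chromosomes then
    contigs) as FASTA."""
    from .simulate.genome import decode

    with open(path, "w") as fh:
        for name, codes in genome.records():
            fh.write(f">{name}\n")
            s = decode(codes)
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")


def read_fasta_arrays(path) -> dict[str, np.ndarray]:
    """FASTA -> dict of uint8 code arrays (via pyfaidx)."""
    from pyfaidx import Fasta

    from .simulate.genome import encode

    fa = Fasta(str(path), rebuild=True)
    return {name: encode(str(fa[name][:])) for name in fa.keys()}


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

_GT = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}


def write_vcf(gm: GenotypeMatrix, path) -> None:
    order = np.argsort(
        gm.markers["chrom"].astype(str).values + ":"
        + gm.markers["pos"].astype(int).astype(str).str.zfill(12).values
    )
    samples = list(gm.individuals.index)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=salmap-simulate\n")
        for chrom in pd.unique(gm.markers["chrom"].iloc[order]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(samples) + "\n")
        for j in order:
            row = gm.markers.iloc[j]
            gts = "\t".join(_GT[int(g)] for g in gm.calls[:, j])
            fh.write(
                f"{row['chrom']}\t{int(row['pos']) + 1}\t{gm.markers.index[j]}\t"
                f"{row['ref']}\t{row['alt']}\t.\tPASS\t.\tGT\t{gts}\n"
            )


def read_vcf(vcf_path, pedigree_path) -> GenotypeMatrix:
    """VCF (GT field) + 4-column pedigree TSV -> GenotypeMatrix."""
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path), gts012=True)
    samples = list(vcf.samples)
    ids, chroms, poss, refs, alts, cols = [], [], [], [], [], []
    for var in vcf:
        ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        chroms.append(var.CHROM)
        poss.append(var.POS - 1)
        refs.append(var.REF)
        alts.append(var.ALT[0] if var.ALT else ".")
        g = var.gt_types.astype(np.int8)  # 0=hom_ref, 1=het, 2=hom_alt, 3=missing
        g[g == 3] = -1
        cols.append(g)
    markers = pd.DataFrame(
        {"chrom": chroms, "pos": poss, "ref": refs, "alt": alts},
        index=pd.Index(ids, name="marker_id"),
    )
    individuals = read_pedigree(pedigree_path)
    if list(individuals.index) != samples:
        individuals = individuals.loc[samples]
    calls = np.stack(cols, axis=1) if cols else np.zeros((len(samples), 0), np.int8)
    return GenotypeMatrix(markers, individuals, calls)


# ---------------------------------------------------------------------------
# pedigree / flanks / map / placement tables
# ---------------------------------------------------------------------------


def write_pedigree(individuals: pd.DataFrame, path) -> None:
    df = individuals.reset_index()[["id", "sire", "dam", "sex"]]
    df.to_csv(path, sep="\t", index=False)


def read_pedigree(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return make_individual_table(list(df.itertuples(index=False, name=None)))


def write_flanks(flanks: pd.DataFrame, path) -> None:
    flanks.reset_index().to_csv(path, sep="\t", index=False)


def read_flanks(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t").set_index("marker_id")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------


def write_gff3(genes, path) -> None:
    """Gene models (gene/mRNA/exon/CDS/UTR) with per-transcript expression."""
    from .simulate.genes import transcript_gpos

    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gene in genes.genes:
            gs, ge = gene.span
            fh.write(
                f"{gene.chrom}\tsalmap\tgene\t{gs + 1}\t{ge}\t.\t{gene.strand}\t.\t"
                f"ID={gene.gid}\n"
            )
            for tx in gene.transcripts:
                ts, te = tx.span
                fh.write(
                    f"{gene.chrom}\tsalmap\tmRNA\t{ts + 1}\t{te}\t.\t{gene.strand}\t.\t"
                    f"ID={tx.tid};Parent={gene.gid};expression={tx.expression}\n"
                )
                for s, e in tx.exons:
                    fh.write(
                        f"{gene.chrom}\tsalmap\texon\t{s + 1}\t{e}\t.\t{gene.strand}\t.\t"
                        f"Parent={tx.tid}\n"
                    )
                gpos = transcript_gpos(tx, gene.strand)
                c0, c1 = tx.cds_t
                for s, e in _runs(np.sort(gpos[c0:c1])):
                    fh.write(
                        f"{gene.chrom}\tsalmap\tCDS\t{s + 1}\t{e}\t.\t{gene.strand}\t0\t"
                        f"Parent={tx.tid}\n"
                    )
                for feat, lo, hi in (
                    ("five_prime_UTR", 0, c0),
                    ("three_prime_UTR", c1, len(gpos)),
                ):
                    for s, e in _runs(np.sort(gpos[lo:hi])):
                        fh.write(
                            f"{gene.chrom}\tsalmap\t{feat}\t{s + 1}\t{e}\t.\t"
                            f"{gene.strand}\t.\tParent={tx.tid}\n"
                        )


def _runs(sorted_pos: np.ndarray):
    """Maximal contiguous runs of sorted genomic positions as (start, end-1+1)."""
    if len(sorted_pos) == 0:
        return
    breaks = np.flatnonzero(np.diff(sorted_pos) > 1)
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [len(sorted_pos) - 1]])
    for a, b in zip(starts, ends):
        yield int(sorted_pos[a]), int(sorted_pos[b]) + 1


# ---------------------------------------------------------------------------
# truth
# ---------------------------------------------------------------------------


def write_truth(truth, path) -> None:
    payload = {
        "markers": json.loads(truth.markers.reset_index().to_json(orient="records")),
        "genetic_lengths": json.loads(truth.genetic_lengths.to_json())
        if truth.genetic_lengths is not None
        else None,
        "crossovers": [
            {
                "offspring": r.offspring,
                "parent": r.parent,
                "sex": r.sex,
                "chrom": r.chrom,
                "positions": [float(x) for x in r.positions],
            }
            for r in truth.crossovers
        ],
    }
    Path(path).write_text(json.dumps(payload))


def write_fixture(fixture, outdir) -> dict[str, Path]:
    """Write a simulated fixture as its on-disk file set."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": outdir / "genome.fa",
        "vcf": outdir / "genotypes.vcf",
        "pedigree": outdir / "pedigree.tsv",
        "flanks": outdir / "flanks.tsv",
        "gff3": outdir / "genes.gff3",
        "truth": outdir / "truth.json",
    }
    write_fasta(fixture.genome, paths["fasta"])
    write_vcf(fixture.gm, paths["vcf"])
    write_pedigree(fixture.gm.individuals, paths["pedigree"])
    write_flanks(fixture.flanks, paths["flanks"])
    write_gff3(fixture.genes, paths["gff3"])
    write_truth(fixture.truth, paths["truth"])
    return paths
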