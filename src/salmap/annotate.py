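"""Positional and coding-effect classification of uniquely placed SNPs.

For every gene the most highly expressed transcript is taken as
canonical; an ORF (ATG-initiated, stop-terminated, >= 100 aa) is predicted
on its spliced sequence and mapped back to the genome, standing in for a
Transdecoder-style coding-region call.  Each SNP then receives exactly
one category by precedence: CDS (synonymous / nonsynonymous /
start-stop change) > UTR > splice region > intron > intergenic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate.genome import COMPLEMENT, decode, encode

SPLICE_REGION_BP = 8
MIN_ORF_AA = 100

STOPS = {"TAA", "TAG", "TGA"}

def _codon_table() -> dict[str, str]:
    bases = "TCAG"
    aas = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
    table = {}
    k = 0
    for a in bases:
        for b in bases:
            for c in bases:
                table[a + b + c] = aas[k]
                k += 1
    return table


CODON_TABLE = _codon_table()


def translate_codon(codon: str) -> str:
    """Standard genetic code (NCBI table 1); stops translate to '*'."""
    return CODON_TABLE[codon]


def translate(seq: str) -> str:
    return "".join(
        CODON_TABLE.get(seq[i : i + 3], "X") for i in range(0, len(seq) - 2, 3)
    )


# ---------------------------------------------------------------------------
# gene models
# ---------------------------------------------------------------------------


@dataclass
class TranscriptModel:
    tid: str
    exons: list[tuple[int, int]]  # genomic 0-based half-open, sorted
    expression: float

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def exonic_length(self) -> int:
        return sum(e - s for s, e in self.exons)


@dataclass
class GeneAnnotation:
    gid: str
    chrom: str
    strand: str
    transcripts: list[TranscriptModel] = field(default_factory=list)

    @property
    def span(self) -> tuple[int, int]:
        starts, ends = zip(*(t.span for t in self.transcripts))
        return min(starts), max(ends)


def load_gene_models(gff3_path) -> list[GeneAnnotation]:
    """Read gene/mRNA/exon features (with mRNA ``expression`` attribute)
    from GFF3 via gffutils."""
    import gffutils

    db = gffutils.create_db(
        str(gff3_path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes = []
    for g in db.features_of_type("gene"):
        gene = GeneAnnotation(gid=g.id, chrom=g.seqid, strand=g.strand)
        for t in db.children(g, featuretype="mRNA"):
            exons = sorted(
                (e.start - 1, e.end) for e in db.children(t, featuretype="exon")
            )
            expr = float(t.attributes.get("expression", ["nan"])[0])
            gene.transcripts.append(TranscriptModel(t.id, exons, expr))
        if gene.transcripts:
            genes.append(gene)
    return genes


def gene_models_from_geneset(gs) -> list[GeneAnnotation]:
    """Adapter from the simulator's GeneSet (exons + expression only; CDS
    is re-derived by ORF prediction, not read from the truth)."""
    out = []
    for g in gs.genes:
        out.append(
            GeneAnnotation(
                gid=g.gid,
                chrom=g.chrom,
                strand=g.strand,
                transcripts=[
                    TranscriptModel(t.tid, list(t.exons), t.expression)
                    for t in g.transcripts
                ],
            )
        )
    return out


# ---------------------------------------------------------------------------
# canonical transcript and ORF
# ---------------------------------------------------------------------------


def transcript_positions(tx: TranscriptModel, strand: str) -> np.ndarray:
    """Genomic position of each transcript base, transcript orientation."""
    gpos = np.concatenate([np.arange(s, e) for s, e in tx.exons])
    return gpos[::-1] if strand == "-" else gpos


def spliced_sequence(tx: TranscriptModel, strand: str, chrom_codes: np.ndarray) -> str:
    codes = chrom_codes[transcript_positions(tx, strand)]
    if strand == "-":
        codes = COMPLEMENT[codes]
    return decode(codes)


def find_orf(seq: str, min_aa: int = MIN_ORF_AA) -> tuple[int, int] | None:
    """Longest ATG-initiated, stop-terminated ORF with >= min_aa codons
    before the stop, over the three forward frames; ties break to the
    5'-most start.  Returns (start, end) with the stop codon included."""
    n = len(seq)
    if n < 3 * (min_aa + 1):
        return None
    best: tuple[int, int] | None = None  # (aa_len, start)
    for frame in range(3):
        start = None
        for q in range(frame, n - 2, 3):
            codon = seq[q : q + 3]
            if start is None:
                if codon == "ATG":
                    start = q
            elif codon in STOPS:
                aa = (q - start) // 3
                if aa >= min_aa and (
                    best is None or aa > best[0] or (aa == best[0] and start < best[1])
                ):
                    best = (aa, start)
                start = None
        # ORFs whose stop lies beyond the sequence end do not qualify
    if best is None:
        return None
    aa, start = best
    return start, start + 3 * (aa + 1)


def select_canonical_transcript(
    gene: GeneAnnotation, chrom_codes: np.ndarray, min_aa: int = MIN_ORF_AA
) -> TranscriptModel:
    """Highest expression; ties broken by longest predicted ORF, then
    lexicographic transcript id."""

    def orf_len(tx: TranscriptModel) -> int:
        orf = find_orf(spliced_sequence(tx, gene.strand, chrom_codes), min_aa)
        return 0 if orf is None else orf[1] - orf[0]

    best = gene.transcripts[0]
    best_key = (best.expression, None, best.tid)
    for tx in gene.transcripts[1:]:
        if tx.expression > best_key[0]:
            best, best_key = tx, (tx.expression, None, tx.tid)
        elif tx.expression == best_key[0]:
            if best_key[1] is None:
                best_key = (best_key[0], orf_len(best), best_key[2])
            cand = orf_len(tx)
            if cand > best_key[1] or (cand == best_key[1] and tx.tid < best_key[2]):
                best, best_key = tx, (tx.expression, cand, tx.tid)
    return best


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

CATEGORIES = (
    "intergenic",
    "intron",
    "splice_region",
    "utr5",
    "utr3",
    "synonymous",
    "nonsynonymous",
    "start_stop_change",
)
#: precedence when a SNP overlaps several genes (higher wins)
_PRECEDENCE = {
    "start_stop_change": 7,
    "nonsynonymous": 6,
    "synonymous": 5,
    "utr5": 4,
    "utr3": 4,
    "splice_region": 3,
    "intron": 2,
    "intergenic": 0,
}


@dataclass
class _PreparedGene:
    gene: GeneAnnotation
    tx: TranscriptModel
    gpos: np.ndarray            # transcript base -> genomic position
    spliced: str
    orf: tuple[int, int] | None


def _prepare(genes: list[GeneAnnotation], sequences, min_aa) -> dict[str, list[_PreparedGene]]:
    by_chrom: dict[str, list[_PreparedGene]] = {}
    for gene in genes:
        codes = sequences.get(gene.chrom)
        if codes is None:
            continue
        tx = select_canonical_transcript(gene, codes, min_aa)
        gpos = transcript_positions(tx, gene.strand)
        spliced = spliced_sequence(tx, gene.strand, codes)
        orf = find_orf(spliced, min_aa)
        by_chrom.setdefault(gene.chrom, []).append(
            _PreparedGene(gene, tx, gpos, spliced, orf)
        )
    for lst in by_chrom.values():
        lst.sort(key=lambda p: p.tx.span[0])
    return by_chrom


def _classify_one(p: _PreparedGene, pos: int, ref: str, alt: str):
    """Category (and codon detail) of a SNP inside one prepared gene, or
    None when the site falls outside the canonical transcript."""
    start, end = p.tx.span
    if not start <= pos < end:
        return None
    hit = np.flatnonzero(p.gpos == pos)
    if len(hit) == 0:
        d = min(
            min(pos - e + 1, s - pos)
            for (_, e), (s, _) in zip(p.tx.exons[:-1], p.tx.exons[1:])
            if e <= pos < s
        )
        return ("splice_region" if d <= SPLICE_REGION_BP else "intron", None)
    if p.orf is None:
        return None  # no qualifying ORF: gene treated as non-coding
    t = int(hit[0])
    c0, c1 = p.orf
    if t < c0:
        return ("utr5", None)
    if t >= c1:
        return ("utr3", None)
    strand = p.gene.strand
    alt_t = alt if strand == "+" else decode(COMPLEMENT[encode(alt)])[0]
    ci = (t - c0) // 3
    off = (t - c0) % 3
    ref_codon = p.spliced[c0 + 3 * ci : c0 + 3 * ci + 3]
    alt_codon = ref_codon[:off] + alt_t + ref_codon[off + 1 :]
    detail = (ref_codon, alt_codon)
    if ci == 0 and alt_codon != "ATG":
        return ("start_stop_change", detail)
    if (ref_codon in STOPS) != (alt_codon in STOPS):
        return ("start_stop_change", detail)
    aa_r, aa_a = translate_codon(ref_codon), translate_codon(alt_codon)
    return (("synonymous" if aa_r == aa_a else "nonsynonymous"), detail)


def classify_variants(
    placements: pd.DataFrame,
    markers: pd.DataFrame,
    genes: list[GeneAnnotation],
    sequences: dict[str, np.ndarray],
    min_aa: int = MIN_ORF_AA,
    chromosomes: set[str] | None = None,
) -> pd.DataFrame:
    """Effect category per resolved SNP placement.

    ``markers`` supplies ref/alt alleles; placements on records without
    gene models (unanchored contigs) are classified intergenic and
    flagged off-chromosome.
    """
    if chromosomes is None:
        chromosomes = {n for n in sequences if not n.startswith("contig")}
    prepared = _prepare(genes, sequences, min_aa)
    res = placements[placements["status"].isin(("unique", "resolved_by_linkage"))]
    rows = []
    for mid, r in res.iterrows():
        target, pos = r["target"], int(r["pos"])
        ref = markers.loc[mid, "ref"] if mid in markers.index else "N"
        alt = markers.loc[mid, "alt"] if mid in markers.index else "N"
        off_chrom = target not in chromosomes
        best = ("intergenic", None, "")
        for p in prepared.get(target, []):
            out = _classify_one(p, pos, ref, alt)
            if out is None:
                continue
            cat, detail = out
            if _PRECEDENCE[cat] > _PRECEDENCE[best[0]]:
                best = (cat, detail, p.gene.gid)
        cat, detail, gid = best
        rows.append(
            (
                mid, target, pos, gid, cat,
                detail[0] if detail else "",
                detail[1] if detail else "",
                f"{translate_codon(detail[0])}>{translate_codon(detail[1])}"
                if detail
                else "",
                off_chrom,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "marker_id", "chrom", "pos", "gene", "category",
            "ref_codon", "alt_codon", "aa_change", "off_chromosome",
        ],
    ).set_index("marker_id")


GENIC = (
    "utr5", "utr3", "intron", "splice_region",
    "synonymous", "nonsynonymous", "start_stop_change",
)
EXONIC = ("synonymous", "nonsynonymous", "start_stop_change")


def summarize_effects(
    effects: pd.DataFrame, include_off_chromosome: bool = False
) -> dict:
    """Category totals, genic percentage, intronic share of genic, and a
    per-chromosome breakdown (off-chromosome SNPs are excluded from the
    per-chromosome rows)."""
    counts = {c: int((effects["category"] == c).sum()) for c in CATEGORIES}
    n = len(effects)
    genic = sum(counts[c] for c in GENIC)
    intronic = counts["intron"] + counts["splice_region"]
    on = effects[~effects["off_chromosome"]]
    per_chrom = pd.DataFrame(
        {
            "exonic": on[on["category"].isin(EXONIC)].groupby("chrom").size(),
            "intronic": on[on["category"].isin(("intron", "splice_region"))]
            .groupby("chrom").size(),
            "utr": on[on["category"].isin(("utr5", "utr3"))].groupby("chrom").size(),
            "intergenic": on[on["category"] == "intergenic"].groupby("chrom").size(),
        }
    ).fillna(0).astype(int)
    return {
        "n_snps": n,
        "counts": counts,
        "genic": genic,
        "genic_pct": 100.0 * genic / n if n else 0.0,
        "intronic_share_of_genic_pct": 100.0 * intronic / genic if genic else 0.0,
        "per_chromosome": per_chrom,
    }
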