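"""Toy gene models with valid planted ORFs and per-transcript expression.

Genes are placed without overlap on chromosome sequence (never across
N-masked excised spans).  For each gene the exonic sequence is rewritten
in place so that the spliced canonical transcript carries exactly one
longest ORF: an ATG, >= 100 sense codons, and a stop.  Stop codons are
planted in all three frames at the 3' end of the 5'UTR so no upstream
start can read through into the CDS.  Additional transcript variants are
UTR truncations sharing the same CDS.

The generation-time effect classifier in :func:`true_effects` labels every
marker by brute force (full mutant-CDS translation through Bio.Seq); it is
the independent oracle for the annotation pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .genome import COMPLEMENT, N_CODE, SimulatedGenome, decode, encode

STOP_CODONS = ("TAA", "TAG", "TGA")
_SENSE = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in STOP_CODONS
]

EFFECT_CATEGORIES = (
    "intergenic",
    "intron",
    "splice_region",
    "utr5",
    "utr3",
    "synonymous",
    "nonsynonymous",
    "start_stop_change",
)

SPLICE_REGION_BP = 8


@dataclass
class Transcript:
    tid: str
    exons: list[tuple[int, int]]     # genomic, 0-based half-open, sorted
    expression: float
    cds_t: tuple[int, int]           # CDS span in transcript coordinates (incl. stop)

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def exonic_length(self) -> int:
        return sum(e - s for s, e in self.exons)


@dataclass
class Gene:
    gid: str
    chrom: str
    strand: str                      # '+' or '-'
    transcripts: list[Transcript] = field(default_factory=list)

    @property
    def span(self) -> tuple[int, int]:
        starts, ends = zip(*(t.span for t in self.transcripts))
        return min(starts), max(ends)


@dataclass
class GeneSet:
    genes: list[Gene] = field(default_factory=list)

    def by_chrom(self) -> dict[str, list[Gene]]:
        out: dict[str, list[Gene]] = {}
        for g in self.genes:
            out.setdefault(g.chrom, []).append(g)
        for lst in out.values():
            lst.sort(key=lambda g: g.span[0])
        return out


def transcript_gpos(tx: Transcript, strand: str) -> np.ndarray:
    """Genomic position of each transcript base, in transcript orientation."""
    gpos = np.concatenate([np.arange(s, e) for s, e in tx.exons])
    return gpos[::-1] if strand == "-" else gpos


def spliced_codes(tx: Transcript, strand: str, chrom_seq: np.ndarray) -> np.ndarray:
    codes = chrom_seq[transcript_gpos(tx, strand)]
    return COMPLEMENT[codes] if strand == "-" else codes


def canonical_transcript(gene: Gene) -> Transcript:
    """Highest expression; ties by longest CDS, then transcript id."""
    return max(
        gene.transcripts,
        key=lambda t: (t.expression, t.cds_t[1] - t.cds_t[0], t.tid),
    )


def _brute_longest_orf(seq: str, min_aa: int = 100):
    """(start, n_aa) of the longest ATG-initiated, stop-terminated ORF with
    >= min_aa codons before the stop; ties to the 5'-most start."""
    best = None
    for start in range(len(seq) - 2):
        if seq[start : start + 3] != "ATG":
            continue
        aa = None
        for q in range(start + 3, len(seq) - 2, 3):
            if seq[q : q + 3] in STOP_CODONS:
                aa = (q - start) // 3
                break
        if aa is None or aa < min_aa:
            continue
        if best is None or aa > best[1]:
            best = (start, aa)
    return best


def generate_gene_models(
    genome: SimulatedGenome,
    n_genes: int,
    seed: int = 0,
    min_aa: int = 100,
    max_aa: int = 220,
    margin: int = 500,
) -> GeneSet:
    """Place ``n_genes`` non-overlapping genes and rewrite exonic sequence
    in place so every CDS translates cleanly.  Mutates ``genome``."""
    rng = np.random.default_rng(seed)
    chroms = list(genome.chromosomes)
    lengths = np.array([len(genome.chromosomes[c]) for c in chroms], dtype=float)
    weights = lengths / lengths.sum()
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}

    gs = GeneSet()
    for k in range(n_genes):
        placed = False
        for _ in range(500):
            utr5 = int(rng.integers(60, 251))
            n_aa = int(rng.integers(min_aa, max_aa + 1))
            cds_len = 3 * (n_aa + 1)  # incl. stop codon
            utr3 = int(rng.integers(80, 301))
            exonic = utr5 + cds_len + utr3
            n_exons = int(rng.integers(1, 5))
            exon_lens = _split_lengths(exonic, n_exons, 40, rng)
            intron_lens = [int(rng.integers(60, 401)) for _ in range(n_exons - 1)]
            span = exonic + sum(intron_lens)

            ci = int(rng.choice(len(chroms), p=weights))
            chrom = chroms[ci]
            L = int(lengths[ci])
            if L < span + 2 * margin:
                continue
            start = int(rng.integers(margin, L - margin - span))
            end = start + span
            seq = genome.chromosomes[chrom]
            if (seq[start:end] == N_CODE).any():
                continue
            if any(start < e + 200 and end > s - 200 for s, e in occupied[chrom]):
                continue

            strand = "+" if rng.integers(2) else "-"
            exons, pos = [], start
            for i, el in enumerate(exon_lens):
                exons.append((pos, pos + el))
                pos += el + (intron_lens[i] if i < n_exons - 1 else 0)
            gene = _build_gene(
                f"gene_{k + 1:04d}", chrom, strand, exons, utr5, cds_len, utr3,
                seq, rng, min_aa,
            )
            if gene is None:
                continue
            occupied[chrom].append((start, end))
            gs.genes.append(gene)
            placed = True
            break
        if not placed:
            raise RuntimeError(
                f"could not place gene {k + 1}; placed {len(gs.genes)} of {n_genes}"
            )
    return gs


def _split_lengths(total, parts, min_len, rng):
    if parts == 1:
        return [total]
    for _ in range(100):
        cuts = np.sort(rng.integers(min_len, total - min_len, size=parts - 1))
        lens = np.diff(np.concatenate([[0], cuts, [total]]))
        if (lens >= min_len).all():
            return [int(x) for x in lens]
    return [total // parts] * (parts - 1) + [total - (parts - 1) * (total // parts)]


def _build_gene(gid, chrom, strand, exons, utr5, cds_len, utr3, seq, rng, min_aa):
    exonic = utr5 + cds_len + utr3
    n_aa = cds_len // 3 - 1
    canon = Transcript(f"{gid}.t1", list(exons), 0.0, (utr5, utr5 + cds_len))
    gpos = transcript_gpos(canon, strand)

    for _ in range(20):
        tseq = rng.integers(0, 4, size=exonic, dtype=np.uint8)
        # stop codons in all three frames at the tail of the 5'UTR
        for off in (utr5 - 11, utr5 - 7, utr5 - 3):
            tseq[off : off + 3] = encode(STOP_CODONS[int(rng.integers(3))])
        cds = "ATG" + "".join(
            _SENSE[int(i)] for i in rng.integers(0, len(_SENSE), size=n_aa - 1)
        ) + STOP_CODONS[int(rng.integers(3))]
        tseq[utr5 : utr5 + cds_len] = encode(cds)
        seq[gpos] = COMPLEMENT[tseq] if strand == "-" else tseq

        transcripts = [canon]
        for v in range(int(rng.integers(0, 3))):
            tx = _truncated_variant(gid, v, canon, strand, utr5, cds_len, utr3, rng)
            if tx is not None:
                transcripts.append(tx)
        ok = True
        for tx in transcripts:
            s = decode(spliced_codes(tx, strand, seq))
            if _brute_longest_orf(s, min_aa) != (tx.cds_t[0], n_aa):
                ok = False
                break
        if ok:
            for tx in transcripts:
                tx.expression = float(np.round(rng.lognormal(1.0, 1.0), 3))
            return Gene(gid, chrom, strand, transcripts)
    return None


def _truncated_variant(gid, v, canon, strand, utr5, cds_len, utr3, rng):
    """A transcript sharing the CDS but with a truncated terminal UTR."""
    end_5prime = bool(rng.integers(2))
    trunc = int(rng.integers(10, (utr5 - 15 if end_5prime else utr3 - 20) + 1))
    exons = [list(e) for e in canon.exons]
    # the transcript 5' end is the genomic left end on '+', right end on '-'
    cut_left = (strand == "+") == end_5prime
    if cut_left:
        if exons[0][1] - exons[0][0] - trunc < 20:
            return None
        exons[0][0] += trunc
    else:
        if exons[-1][1] - exons[-1][0] - trunc < 20:
            return None
        exons[-1][1] -= trunc
    cds_off = utr5 - trunc if end_5prime else utr5
    return Transcript(
        f"{gid}.t{v + 2}", [tuple(e) for e in exons], 0.0, (cds_off, cds_off + cds_len)
    )


# ---------------------------------------------------------------------------
# generation-time truth labelling (independent oracle for the annotator)
# ---------------------------------------------------------------------------


def _cds_effect(ref_cds: str, alt_cds: str) -> str:
    if alt_cds[:3] != "ATG":
        return "start_stop_change"
    pr = str(Seq(ref_cds).translate())
    pa = str(Seq(alt_cds).translate())
    if pr == pa:
        return "synonymous"
    stops_r = {i for i, a in enumerate(pr) if a == "*"}
    stops_a = {i for i, a in enumerate(pa) if a == "*"}
    if stops_r != stops_a:
        return "start_stop_change"
    return "nonsynonymous"


def true_effects(
    genes: GeneSet, genome: SimulatedGenome, markers: pd.DataFrame
) -> pd.DataFrame:
    """Effect category per marker by brute force against the gene structures.

    ``markers`` needs columns chrom, chrom_pos, ref, alt (chromosome
    coordinates).  Returns category and gene id per marker.
    """
    by_chrom = genes.by_chrom()
    cats, gids = [], []
    for mid, row in markers.iterrows():
        chrom, pos = row["chrom"], int(row["chrom_pos"])
        gene = next(
            (
                g
                for g in by_chrom.get(chrom, [])
                if g.span[0] <= pos < g.span[1]
            ),
            None,
        )
        if gene is None:
            cats.append("intergenic")
            gids.append("")
            continue
        tx = canonical_transcript(gene)
        cats.append(_classify_in_gene(gene, tx, genome, pos, row["ref"], row["alt"]))
        gids.append(gene.gid if cats[-1] != "intergenic" else "")
    return pd.DataFrame({"effect": cats, "gene": gids}, index=markers.index)


def _classify_in_gene(gene, tx, genome, pos, ref, alt) -> str:
    start, end = tx.span
    if not start <= pos < end:
        return "intergenic"  # outside the canonical transcript (UTR-truncated)
    seq = genome.chromosomes[gene.chrom]
    gpos = transcript_gpos(tx, gene.strand)
    hit = np.flatnonzero(gpos == pos)
    if len(hit) == 0:  # intronic: distance in intronic bases from nearest junction
        d = min(
            min(pos - e + 1, s - pos)
            for (_, e), (s, _) in zip(tx.exons[:-1], tx.exons[1:])
            if e <= pos < s
        )
        return "splice_region" if d <= SPLICE_REGION_BP else "intron"
    t = int(hit[0])
    c0, c1 = tx.cds_t
    if t < c0:
        return "utr5"
    if t >= c1:
        return "utr3"
    ref_cds = decode(spliced_codes(tx, gene.strand, seq))[c0:c1]
    alt_seq = seq.copy()
    alt_seq[pos] = encode(alt)[0]
    alt_cds = decode(spliced_codes(tx, gene.strand, alt_seq))[c0:c1]
    assert ref_cds != alt_cds
    return _cds_effect(ref_cds, alt_cds)
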