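"""Simulated reference assembly: chromosomes plus excised "unplaced" contigs.

Sequences are held as numpy ``uint8`` code arrays (A=0, C=1, G=2, T=3, N=4)
so downstream exact-match searching and codon rewriting stay vectorised.
A contig is a verbatim substring excised from its source chromosome; the
excised span is N-masked in the chromosome record, so placed and unplaced
sequence are disjoint and exact flank matches are unique.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

BASES = np.frombuffer(b"ACGTN", dtype=np.uint8)
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGTN"):
    _CODE[_b] = _i
    _CODE[ord(chr(_b).lower())] = _i
#: complement lookup in code space (N stays N)
COMPLEMENT = np.array([3, 2, 1, 0, 4], dtype=np.uint8)
N_CODE = 4


def encode(seq: str | bytes) -> np.ndarray:
    raw = seq.encode() if isinstance(seq, str) else seq
    codes = _CODE[np.frombuffer(raw, dtype=np.uint8)]
    if (codes == 255).any():
        bad = chr(raw[int(np.argmax(codes == 255))])
        raise ValueError(f"non-IUPAC base {bad!r} in sequence")
    return codes


def decode(codes: np.ndarray) -> str:
    return BASES[codes].tobytes().decode()


def reverse_complement(codes: np.ndarray) -> np.ndarray:
    return COMPLEMENT[codes[::-1]]


@dataclass
class Contig:
    name: str
    sequence: np.ndarray
    source_chromosome: str
    offset: int  # 0-based start of the excised span on the source chromosome

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class SimulatedGenome:
    chromosomes: dict[str, np.ndarray] = field(default_factory=dict)
    contigs: list[Contig] = field(default_factory=list)

    @property
    def chromosome_lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.chromosomes.items()}

    def records(self):
        """All assembly records (chromosomes first, then contigs)."""
        yield from self.chromosomes.items()
        for c in self.contigs:
            yield c.name, c.sequence

    def record(self, name: str) -> np.ndarray:
        if name in self.chromosomes:
            return self.chromosomes[name]
        for c in self.contigs:
            if c.name == name:
                return c.sequence
        raise KeyError(name)

    def contig_spans(self, chrom: str) -> list[tuple[int, int, str]]:
        """Excised (start, end, contig_name) spans on one chromosome."""
        return sorted(
            (c.offset, c.offset + c.length, c.name)
            for c in self.contigs
            if c.source_chromosome == chrom
        )

    def total_length(self) -> int:
        return sum(len(s) for _, s in self.records())

    def unplaced_length(self) -> int:
        return sum(c.length for c in self.contigs)


def generate_genome(
    n_chrom: int = 5,
    length_range: tuple[int, int] = (18_000_000, 22_000_000),
    unplaced_fraction: float = 0.22,
    seed: int = 0,
    contig_length_range: tuple[int, int] = (50_000, 300_000),
) -> SimulatedGenome:
    """Generate a random assembly with a fraction of sequence held out as
    unplaced contigs.

    The contig spans are excised *logically*: their sequence lives only in
    the contig records while the chromosome records carry N over the span,
    keeping chromosome coordinates stable.
    """
    if n_chrom < 1:
        raise ValueError("n_chrom must be >= 1")
    if not 0.0 <= unplaced_fraction < 1.0:
        raise ValueError("unplaced_fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    width = len(str(n_chrom))
    genome = SimulatedGenome()
    for k in range(n_chrom):
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        genome.chromosomes[f"chr{k + 1:0{width}d}"] = rng.integers(
            0, 4, size=length, dtype=np.uint8
        )

    if unplaced_fraction > 0.0:
        _excise_contigs(genome, unplaced_fraction, contig_length_range, rng)
    return genome


def _excise_contigs(genome, fraction, contig_length_range, rng, margin=2_000):
    lo, hi = contig_length_range
    serial = 0
    for chrom, seq in genome.chromosomes.items():
        length = len(seq)
        # chromosome records keep their full (N-masked) length, so the
        # carved total must satisfy u / (length + u) = fraction
        target = fraction / (1.0 - fraction) * length
        if length < 2 * margin + lo:
            raise ValueError(
                f"chromosome {chrom} ({length} bp) too short to host contigs "
                f"of {lo}-{hi} bp"
            )
        taken: list[tuple[int, int]] = []
        carved = 0
        attempts = 0
        while carved < target:
            attempts += 1
            if attempts > 10_000:
                raise ValueError(
                    f"could not carve {fraction:.0%} of {chrom} into contigs; "
                    "chromosome too short for the requested contig sizes"
                )
            clen = int(rng.integers(lo, min(hi, length // 4) + 1))
            if carved + clen > 1.1 * target:
                clen = max(lo, int(target - carved))
            start = int(rng.integers(margin, length - margin - clen))
            end = start + clen
            if any(start < e + margin and end > s - margin for s, e in taken):
                continue
            taken.append((start, end))
            carved += clen
        for start, end in sorted(taken):
            serial += 1
            genome.contigs.append(
                Contig(
                    name=f"contig_{serial:04d}",
                    sequence=seq[start:end].copy(),
                    source_chromosome=chrom,
                    offset=start,
                )
            )
            seq[start:end] = N_CODE
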