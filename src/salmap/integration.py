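"""Integration of the genetic map with the physical assembly.

Markers are placed by exact full-length matching of their 71-bp flanking
sequence (SNP site treated as a one-base wildcard, both strands) against
every assembly record — the dependency-free equivalent of keeping only
complete exact BLAST hits.  Multi-hit markers are resolved by linkage
(keep the hit on the chromosome the marker maps to), unplaced contigs are
anchored to chromosomes by plurality of their markers' linkage groups,
and genetic-vs-physical discordance is flagged via the longest monotone
subsequence of genetic order along physical position.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .simulate.genome import COMPLEMENT, encode

FLANK = 35
_ANCHOR_K = 12  # 2-bit-packed seed: the K bases immediately 5' of the SNP site
_SENTINEL = np.uint32(0xFFFFFFFF)


def _pack_kmers(codes: np.ndarray, k: int = _ANCHOR_K) -> np.ndarray:
    """2-bit-pack every k-mer; windows containing non-ACGT get a sentinel
    value no real pattern can take."""
    n = len(codes)
    if n < k:
        return np.empty(0, dtype=np.uint32)
    m = n - k + 1
    acc = np.zeros(m, dtype=np.uint32)
    bad = np.zeros(m, dtype=bool)
    x = np.minimum(codes, 3).astype(np.uint32)
    for t in range(k):
        acc = (acc << np.uint32(2)) | x[t : t + m]
        bad |= codes[t : t + m] > 3
    acc[bad] = _SENTINEL
    return acc


def _pack_pattern(codes: np.ndarray) -> np.uint32:
    h = np.uint32(0)
    for c in codes:
        h = (h << np.uint32(2)) | np.uint32(c)
    return h


def place_markers_by_flank(
    flanks: pd.DataFrame, sequences: dict[str, np.ndarray]
) -> pd.DataFrame:
    """Exact-match placement of 71-mer flanks (SNP at offset 35) on both
    strands of every record.

    A short packed seed (the bases just 5' of the SNP) screens candidate
    positions in one vectorised pass per record; every candidate is then
    verified by full-length comparison with the SNP base as a wildcard.
    Returns one row per hit: marker_id, target, pos (0-based SNP site),
    strand; flanks containing non-ACGT outside the central wildcard are
    skipped with status 'bad_flank'.
    """
    # per marker and strand: oriented pattern + packed anchor
    patterns: dict[int, list] = {}
    rows = []
    ids = list(flanks.index)
    for mid, row in flanks.iterrows():
        flank = row["flank"]
        off = int(row.get("snp_offset", FLANK))
        ok = len(flank) == 2 * FLANK + 1 and off == FLANK
        codes = None
        if ok:
            try:
                codes = encode(flank)
            except ValueError:
                ok = False
        if not ok or (np.delete(codes, FLANK) > 3).any():
            rows.append((mid, None, -1, ".", "bad_flank"))
            continue
        for strand, pat in (("+", codes), ("-", COMPLEMENT[codes[::-1]])):
            anchor = int(_pack_pattern(pat[FLANK - _ANCHOR_K : FLANK]))
            patterns.setdefault(anchor, []).append((mid, strand, pat))

    anchor_vals = np.array(sorted(patterns), dtype=np.uint32)
    hits: dict[str, set] = {m: set() for m in ids}
    for name, codes in sequences.items() if len(anchor_vals) else ():
        H = _pack_kmers(codes)
        if len(H) == 0:
            continue
        loc = np.searchsorted(anchor_vals, H)
        loc[loc == len(anchor_vals)] = 0
        cand = np.flatnonzero(anchor_vals[loc] == H)
        for start in cand:
            snp = int(start) + _ANCHOR_K  # anchor ends right before the SNP
            a, b = snp - FLANK, snp + FLANK + 1
            if a < 0 or b > len(codes):
                continue
            window = codes[a:b]
            if (window > 3).any():
                continue
            for mid, strand, pat in patterns[int(H[start])]:
                if np.array_equal(window[:FLANK], pat[:FLANK]) and np.array_equal(
                    window[FLANK + 1 :], pat[FLANK + 1 :]
                ):
                    hits[mid].add((name, snp, strand))
    for mid in ids:
        found = hits.get(mid, set())
        for target, snp, strand in sorted(found):
            rows.append((mid, target, snp, strand, "hit"))
        if not found and not any(r[0] == mid for r in rows):
            rows.append((mid, None, -1, ".", "no_hit"))
    return pd.DataFrame(
        rows, columns=["marker_id", "target", "pos", "strand", "status"]
    )


def collate_placements(hits: pd.DataFrame) -> pd.DataFrame:
    """One row per marker with n_exact_hits and a resolution status:
    unique / multi (pending) / unplaced."""
    out = []
    for mid, sub in hits.groupby("marker_id", sort=False):
        real = sub[sub["status"] == "hit"]
        if len(real) == 0:
            out.append((mid, None, -1, ".", 0, sub["status"].iloc[0]))
        elif len(real) == 1:
            r = real.iloc[0]
            out.append((mid, r["target"], int(r["pos"]), r["strand"], 1, "unique"))
        else:
            r = real.iloc[0]
            out.append((mid, r["target"], int(r["pos"]), r["strand"], len(real), "multi"))
    return pd.DataFrame(
        out,
        columns=["marker_id", "target", "pos", "strand", "n_exact_hits", "status"],
    ).set_index("marker_id")


def linkage_group_chromosomes(
    placements: pd.DataFrame, genetic_map: pd.DataFrame, chromosomes: set[str]
) -> dict[str, str]:
    """Majority vote of uniquely placed markers: linkage group -> chromosome."""
    uniq = placements[
        (placements["status"] == "unique") & placements["target"].isin(chromosomes)
    ]
    joined = genetic_map.join(uniq[["target"]], how="inner")
    out = {}
    for lg, sub in joined.groupby("linkage_group"):
        counts = sub["target"].value_counts()
        if len(counts):
            out[lg] = counts.index[0]
    return out


def resolve_multihit(
    placements: pd.DataFrame,
    hits: pd.DataFrame,
    genetic_map: pd.DataFrame,
    lg_to_chrom: dict[str, str],
) -> pd.DataFrame:
    """Keep the hit on the marker's linkage chromosome when exactly one hit
    lies there; otherwise the marker stays unresolved (excluded from
    downstream positional statistics)."""
    placements = placements.copy()
    multi = placements.index[placements["status"] == "multi"]
    lg_of = genetic_map["linkage_group"] if "linkage_group" in genetic_map else None
    for mid in multi:
        chrom = None
        if lg_of is not None and mid in genetic_map.index:
            chrom = lg_to_chrom.get(genetic_map.loc[mid, "linkage_group"])
        cand = hits[(hits["marker_id"] == mid) & (hits["status"] == "hit")]
        on_chrom = cand[cand["target"] == chrom] if chrom else cand.iloc[0:0]
        if len(on_chrom) == 1:
            r = on_chrom.iloc[0]
            placements.loc[mid, ["target", "pos", "strand", "status"]] = [
                r["target"], int(r["pos"]), r["strand"], "resolved_by_linkage",
            ]
        else:
            placements.loc[mid, "status"] = "unresolved"
    return placements


RESOLVED = ("unique", "resolved_by_linkage")


def per_chrom_correlation(
    genetic_map: pd.DataFrame,
    placements: pd.DataFrame,
    lg_to_chrom: dict[str, str],
    method: str = "pearson",
) -> pd.DataFrame:
    """|r| between cM and bp per chromosome and sex over resolved markers
    (absolute value: group orientation is arbitrary).  Chromosomes with
    fewer than 3 co-placed markers are flagged undefined."""
    res = placements[placements["status"].isin(RESOLVED)]
    joined = genetic_map.join(res[["target", "pos"]], how="inner")
    rows = []
    for lg, chrom in lg_to_chrom.items():
        sub = joined[(joined["linkage_group"] == lg) & (joined["target"] == chrom)]
        if len(sub) < 3:
            rows.append((chrom, lg, len(sub), np.nan, np.nan, True))
            continue
        corr = stats.pearsonr if method == "pearson" else stats.spearmanr

        def _r(x, y):
            # a constant cM track (no informative meioses) has no defined r
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                return np.nan
            return abs(corr(x, y)[0])

        rm = _r(sub["pos"].to_numpy(float), sub["male_cM"].to_numpy(float))
        rf = _r(sub["pos"].to_numpy(float), sub["female_cM"].to_numpy(float))
        rows.append((chrom, lg, len(sub), rm, rf, False))
    return pd.DataFrame(
        rows,
        columns=["chrom", "linkage_group", "n", "male_r", "female_r", "undefined"],
    ).set_index("chrom")


@dataclass
class AnchorReport:
    table: pd.DataFrame          # per contig: chrom or '', support counts, length
    n_anchored: int
    anchored_bp: int
    total_unplaced_bp: int

    @property
    def anchored_fraction(self) -> float:
        return self.anchored_bp / self.total_unplaced_bp if self.total_unplaced_bp else 0.0


def anchor_contigs(
    placements: pd.DataFrame,
    genetic_map: pd.DataFrame,
    lg_to_chrom: dict[str, str],
    contig_lengths: dict[str, int],
    min_support: int = 1,
) -> AnchorReport:
    """Assign each unplaced contig to the chromosome whose linkage group
    claims a strict plurality of the contig's placed markers."""
    res = placements[placements["status"].isin(RESOLVED)]
    on_contig = res[res["target"].isin(contig_lengths)]
    joined = genetic_map[["linkage_group"]].join(on_contig[["target"]], how="inner")
    rows = []
    support: dict[str, pd.Series] = {
        t: sub["linkage_group"].value_counts() for t, sub in joined.groupby("target")
    }
    for contig, length in contig_lengths.items():
        counts = support.get(contig)
        assigned = ""
        top = 0
        if counts is not None and len(counts):
            top = int(counts.iloc[0])
            runner = int(counts.iloc[1]) if len(counts) > 1 else 0
            if top >= min_support and top > runner:
                assigned = lg_to_chrom.get(counts.index[0], "")
        rows.append((contig, assigned, top, int(length)))
    table = pd.DataFrame(
        rows, columns=["contig", "chrom", "support", "length"]
    ).set_index("contig")
    anchored = table[table["chrom"] != ""]
    return AnchorReport(
        table=table,
        n_anchored=len(anchored),
        anchored_bp=int(anchored["length"].sum()),
        total_unplaced_bp=int(table["length"].sum()),
    )


def _longest_monotone_idx(values: np.ndarray) -> np.ndarray:
    """Indices of the longest monotone (increasing or decreasing, whichever
    is longer) subsequence; O(n log n) patience sorting."""

    def lis(v: np.ndarray) -> np.ndarray:
        tails: list[float] = []
        tails_idx: list[int] = []
        parent = np.full(len(v), -1)
        for k, x in enumerate(v):
            lo = int(np.searchsorted(np.asarray(tails), x, side="left"))
            if lo == len(tails):
                tails.append(x)
                tails_idx.append(k)
            else:
                tails[lo] = x
                tails_idx[lo] = k
            parent[k] = tails_idx[lo - 1] if lo > 0 else -1
        out = []
        k = tails_idx[-1]
        while k >= 0:
            out.append(k)
            k = parent[k]
        return np.array(out[::-1])

    inc = lis(values.astype(float))
    dec = lis(-values.astype(float))
    return inc if len(inc) >= len(dec) else dec


@dataclass
class DiscordanceSegment:
    chrom: str
    marker_ids: list[str]
    start_bp: int
    end_bp: int


def detect_discordance(
    genetic_map: pd.DataFrame,
    placements: pd.DataFrame,
    lg_to_chrom: dict[str, str],
    min_run: int = 3,
) -> tuple[list[DiscordanceSegment], dict[str, list[str]]]:
    """Flag maximal runs (>= min_run) of markers whose genetic order
    conflicts with physical order.

    For each chromosome, markers are sorted by physical position and the
    longest monotone subsequence of genetic order index is found; markers
    outside it are discordant.  Also returns the concordant (monotone)
    marker subset per chromosome, used to build cM interpolators.
    """
    res = placements[placements["status"].isin(RESOLVED)]
    joined = genetic_map.join(res[["target", "pos"]], how="inner")
    segments = []
    concordant: dict[str, list[str]] = {}
    for lg, chrom in lg_to_chrom.items():
        sub = joined[(joined["linkage_group"] == lg) & (joined["target"] == chrom)]
        sub = sub.sort_values("pos")
        if len(sub) < 2:
            concordant[chrom] = list(sub.index)
            continue
        keep = _longest_monotone_idx(sub["order_index"].to_numpy())
        concordant[chrom] = list(sub.index[keep])
        flag = np.ones(len(sub), dtype=bool)
        flag[keep] = False
        k = 0
        while k < len(sub):
            if not flag[k]:
                k += 1
                continue
            j = k
            while j + 1 < len(sub) and flag[j + 1]:
                j += 1
            if j - k + 1 >= min_run:
                segments.append(
                    DiscordanceSegment(
                        chrom=chrom,
                        marker_ids=list(sub.index[k : j + 1]),
                        start_bp=int(sub["pos"].iloc[k]),
                        end_bp=int(sub["pos"].iloc[j]),
                    )
                )
            k = j + 1
    return segments, concordant


@dataclass
class IntegrationResult:
    placements: pd.DataFrame
    lg_to_chrom: dict[str, str]
    correlations: pd.DataFrame
    anchors: AnchorReport
    discordance: list[DiscordanceSegment]
    concordant: dict[str, list[str]]


def integrate(
    flanks: pd.DataFrame,
    sequences: dict[str, np.ndarray],
    genetic_map: pd.DataFrame,
    chromosomes: set[str] | None = None,
    min_support: int = 1,
    min_run: int = 3,
) -> IntegrationResult:
    """Full integration stage: place, resolve, correlate, anchor, flag."""
    if chromosomes is None:
        chromosomes = {n for n in sequences if not n.startswith("contig")}
    contig_lengths = {
        n: len(s) for n, s in sequences.items() if n not in chromosomes
    }
    hits = place_markers_by_flank(flanks, sequences)
    placements = collate_placements(hits)
    lg_to_chrom = linkage_group_chromosomes(placements, genetic_map, chromosomes)
    placements = resolve_multihit(placements, hits, genetic_map, lg_to_chrom)
    correlations = per_chrom_correlation(genetic_map, placements, lg_to_chrom)
    anchors = anchor_contigs(
        placements, genetic_map, lg_to_chrom, contig_lengths, min_support
    )
    discordance, concordant = detect_discordance(
        genetic_map, placements, lg_to_chrom, min_run
    )
    return IntegrationResult(
        placements, lg_to_chrom, correlations, anchors, discordance, concordant
    )
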