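"""Windowed recombination landscape and map-level summaries.

The local recombination-rate proxy is cM/Mb evaluated in 50 windows per
chromosome, each spanning 2% of the chromosome's physical length, from a
piecewise-linear interpolation of genetic position against physical
position (Marey map) restricted to concordant markers.  Window rates are
folded by distance to the nearest telomere into 25 two-percent bins and
averaged across chromosomes, separating the sexes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

N_WINDOWS = 50  # each window = 2% of the chromosome


@dataclass
class MareyInterpolator:
    """Piecewise-linear cM(bp) for one chromosome and sex; constant beyond
    the terminal markers (rate 0 outside the mapped span)."""

    bp: np.ndarray
    cM: np.ndarray

    @classmethod
    def build(cls, bp: np.ndarray, cM: np.ndarray) -> "MareyInterpolator | None":
        if len(bp) < 2:
            return None
        order = np.argsort(bp)
        bp, cM = np.asarray(bp, float)[order], np.asarray(cM, float)[order]
        # orientation is arbitrary: flip so cM increases with bp
        if cM[-1] < cM[0]:
            cM = cM[0] - cM
        cM = np.maximum.accumulate(cM - cM[0])
        return cls(bp, cM)

    def __call__(self, query_bp) -> np.ndarray:
        return np.interp(np.asarray(query_bp, dtype=float), self.bp, self.cM)

    @property
    def span(self) -> tuple[float, float]:
        return float(self.bp[0]), float(self.bp[-1])


def interpolate_cM(
    genetic_map: pd.DataFrame,
    placements: pd.DataFrame,
    concordant_ids: list[str],
    sex: str,
) -> MareyInterpolator | None:
    """Marey interpolator from a chromosome's concordant marker subset."""
    col = "male_cM" if sex == "M" else "female_cM"
    ids = [m for m in concordant_ids if m in genetic_map.index]
    if len(ids) < 2:
        return None
    bp = placements.loc[ids, "pos"].to_numpy(dtype=float)
    cm = genetic_map.loc[ids, col].to_numpy(dtype=float)
    return MareyInterpolator.build(bp, cm)


def window_rates(
    chrom: str,
    length_bp: int,
    interpolators: dict[str, MareyInterpolator | None],
    marker_bp: np.ndarray,
) -> pd.DataFrame:
    """cM/Mb per 2%-length window and sex.

    A window is *defined* when at least 90% of its span lies inside the
    mapped marker span; windows outside it report rate 0 and are flagged.
    """
    edges = np.linspace(0.0, float(length_bp), N_WINDOWS + 1)
    starts, ends = edges[:-1], edges[1:]
    mb = (ends - starts) / 1e6
    out = {
        "chrom": chrom,
        "window": np.arange(1, N_WINDOWS + 1),
        "start": starts.astype(int),
        "end": ends.astype(int),
        "support": [
            int(((marker_bp >= a) & (marker_bp < b)).sum()) for a, b in zip(starts, ends)
        ],
    }
    for sex, col in (("M", "male_cM_per_Mb"), ("F", "female_cM_per_Mb")):
        ip = interpolators.get(sex)
        if ip is None:
            out[col] = np.full(N_WINDOWS, np.nan)
            out[f"{'male' if sex == 'M' else 'female'}_defined"] = np.zeros(
                N_WINDOWS, dtype=bool
            )
            continue
        rate = (ip(ends) - ip(starts)) / mb
        lo, hi = ip.span
        # windows substantially outside the mapped span report rates diluted
        # by the zero-rate extrapolation zone, so they are flagged undefined
        overlap = np.minimum(ends, hi) - np.maximum(starts, lo)
        defined = overlap >= 0.9 * (ends - starts)
        out[col] = rate
        out[f"{'male' if sex == 'M' else 'female'}_defined"] = defined
    return pd.DataFrame(out)


def telomere_profile(windows: pd.DataFrame) -> pd.DataFrame:
    """Fold window rates by distance to the nearest chromosome end.

    Window k of 50 lands in distance bin min(k, 51-k) of 25; bin means are
    unweighted over defined windows across chromosomes, per sex.
    """
    w = windows.copy()
    w["bin"] = np.minimum(w["window"], N_WINDOWS + 1 - w["window"])
    rows = []
    for b in range(1, N_WINDOWS // 2 + 1):
        sub = w[w["bin"] == b]
        vals = {}
        for sex, col, dcol in (
            ("male", "male_cM_per_Mb", "male_defined"),
            ("female", "female_cM_per_Mb", "female_defined"),
        ):
            ok = sub[sub[dcol].fillna(False)] if dcol in sub else sub.iloc[0:0]
            vals[f"{sex}_mean"] = float(ok[col].mean()) if len(ok) else np.nan
            vals[f"{sex}_n"] = len(ok)
        rows.append(
            {
                "bin": b,
                "dist_pct_lo": 2.0 * (b - 1),
                "dist_pct_hi": 2.0 * b,
                **vals,
            }
        )
    return pd.DataFrame(rows)


def landscape_windows(
    genetic_map: pd.DataFrame,
    placements: pd.DataFrame,
    concordant: dict[str, list[str]],
    chromosome_lengths: dict[str, int],
    gm=None,
    error_rate: float | str = "profile",
) -> pd.DataFrame:
    """Window rates for every chromosome with a usable Marey map.

    When the genotype matrix ``gm`` is given, the genetic axis of each
    Marey map is re-estimated along the concordant markers in physical
    order (see :func:`salmap.linkage.marey_tracks`), so that map-length
    artifacts from excluded discordant markers do not inflate local
    rates; otherwise the map's cumulative cM positions are used as-is.
    """
    frames = []
    res = placements[placements["status"].isin(("unique", "resolved_by_linkage"))]
    tracks = None
    if gm is not None:
        from .linkage import marey_tracks

        ordered = {}
        for chrom, ids in concordant.items():
            ids = [m for m in ids if m in res.index and m in genetic_map.index]
            ordered[chrom] = sorted(ids, key=lambda m: res.loc[m, "pos"])
        tracks = marey_tracks(gm, ordered, error_rate=error_rate)
    for chrom, ids in concordant.items():
        length = chromosome_lengths.get(chrom)
        if length is None:
            continue
        if tracks is not None:
            tr = tracks.get(chrom)
            if tr is None:
                interps = {"M": None, "F": None}
            else:
                bp = res.loc[tr.index, "pos"].to_numpy(float)
                interps = {
                    sex: MareyInterpolator.build(bp, tr[col].to_numpy(float))
                    for sex, col in (("M", "male_cM"), ("F", "female_cM"))
                }
        else:
            interps = {
                sex: interpolate_cM(genetic_map, res, ids, sex) for sex in ("M", "F")
            }
        on_chrom = res[res["target"] == chrom]
        frames.append(
            window_rates(chrom, length, interps, on_chrom["pos"].to_numpy(float))
        )
    return (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(
            columns=["chrom", "window", "start", "end", "support",
                     "male_cM_per_Mb", "male_defined",
                     "female_cM_per_Mb", "female_defined"]
        )
    )


def subtelomeric_fold(
    profile: pd.DataFrame,
    sex: str = "male",
    subtelomeric_fraction: float = 0.1,
    interior_bins: int = 5,
) -> float:
    """Mean rate in bins inside the subtelomeric zone divided by the mean
    over the innermost ``interior_bins`` bins."""
    n_sub = max(1, int(round(subtelomeric_fraction * N_WINDOWS)))  # 2% bins
    col = f"{sex}_mean"
    sub = profile[profile["bin"] <= n_sub][col].dropna()
    interior = profile[profile["bin"] > N_WINDOWS // 2 - interior_bins][col].dropna()
    if not len(sub) or not len(interior) or interior.mean() == 0:
        return float("nan")
    return float(sub.mean() / interior.mean())


def summarize_maps(
    genetic_map: pd.DataFrame,
    assembled_bp: int | None = None,
    anchors=None,
) -> dict:
    """Map-level summary: per-group maxima, per-sex totals, female:male
    ratio, SNP densities, anchored-contig totals."""
    if len(genetic_map) == 0:
        raise ValueError("empty genetic map")
    per_group = genetic_map.groupby("linkage_group").agg(
        n_snps=("order_index", "size"),
        male_max_cM=("male_cM", "max"),
        female_max_cM=("female_cM", "max"),
    )
    total_m = float(per_group["male_max_cM"].sum())
    total_f = float(per_group["female_max_cM"].sum())
    n_snps = int(per_group["n_snps"].sum())
    out = {
        "n_groups": int(len(per_group)),
        "n_snps": n_snps,
        "male_total_cM": total_m,
        "female_total_cM": total_f,
        "female_male_ratio": total_f / total_m if total_m > 0 else float("nan"),
        "per_group": per_group,
        "male_cM_per_snp": total_m / n_snps if n_snps else float("nan"),
        "female_cM_per_snp": total_f / n_snps if n_snps else float("nan"),
    }
    if assembled_bp is not None and n_snps:
        out["kb_per_snp"] = assembled_bp / n_snps / 1e3
    if anchors is not None:
        out["anchored_contigs"] = anchors.n_anchored
        out["anchored_bp"] = anchors.anchored_bp
        out["anchored_fraction_of_unplaced"] = anchors.anchored_fraction
    return out
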