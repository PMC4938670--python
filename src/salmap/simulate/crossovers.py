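"""Sex-specific crossover landscapes and meiosis simulation.

The landscape is a piecewise-constant crossover intensity (cM/Mb) over
physical position, one track per chromosome and sex.  The female track is
flat; the male track has elevated intensity in the subtelomeric zone at
each chromosome end, emulating the strong male subtelomeric recombination
peak of salmonids.  Crossovers are laid down as a Poisson process along
the genetic (cM) axis — no interference — which matches the Haldane map
function used when maps are rebuilt from genotypes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

MALE, FEMALE = "M", "F"


@dataclass
class ChromLandscape:
    """One chromosome, one sex: intensity ``rates[k]`` on [breaks[k], breaks[k+1])."""

    breaks: np.ndarray  # bp edges, breaks[0] = 0, breaks[-1] = chromosome length
    rates: np.ndarray   # cM/Mb per segment, len(breaks) - 1

    def __post_init__(self):
        self.breaks = np.asarray(self.breaks, dtype=float)
        self.rates = np.asarray(self.rates, dtype=float)
        if (self.rates < 0).any():
            raise ValueError("crossover intensities must be >= 0")
        # cumulative genetic position (cM) at each break
        seg_cm = np.diff(self.breaks) / 1e6 * self.rates
        self.cum_cM_at_breaks = np.concatenate([[0.0], np.cumsum(seg_cm)])

    @property
    def length_bp(self) -> float:
        return float(self.breaks[-1])

    @property
    def genetic_length_cM(self) -> float:
        return float(self.cum_cM_at_breaks[-1])

    def cum_cM(self, bp) -> np.ndarray:
        """Genetic position (cM) at physical position(s) ``bp``."""
        bp = np.asarray(bp, dtype=float)
        seg = np.clip(np.searchsorted(self.breaks, bp, side="right") - 1, 0, len(self.rates) - 1)
        return self.cum_cM_at_breaks[seg] + (bp - self.breaks[seg]) / 1e6 * self.rates[seg]

    def bp_at_cM(self, cm) -> np.ndarray:
        """Inverse of :meth:`cum_cM` (requires strictly positive rates)."""
        cm = np.asarray(cm, dtype=float)
        seg = np.clip(
            np.searchsorted(self.cum_cM_at_breaks, cm, side="right") - 1, 0, len(self.rates) - 1
        )
        with np.errstate(divide="ignore", invalid="ignore"):
            off = (cm - self.cum_cM_at_breaks[seg]) / self.rates[seg] * 1e6
        return self.breaks[seg] + np.where(np.isfinite(off), off, 0.0)

    def rate_at(self, bp) -> np.ndarray:
        bp = np.asarray(bp, dtype=float)
        seg = np.clip(np.searchsorted(self.breaks, bp, side="right") - 1, 0, len(self.rates) - 1)
        return self.rates[seg]


@dataclass
class RecombinationLandscape:
    """Per-chromosome, per-sex crossover intensity tracks."""

    tracks: dict[tuple[str, str], ChromLandscape] = field(default_factory=dict)

    def track(self, chrom: str, sex: str) -> ChromLandscape:
        return self.tracks[(chrom, sex)]

    def genetic_length(self, chrom: str, sex: str) -> float:
        return self.track(chrom, sex).genetic_length_cM

    def total_length(self, sex: str) -> float:
        return sum(t.genetic_length_cM for (c, s), t in self.tracks.items() if s == sex)

    def chromosomes(self) -> list[str]:
        return sorted({c for c, _ in self.tracks})


def default_landscape(
    chromosome_lengths: dict[str, int],
    male_interior_rate: float = 1.0,
    male_subtelomeric_factor: float = 10.0,
    subtelomeric_fraction: float = 0.1,
    target_length_ratio: float = 1.5,
    female_base_rate: float | None = None,
) -> RecombinationLandscape:
    """Build the default heterochiasmic landscape.

    Male: ``male_interior_rate`` cM/Mb in the chromosome interior, elevated
    ``male_subtelomeric_factor``-fold over the outer ``subtelomeric_fraction``
    of the chromosome at each end.  Female: flat.  Unless given explicitly,
    the female rate is derived so that the female:male total genetic length
    equals ``target_length_ratio`` exactly.
    """
    if not 0.0 < subtelomeric_fraction < 0.5:
        raise ValueError("subtelomeric_fraction must be in (0, 0.5)")
    f = subtelomeric_fraction
    # male genome-average rate relative to the interior rate
    male_avg = male_interior_rate * (1.0 - 2.0 * f + 2.0 * f * male_subtelomeric_factor)
    if female_base_rate is None:
        female_base_rate = target_length_ratio * male_avg
    ls = RecombinationLandscape()
    for chrom, length in chromosome_lengths.items():
        if length <= 0:
            raise ValueError(f"chromosome {chrom} has non-positive length")
        a, b = f * length, (1.0 - f) * length
        ls.tracks[(chrom, MALE)] = ChromLandscape(
            breaks=np.array([0.0, a, b, float(length)]),
            rates=np.array(
                [
                    male_interior_rate * male_subtelomeric_factor,
                    male_interior_rate,
                    male_interior_rate * male_subtelomeric_factor,
                ]
            ),
        )
        ls.tracks[(chrom, FEMALE)] = ChromLandscape(
            breaks=np.array([0.0, float(length)]), rates=np.array([female_base_rate])
        )
    return ls


def sample_crossovers(track: ChromLandscape, rng: np.random.Generator) -> np.ndarray:
    """Crossover positions (bp) for one meiosis on one chromosome.

    The count is Poisson with mean equal to the genetic length in Morgans;
    positions are drawn proportional to local intensity by inverting the
    cumulative genetic map.
    """
    if track.length_bp <= 0:
        raise ValueError("zero-length chromosome")
    g = track.genetic_length_cM
    n = rng.poisson(g / 100.0)
    if n == 0 or g == 0.0:
        return np.empty(0)
    return np.sort(track.bp_at_cM(rng.uniform(0.0, g, size=n)))


def gamete(
    hap_pair: tuple[np.ndarray, np.ndarray],
    marker_bp: np.ndarray,
    crossovers: np.ndarray,
    start_phase: int,
) -> np.ndarray:
    """Transmitted alleles at ``marker_bp`` given crossover positions.

    ``start_phase`` selects the haplotype transmitted at position 0; each
    crossover toggles it.
    """
    phase = (start_phase + np.searchsorted(crossovers, marker_bp)) % 2
    return np.where(phase == 0, hap_pair[0], hap_pair[1])


def simulate_meiosis(
    hap_pair: tuple[np.ndarray, np.ndarray],
    track: ChromLandscape,
    marker_bp: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """One meiosis: returns (transmitted alleles, crossover positions)."""
    xo = sample_crossovers(track, rng)
    return gamete(hap_pair, marker_bp, xo, int(rng.integers(2))), xo
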