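"""Synthetic study generator: genome, landscapes, pedigree, genotypes,
flanks, gene models — with generation-time truth for testing every
downstream stage.

:func:`simulate_study` is the orchestrator; the order matters (gene models
rewrite exonic sequence in place, so marker flanks are extracted after
gene placement).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .crossovers import (
    FEMALE,
    MALE,
    ChromLandscape,
    RecombinationLandscape,
    default_landscape,
    gamete,
    sample_crossovers,
    simulate_meiosis,
)
from .genes import GeneSet, canonical_transcript, generate_gene_models, true_effects
from .genome import Contig, SimulatedGenome, decode, encode, generate_genome, reverse_complement
from .markers import TruthSet, extract_flanks, sample_marker_sites, simulate_genotypes
from .pedigree import PedigreeSpec

__all__ = [
    "FEMALE",
    "MALE",
    "ChromLandscape",
    "Contig",
    "GeneSet",
    "PedigreeSpec",
    "RecombinationLandscape",
    "SimulatedGenome",
    "StudyConfig",
    "Fixture",
    "TruthSet",
    "canonical_transcript",
    "decode",
    "default_landscape",
    "encode",
    "extract_flanks",
    "gamete",
    "generate_gene_models",
    "generate_genome",
    "reverse_complement",
    "sample_crossovers",
    "sample_marker_sites",
    "simulate_meiosis",
    "simulate_genotypes",
    "simulate_study",
    "true_effects",
]


@dataclass
class StudyConfig:
    """Desk-scale defaults: 5 chromosomes of ~20 Mb, 2000 markers, 10 sires /
    20 dams / 8 offspring per family, 22% of sequence held out unplaced."""

    n_chrom: int = 5
    length_range: tuple[int, int] = (18_000_000, 22_000_000)
    unplaced_fraction: float = 0.22
    contig_length_range: tuple[int, int] = (50_000, 300_000)
    n_markers: int = 2000
    maf_distribution: object = (0.05, 0.5)
    genotyping_error_rate: float = 0.005
    missing_rate: float = 0.01
    include_contig_markers: bool = True
    n_genes: int = 40
    pedigree: PedigreeSpec = field(default_factory=PedigreeSpec)
    # landscape parameters
    male_interior_rate: float = 1.0
    male_subtelomeric_factor: float = 10.0
    subtelomeric_fraction: float = 0.1
    target_length_ratio: float = 1.5
    female_base_rate: float | None = None


@dataclass
class Fixture:
    config: StudyConfig
    genome: SimulatedGenome
    landscape: RecombinationLandscape
    genes: GeneSet
    gm: object            # GenotypeMatrix
    flanks: object        # DataFrame
    truth: TruthSet


def simulate_study(config: StudyConfig | None = None, seed: int = 0) -> Fixture:
    """Generate a complete, self-consistent fixture set with known truth."""
    config = config or StudyConfig()
    genome = generate_genome(
        n_chrom=config.n_chrom,
        length_range=config.length_range,
        unplaced_fraction=config.unplaced_fraction,
        seed=seed,
        contig_length_range=config.contig_length_range,
    )
    genes = (
        generate_gene_models(genome, config.n_genes, seed=seed + 1)
        if config.n_genes > 0
        else GeneSet()
    )
    landscape = default_landscape(
        genome.chromosome_lengths,
        male_interior_rate=config.male_interior_rate,
        male_subtelomeric_factor=config.male_subtelomeric_factor,
        subtelomeric_fraction=config.subtelomeric_fraction,
        target_length_ratio=config.target_length_ratio,
        female_base_rate=config.female_base_rate,
    )
    gm, flanks, truth = simulate_genotypes(
        genome,
        landscape,
        config.pedigree,
        n_markers=config.n_markers,
        maf_distribution=config.maf_distribution,
        genotyping_error_rate=config.genotyping_error_rate,
        missing_rate=config.missing_rate,
        seed=seed + 2,
        include_contigs=config.include_contig_markers,
    )
    eff = true_effects(genes, genome, truth.markers)
    truth.markers["effect"] = eff["effect"]
    truth.markers["gene"] = eff["gene"]
    truth.genes = genes
    return Fixture(config, genome, landscape, genes, gm, flanks, truth)
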