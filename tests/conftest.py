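import numpy as np
import pytest

from salmap.simulate import PedigreeSpec, StudyConfig, simulate_study


@pytest.fixture(scope="session")
def small_fixture():
    """3 chromosomes x ~1 Mb, 150 markers, 15% unplaced, 120 offspring."""
    cfg = StudyConfig(
        n_chrom=3,
        length_range=(900_000, 1_100_000),
        unplaced_fraction=0.15,
        contig_length_range=(20_000, 60_000),
        n_markers=150,
        n_genes=10,
        maf_distribution=(0.2, 0.5),
        pedigree=PedigreeSpec(6, 12, 10),
    )
    return simulate_study(cfg, seed=7)


@pytest.fixture(scope="session")
def clean_fixture():
    """Error-free, fully genotyped fixture with intermediate MAF."""
    cfg = StudyConfig(
        n_chrom=3,
        length_range=(3_800_000, 4_200_000),
        unplaced_fraction=0.1,
        contig_length_range=(60_000, 200_000),
        n_markers=36,
        n_genes=0,
        maf_distribution=(0.25, 0.5),
        genotyping_error_rate=0.0,
        missing_rate=0.0,
        pedigree=PedigreeSpec(10, 20, 60),
    )
    return simulate_study(cfg, seed=13)


@pytest.fixture(scope="session")
def gene_fixture():
    """Gene-dense tiny genome for annotation tests."""
    cfg = StudyConfig(
        n_chrom=2,
        length_range=(400_000, 500_000),
        unplaced_fraction=0.0,
        n_markers=500,
        n_genes=60,
        pedigree=PedigreeSpec(2, 4, 4),
    )
    return simulate_study(cfg, seed=11)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
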