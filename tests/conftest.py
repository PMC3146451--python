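import pytest

from islandmob import pipeline
from islandmob import synthetic_data as sd


@pytest.fixture(scope="session")
def island_genome():
    """Default three-feature synthetic genome: one module+cargo island."""
    return sd.generate_island_genome(sd.IslandSimSpec(seed=11))


@pytest.fixture(scope="session")
def two_island_genome():
    spec = sd.IslandSimSpec(
        seed=7, genome_length=45_000,
        islands=[sd.IslandSpec(length=12_000),
                 sd.IslandSpec(length=9_000, has_module=False, cargo=None,
                               repeat_mismatches=2)])
    return sd.generate_island_genome(spec)


@pytest.fixture(scope="session")
def scanned_two_island(two_island_genome, tmp_path_factory):
    genome, truth = two_island_genome
    cfg = pipeline.RunConfig(out_dir=str(tmp_path_factory.mktemp("scan")))
    return pipeline.scan_genome(genome, cfg), truth


@pytest.fixture(scope="session")
def cargo_alignment():
    return sd.generate_cargo_alignment(8, 1560, leader_rate=0.05,
                                       body_rate=0.003, seed=21)


@pytest.fixture(scope="session")
def strain_pair():
    return sd.generate_strain_pair(genome_length=20_000, n_events=192,
                                   seed=13)
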