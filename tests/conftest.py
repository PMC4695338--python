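import dataclasses

import pytest
from hypothesis import HealthCheck, settings

import ieskit as ik

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_params() -> ik.SimulationParams:
    """Desk-scale genome small enough for per-test simulation."""
    return ik.SimulationParams(
        seed=11, genome_length=500_000, n_ies=40, depth=20.0, read_length=50
    )


@pytest.fixture(scope="session")
def small_genome(small_params) -> ik.GenomeModel:
    return ik.generate_genome(small_params)


@pytest.fixture(scope="session")
def study_params() -> ik.SimulationParams:
    """The full study conditions: 5 Mb, 300 IESs, 1/3 IES fraction, 20x, 50 nt."""
    return ik.SimulationParams(seed=1, genome_length=5_000_000, n_ies=300)


@pytest.fixture(scope="session")
def study_genome(study_params) -> ik.GenomeModel:
    return ik.generate_genome(study_params)


@pytest.fixture(scope="session")
def study_mic_coverage(study_genome, study_params) -> ik.CoverageTable:
    reads = ik.simulate_wgs(study_genome, study_params, "MIC", label="MIC")
    return ik.count_reads(reads, study_genome.intervals, sample="MIC")


def newmac_coverage(genome, params, retained, contamination, label):
    p = dataclasses.replace(
        params,
        contamination=contamination,
        elimination_status=ik.default_elimination(genome, retained),
    )
    reads = ik.simulate_wgs(genome, p, "newMAC", label=label)
    return ik.count_reads(reads, genome.intervals, sample=label)
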