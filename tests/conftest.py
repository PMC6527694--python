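import pytest

import atacatlas as aa


@pytest.fixture(scope="session")
def small_config() -> aa.SimulationConfig:
    """A cheap 4-tissue atlas used by unit tests."""
    return aa.SimulationConfig(
        n_tissues=4,
        n_chromosomes=2,
        chromosome_length=2_000_000,
        n_shared_peaks=60,
        n_restricted_peaks=20,
        n_tss=60,
        fragments_per_sample=30_000,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_atlas(small_config) -> aa.SimulatedAtlas:
    return aa.simulate_atlas(small_config)


@pytest.fixture(scope="session")
def default_atlas() -> aa.SimulatedAtlas:
    """The full study-scale panel: 20 tissues x 2 replicates."""
    return aa.simulate_atlas(aa.SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def default_counts(default_atlas) -> aa.CountsMatrix:
    """Counts over the true peak set for the study-scale panel."""
    return aa.build_counts_matrix(
        default_atlas.fragments,
        default_atlas.truth.peaks,
        library_sizes={r.sample_id: r.usable_reads for r in default_atlas.records},
    )
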