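import pytest

from exofeed.simulate import (
    LibrarySpec,
    SimulationConfig,
    default_library_design,
    simulate_dataset,
)


def three_vs_three(condition: str = "ND169_KD") -> tuple[LibrarySpec, ...]:
    """One serotype, 3 WT + 3 feeding replicates."""
    libs = [LibrarySpec(f"51A_WT_r{i}", "51A", "WT", i) for i in (1, 2, 3)]
    libs += [LibrarySpec(f"51A_{condition}_r{i}", "51A", condition, i) for i in (1, 2, 3)]
    return tuple(libs)


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A tiny but complete study: 2 serotypes, 3 conditions, 2 replicates."""
    return SimulationConfig(
        seed=42,
        n_scaffolds=2,
        scaffold_length=120_000,
        n_loci=60,
        n_free_genes=10,
        n_background_loci=10,
        depth=30_000,
        library_design=default_library_design(("51A", "51B"), 2),
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_dataset(small_config)
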