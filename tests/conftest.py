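import pytest

from epimark.synthetic import SimulationConfig, simulate_dataset

SMALL_MARKS = ("H3K27ac", "H3K4me1")


def small_config(**overrides) -> SimulationConfig:
    """A fast, fully featured dataset: 2 chromosomes, 300 genes, 2 marks."""
    base = dict(
        seed=11,
        n_chroms=2,
        chrom_length=3_000_000,
        n_genes=300,
        n_peaks_per_mark={m: 300 for m in SMALL_MARKS},
        conditions=("control", "Fe2O3", "FeSO4"),
        replicates_per_condition=2,
        n_kdd=4,
        kdd_length_range=(100_000, 200_000),
    )
    base.update(overrides)
    return SimulationConfig(**base)


@pytest.fixture(scope="session")
def small_bundle():
    return simulate_dataset(small_config())
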