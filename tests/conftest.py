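import pytest

from ilstools.synth import SynthConfig, generate_dataset


@pytest.fixture(scope="session")
def small_null_dataset():
    """A reduced pure-ILS dataset (no injected sites) shared by tests."""
    cfg = SynthConfig(n_genes=40, codons_per_gene=40, seed=202)
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def injected_dataset():
    """Low-background dataset with ten injected group-diagnostic sites."""
    cfg = SynthConfig(
        n_genes=20,
        codons_per_gene=50,
        mutation_rate=0.002,
        n_injected_sites=10,
        missingness_rate=0.0,
        seed=77,
    )
    return generate_dataset(cfg)
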