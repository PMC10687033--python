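import pytest

from clonotrace import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small but structured cohort shared by read-only tests."""
    config = CohortConfig(
        n_patients=6,
        cells_per_tumour=300,
        cells_per_pbmc=600,
        n_samples_bulk=60,
        n_genes_bulk=300,
        seed=11,
    )
    return generate_cohort(config)
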