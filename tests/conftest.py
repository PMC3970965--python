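import pytest
from hypothesis import settings

from dicistro import synthetic_data

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def toy():
    """Default toy dicistronic genome with its truth annotation."""
    record, truth = synthetic_data.build_toy_genome(synthetic_data.ToyGenomeSpec())
    return record, truth


@pytest.fixture(scope="session")
def toy_exact_dup():
    """Toy genome whose internal 5'-terminal duplicate has zero mismatches."""
    spec = synthetic_data.ToyGenomeSpec(dup_mismatches=0, seed=7)
    record, truth = synthetic_data.build_toy_genome(spec)
    return record, truth
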