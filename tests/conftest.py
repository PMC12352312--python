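import pytest

from sheetscribe.synthdata import NoiseModel, generate_batch
from sheetscribe.taxonmatch import ReferenceLists


@pytest.fixture(scope="session")
def refs() -> ReferenceLists:
    return ReferenceLists.bundled_fixture()


@pytest.fixture(scope="session")
def clean_batch():
    """Small zero-noise synthetic batch shared across tests."""
    return generate_batch(6, seed=42)


@pytest.fixture(scope="session")
def clean_truth(clean_batch):
    return {sheet_id: truth for sheet_id, _, truth in clean_batch}


@pytest.fixture(scope="session")
def noisy_batch():
    """Batch whose printed taxon names carry misspellings."""
    return generate_batch(8, seed=43, noise=NoiseModel(char_sub_rate=0.1))
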