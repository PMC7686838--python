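import sys
from pathlib import Path

import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

sys.path.insert(0, str(Path(__file__).parent))  # makes `oracle` importable

from scaffquery.chemstruct import standardize_all
from scaffquery.synthetic import ChemotypeLibrarySpec, generate_chemotype_library


@pytest.fixture(scope="session")
def library_spec() -> ChemotypeLibrarySpec:
    """The study conditions: 5 scaffold families x 8 analogs + 50 decoys,
    with planted salts, stereocenters and charges."""
    return ChemotypeLibrarySpec(rng_seed=2020)


@pytest.fixture(scope="session")
def synthetic_library(library_spec):
    return generate_chemotype_library(library_spec)


@pytest.fixture(scope="session")
def standardized_library(synthetic_library):
    records, truth = synthetic_library
    accepted, quarantined = standardize_all(records)
    return accepted, quarantined, truth
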