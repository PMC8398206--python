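import pandas as pd
import pytest

from dftbench.descriptors import default_catalog, feature_table
from dftbench.error_metrics import default_references
from dftbench.synthetic import SyntheticConfig, generate_errors


@pytest.fixture(scope="session")
def catalog():
    return default_catalog()


@pytest.fixture(scope="session")
def references():
    return default_references()


@pytest.fixture(scope="session")
def features(catalog) -> pd.DataFrame:
    return feature_table(catalog)


@pytest.fixture(scope="session")
def noisy_errors() -> pd.DataFrame:
    """One seeded error grid shared by tests that only need realistic data."""
    return generate_errors(SyntheticConfig(seed=11))
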