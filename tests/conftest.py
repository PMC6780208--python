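import numpy as np
import pytest

from cellulosomics import DetectionConfig, load_table1_fixture
from cellulosomics.references import reference_profiles, repeat_profile


@pytest.fixture(scope="session")
def table1():
    return load_table1_fixture()


@pytest.fixture(scope="session")
def profiles():
    """Packaged synthetic detection profiles for the core module classes."""
    return reference_profiles(["Coh1", "Coh2", "Doc1", "XDoc2", "CBM3"])


@pytest.fixture(scope="session")
def doc_repeat_profile():
    return repeat_profile("I")


@pytest.fixture()
def det_config():
    return DetectionConfig(random_seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
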