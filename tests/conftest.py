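import numpy as np
import pytest

from traumaprog import synthetic_cohort as sc


@pytest.fixture(scope="session")
def demo_cohort():
    """Default-sized synthetic cohort (108/130/54) shared across tests."""
    spec = sc.CohortSpec(seed=42)
    records = sc.generate_cohort(spec)
    return spec, records


@pytest.fixture(scope="session")
def demo_frame(demo_cohort):
    _, records = demo_cohort
    return sc.cohort_to_frame(records)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
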