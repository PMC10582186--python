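import pytest

from mehgrid import synthetic_data as sd


@pytest.fixture(scope="session")
def small_region():
    return sd.make_region(2, 2, (12, 12), seed=3)


@pytest.fixture(scope="session")
def noise_free_inputs(small_region):
    """All observations equal ground truth: no noise, no missingness."""
    return sd.simulate_inputs(
        small_region, (2010, 2014), noise_cv=0.0, seed=3, duplicate_frac=0.0
    )
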