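import pytest

from cherryripe import (
    MaturityCriteria,
    RipeningParams,
    aggregate_median,
    simulate_orchard,
    true_curves,
)

#: Simulation day of the first observation in the default window; the
#: aggregated series re-anchors its time axis there, so series day d
#: corresponds to simulation day d + START_DAY.
START_DAY = -8.0


@pytest.fixture(scope="session")
def criteria():
    return MaturityCriteria()


@pytest.fixture(scope="session")
def reference_curves():
    """Noise-free NAI/NDVI curves with the default parameters (t0 at day 0)."""
    return true_curves(RipeningParams(), domain=(START_DAY, 18.0))


@pytest.fixture(scope="session")
def noise_free_dataset():
    return simulate_orchard(RipeningParams(noise_sd=0.0))


@pytest.fixture(scope="session")
def noise_free_series(noise_free_dataset):
    return aggregate_median(noise_free_dataset.records)
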