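import dataclasses

import pytest

from mprakit import synthetic_data


@pytest.fixture(scope="session")
def exact_config():
    """Tiny study conditions with sequencing error and overdispersion off."""
    return dataclasses.replace(
        synthetic_data.TINY, read_error_rate=0.0, nb_dispersion=0.0, seed=11
    )


@pytest.fixture(scope="session")
def exact_sim(exact_config):
    """(library, truth) for the exact tiny conditions; shared, read-only."""
    return synthetic_data.simulate_library(exact_config)


@pytest.fixture()
def toy_genome():
    return {"chr1": "A" * 300}
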