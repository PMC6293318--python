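import numpy as np
import pytest

import moodsig as ms


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small three-group cohort (order-only contrast dynamics)."""
    spec = ms.contrast_cohort_spec(n_per_group=8, days=110, seed=11)
    return ms.read_reports(ms.generate_cohort(spec))


@pytest.fixture(scope="session")
def tiny_buckets(tiny_cohort):
    return ms.bucketize(tiny_cohort)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
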