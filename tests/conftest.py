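import numpy as np
import pandas as pd
import pytest

import fetgrowth as fg

#: fast-but-adequate optimizer settings for simulation-heavy tests;
#: GLS coefficients are insensitive to the last digits of the variance
#: components, so a loose tolerance with a single start is sufficient
#: wherever only coefficients/p-values are inspected.
FAST_FIT = dict(xtol=1e-3, restarts=1, polish=False)


@pytest.fixture(scope="session")
def small_truth():
    return fg.DEFAULT_TRUTH.replace(n_fetuses=120)


@pytest.fixture(scope="session")
def small_cohort(small_truth):
    """A 120-fetus synthetic cohort with biometry, fixed seed."""
    return fg.simulate_cohort(small_truth, seed=7)


@pytest.fixture(scope="session")
def small_grs(small_cohort):
    return fg.compute_grs(small_cohort.dosages, small_cohort.panel)["score"]


@pytest.fixture(scope="session")
def unconditional_fit(small_cohort):
    model = fg.GrowthCurveModel.from_cohort(small_cohort, fg.GrowthModelSpec())
    return model.fit(**FAST_FIT)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
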