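import numpy as np
import pytest

from wpet import (PhantomSpec, build_template, make_analysis_mask,
                  simulate_cohort)


@pytest.fixture(scope="session")
def small_spec():
    """Small-grid phantom world used across the unit tests."""
    return PhantomSpec(grid_dims=(24, 28, 24), n_controls=8, n_carriers=6,
                       seed=11)


@pytest.fixture(scope="session")
def template(small_spec):
    return build_template(small_spec)


@pytest.fixture(scope="session")
def cohort(small_spec, template):
    return simulate_cohort(small_spec, template)


@pytest.fixture(scope="session")
def analysis_mask(template):
    return make_analysis_mask(template.gm_prob, template.atlas)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
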