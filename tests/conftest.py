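import numpy as np
import pandas as pd
import pytest

from pmbod.exposure import ExposureBin, ExposureDistribution
from pmbod.synthetic_data import (
    SyntheticExposureSpec,
    SyntheticHealthSpec,
    generate_exposure,
    generate_health_table,
)


def make_dist(rows, variant="central", population_total=None):
    """Build a distribution from (lower, upper, fraction) triples."""
    total = sum(r[2] for r in rows)
    bins = tuple(ExposureBin(lo, up, fr / total) for lo, up, fr in rows)
    return ExposureDistribution(bins=bins, variant=variant, population_total=population_total)


def random_dist(rng, n_bins=50, width=1.0):
    """Random contiguous distribution starting at 0 with n_bins bins."""
    fractions = rng.dirichlet(np.ones(n_bins))
    rows = [(i * width, (i + 1) * width, fractions[i]) for i in range(n_bins)]
    return make_dist(rows)


@pytest.fixture
def degenerate_at_5():
    return make_dist([(4.5, 5.5, 1.0)])


@pytest.fixture
def two_bin_symmetric():
    # mass at midpoints 0.5 and 9.5 only (zero-filled in between to keep
    # the bins contiguous): PWC exactly 5.0
    rows = [(i, i + 1, 0.5 if i in (0, 9) else 0.0) for i in range(10)]
    return make_dist(rows)


@pytest.fixture(scope="session")
def synthetic_variants():
    return generate_exposure(SyntheticExposureSpec(target_pwc=5.0, seed=1))


@pytest.fixture(scope="session")
def synthetic_dist(synthetic_variants):
    return synthetic_variants["central"]


@pytest.fixture(scope="session")
def health_table():
    return generate_health_table(SyntheticHealthSpec())


@pytest.fixture(scope="session")
def registry_table():
    return generate_health_table(
        SyntheticHealthSpec(with_ci=False, source="synthetic-registry")
    )


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def exposure_frame():
    return pd.DataFrame(
        {
            "lower_ugm3": [0.0, 1.0],
            "upper_ugm3": [1.0, 2.0],
            "fraction": [0.5, 0.5],
        }
    )
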