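import numpy as np
import pytest

from connpls import synthetic


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_regions():
    """Four regions in two networks for hand-checkable block averages."""
    return synthetic.make_region_table(4, n_networks=2, seed=0)


@pytest.fixture
def regions_cloud():
    """A 60-region random centroid cloud for spatial-null tests."""
    return synthetic.make_region_table(60, seed=7)


@pytest.fixture
def planted_cohort():
    """Medium cohort with a strong planted latent dimension."""
    return synthetic.generate_cohort(
        n_subjects=300, n_regions=8, n_behav=6, latent_strength=0.8, seed=11
    )


@pytest.fixture
def null_cohort():
    """Cohort with no latent structure and no confound effects."""
    return synthetic.generate_cohort(
        n_subjects=200, n_regions=7, n_behav=5, latent_strength=0.0, seed=13
    )


def standardize(m: np.ndarray) -> np.ndarray:
    return (m - m.mean(axis=0)) / m.std(axis=0, ddof=1)


@pytest.fixture
def std():
    return standardize
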