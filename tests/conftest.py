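import numpy as np
import pytest

from breastdensity import PhantomSpec, make_mammogram_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(20140715)


@pytest.fixture
def mammo_phantom():
    """A well-separated 2D phantom with exact planted gland fraction."""
    spec = PhantomSpec(
        shape=(160, 160), gland_fraction=0.40, gland_sd=30.0, fat_sd=30.0,
        seed=7,
    )
    record, truth, mask = make_mammogram_phantom(spec)
    return record, truth, mask


def sample_mixture_histogram(
    rng, n, fraction_gland, mu_gland, mu_fat, sigma, n_bins=256
):
    """Histogram of a two-Gaussian voxel sample with exact class counts."""
    n_gland = int(round(fraction_gland * n))
    gland = rng.normal(mu_gland, sigma, n_gland)
    fat = rng.normal(mu_fat, sigma, n - n_gland)
    vals = np.concatenate([gland, fat])
    counts, edges = np.histogram(vals, bins=n_bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, counts, n_gland / n
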