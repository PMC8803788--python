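import numpy as np
import pytest
from scipy import stats

from petdle.phantom import Ellipsoid, PhantomSpec, Sinogram, Sphere, thin_counts


def poisson_chi_square_p(fraction, seed_pair, lam=8.0, reps=2000):
    """Chi-square p value for 'thinned Poisson(lam) is Poisson(lam*fraction)'
    on a 5-bin table of 2000 replicates."""
    base_seed, thin_seed = seed_pair
    base = np.random.default_rng(base_seed).poisson(lam, reps)
    sino = Sinogram(counts=base.reshape(-1, 1, 1), duration_fraction=1.0,
                    scale=1.0, seed=0)
    thinned = thin_counts(sino, fraction, seed=thin_seed).counts.ravel()
    target = lam * fraction
    edges = [0, max(1, int(target - 2)), int(target), int(target + 2),
             int(target + 4), np.inf]
    obs = np.histogram(thinned, bins=edges)[0]
    cdf = stats.poisson(target).cdf
    probs = np.diff([0] + [cdf(e - 1) if np.isfinite(e) else 1.0
                           for e in edges[1:]])
    return stats.chisquare(obs, probs * reps).pvalue


@pytest.fixture(scope="session")
def tiny_spec():
    """16x16x16 phantom with one organ-like ellipsoid and one lesion."""
    return PhantomSpec(
        grid_shape=(16, 16, 16),
        voxel_size=(4.0, 4.0, 4.0),
        body=Ellipsoid(center=(7.5, 7.5, 7.5), semi_axes=(7.0, 6.5, 7.0),
                       suv=1.0, label="body"),
        organs=(Ellipsoid(center=(5.5, 7.5, 7.5), semi_axes=(3.0, 3.0, 3.5),
                          suv=2.5, label="liver"),),
        lesions=(Sphere(center=(10.0, 8.0, 8.0), radius=1.6, suv=8.0),),
        seed=0,
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20210728)
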