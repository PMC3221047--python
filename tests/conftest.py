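import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pcmodel import pairwise_distance_bins


def expected_pooled_acf(coords, edges, s):
    """Exact expectation of the pooled spatial ACF estimator for a kernel field.

    Accounts for per-row mean centring: with C the kernel matrix and H the
    centring projector, the centred field has covariance H C H, and the
    pooled estimator converges to the per-bin sum of Cc_ij normalized by
    the marginal sums.
    """
    from scipy.spatial.distance import pdist, squareform

    d = squareform(pdist(coords))
    C = np.exp(-(d**2) / (2.0 * s**2))
    p = len(coords)
    H = np.eye(p) - np.ones((p, p)) / p
    Cc = H @ C @ H
    pairs, _ = pairwise_distance_bins(coords, edges)
    out = []
    for pr in pairs:
        i, j = pr[:, 0], pr[:, 1]
        out.append(Cc[i, j].sum() / np.sqrt(Cc[i, i].sum() * Cc[j, j].sum()))
    return np.array(out)

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
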