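import numpy as np
import pytest
from scipy import stats

from fscshape.fcs_io import N_CHANNELS, Histogram


def density_histogram(mu_lower, mu_upper, sigma, weight_upper=0.5, n_events=50_000,
                      n_channels=N_CHANNELS):
    """Deterministic (noise-free) mixture histogram: expected per-channel
    counts of a two-Gaussian mixture, rounded to integers.

    Used where a property should hold exactly in the large-sample limit
    (e.g. monotone modality switching) without Monte-Carlo jitter.
    """
    edges = np.arange(n_channels + 1)
    cdf = lambda mu: stats.norm.cdf(edges, loc=mu, scale=sigma)  # noqa: E731
    p = (1 - weight_upper) * np.diff(cdf(mu_lower)) + weight_upper * np.diff(cdf(mu_upper))
    counts = np.rint(p * n_events).astype(np.int64)
    return Histogram(counts=counts)


def random_mixture_histogram(rng):
    """One random mixture histogram drawn from a broad parameter grid —
    bimodal, marginal and monomodal shapes all occur."""
    center = rng.uniform(80, 400)
    sep = rng.uniform(0, 120)
    sigma_lo = rng.uniform(4, 25)
    sigma_hi = rng.uniform(4, 25)
    w = rng.uniform(0.2, 0.8)
    n = int(rng.integers(2_000, 30_000))
    lo = rng.normal(center - sep / 2, sigma_lo, int(round(n * (1 - w))))
    hi = rng.normal(center + sep / 2, sigma_hi, n - lo.size)
    ch = np.clip(np.floor(np.concatenate([lo, hi])).astype(np.int64), 0, N_CHANNELS - 1)
    return Histogram(counts=np.bincount(ch, minlength=N_CHANNELS))


@pytest.fixture(scope="session")
def histogram_corpus():
    """200 random mixture histograms for oracle-equivalence checks."""
    rng = np.random.default_rng(20130321)
    return [random_mixture_histogram(rng) for _ in range(200)]
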