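import numpy as np
import pytest

from riskshare.synthetic import CategoryBlock, Member, SyntheticModel


def block_model(targets, ms, rhos, n=2000, extra_noise=None):
    """Model with mutually independent equicorrelated continuous blocks whose
    population LMG shares equal ``targets`` exactly (total outcome variance 1).

    For an equicorrelated block of m members with common latent effect b,
    the block's signal variance is b^2 * (m + m(m-1)rho); independence of
    blocks makes each block's LMG share equal its marginal R^2.
    """
    cats = []
    for k, (t, m, rho) in enumerate(zip(targets, ms, rhos), 1):
        b = np.sqrt(t / (m + m * (m - 1) * rho))
        cats.append(
            CategoryBlock(
                f"cat{k}", [Member(f"c{k}_{j}", effect=b) for j in range(m)], rho=rho
            )
        )
    noise = np.sqrt(1.0 - sum(targets)) if extra_noise is None else extra_noise
    return SyntheticModel(n_participants=n, categories=cats, noise_sd=noise)


@pytest.fixture
def recovery_model():
    return block_model([0.12, 0.06, 0.01], ms=[4, 3, 3], rhos=[0.5, 0.5, 0.5])


@pytest.fixture
def null_model():
    m = block_model([0.0, 0.0, 0.0], ms=[4, 3, 3], rhos=[0.5, 0.5, 0.5],
                    extra_noise=1.0, n=1000)
    return m


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
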