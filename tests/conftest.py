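import numpy as np
import pytest

from groupeqtl import EQTLDataset, ModelParams


def random_instance(rng, N=6, K=5, M=2, H=2, D=12,
                    sigma1_sq=0.8, sigma2_sq=1.2):
    """A random small dataset + parameter pair for oracle checks."""
    X = rng.integers(0, 3, (K, D)).astype(float)
    Z = rng.standard_normal((N, D))
    data = EQTLDataset(X=X, Z=Z)
    params = ModelParams(
        A=rng.standard_normal((M, K)),
        B=rng.standard_normal((N, M)),
        C=0.3 * rng.standard_normal((N, K)),
        W=0.5 * rng.standard_normal((N, H)),
        mu_B=np.zeros(N),
        sigma1_sq=sigma1_sq,
        sigma2_sq=sigma2_sq,
    )
    return data, params


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
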