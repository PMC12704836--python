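import numpy as np
import pandas as pd
import pytest

from freundlich_qsar import (
    DescriptorMatrix,
    SyntheticSpec,
    generate_descriptor_matrix,
    generate_linear_response,
    load_freundlich_table,
)

# Five planted descriptors used across recovery tests; coefficients are
# scaled so each term contributes comparably given its column's range.
PLANTED_BETA = {
    "sum_q(O+N)": -1.0,
    "q(CH+)_max": -10.0,
    "E_LUMO": 9.0,
    "Fukui(-)_max": -4.5,
    "Wiberg(C-C)_min": 0.6,
}


@pytest.fixture(scope="session")
def table():
    return load_freundlich_table()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_descriptors(n, p, seed):
    """Small unstructured descriptor matrix for oracle comparisons."""
    g = np.random.default_rng(seed)
    df = pd.DataFrame(
        g.standard_normal((n, p)),
        columns=[f"d{j + 1}" for j in range(p)],
        index=pd.Index([f"c{i + 1}" for i in range(n)], name="name"),
    )
    return DescriptorMatrix(df)


def planted_dataset(seed, n=38, noise_sd=0.02):
    """Synthetic descriptors plus a sparse planted linear response."""
    spec = SyntheticSpec(
        n_compounds=n,
        beta=PLANTED_BETA,
        intercept=1.0,
        noise_sd=noise_sd,
        seed=seed,
    )
    X = generate_descriptor_matrix(spec)
    y = generate_linear_response(X, spec)
    return X, y


@pytest.fixture
def planted():
    return planted_dataset(seed=11)
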