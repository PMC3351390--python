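import numpy as np
import pandas as pd
import pytest

import endopath as ep


@pytest.fixture(scope="session")
def yule17():
    """A fixed 17-tip pure-birth tree shared across signal tests."""
    return ep.simulate_yule(17, birth_rate=1.0, seed=42)


@pytest.fixture(scope="session")
def vcv17(yule17):
    V, order = ep.vcv(yule17, tuple(sorted(yule17.tip_labels)))
    return V, order


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def trait_table_vi():
    """A 17-species trait table drawn from the thermogenic-capacity model."""
    model = ep.model_zoo("VI", b3="covariance")
    return ep.simulate_traits(model, dict(ep.DEFAULT_THETA), 17, seed=7)


def random_correlation(p, rng):
    """A well-conditioned random correlation matrix."""
    A = rng.standard_normal((p, p + 3))
    S = A @ A.T
    d = np.sqrt(np.diag(S))
    return S / np.outer(d, d)


def table_from_matrix(X, columns):
    df = pd.DataFrame(np.asarray(X, float), columns=list(columns))
    return ep.prepare(ep.TraitTable(df))
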