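import numpy as np
import pandas as pd
import pytest

from tauscreen import make_fixture


@pytest.fixture(scope="session")
def small_fixture():
    return make_fixture("small")


@pytest.fixture(scope="session")
def paper_shaped_fixture():
    return make_fixture("paper_shaped", seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def random_matrix(rng):
    """A 50 x 5 strictly positive expression matrix."""
    values = rng.lognormal(mean=2.0, sigma=0.8, size=(50, 5))
    return pd.DataFrame(
        values,
        index=pd.Index([f"t{i:03d}" for i in range(50)], name="transcript_id"),
        columns=[f"tissue{j}" for j in range(5)],
    )
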