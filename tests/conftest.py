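import warnings

import numpy as np
import pandas as pd
import pytest

from tlsmeta.datatypes import GeneSet
from tlsmeta.synthetic import make_truth, simulate_cohorts


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    """Simulated matrices routinely contain constant/absent genes; the
    warnings are part of the contract but noise in the test log."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield


@pytest.fixture(scope="session")
def small_cohorts():
    """Three small cohorts with a planted program (gamma=2)."""
    truth = make_truth(n_signature=8, gamma=2.0, delta=0.5, seed=11)
    cohorts, truth = simulate_cohorts(3, [50, 60, 40], 80, truth, seed=11)
    return cohorts, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture()
def toy_zmatrix(rng):
    """10 genes x 6 samples of z-like values with some exact ties."""
    z = rng.normal(size=(10, 6))
    z[3, :] = z[7, :]  # duplicated row values create rank ties
    genes = [f"g{i}" for i in range(10)]
    return pd.DataFrame(z, index=genes, columns=[f"s{j}" for j in range(6)])


@pytest.fixture()
def toy_geneset():
    return GeneSet("toy", ("g1", "g3", "g8"))
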