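import numpy as np
import pandas as pd
import pytest

from placentaml.ga import GAConfig
from placentaml.modeling import ClassifierSpec


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def lda_spec():
    return ClassifierSpec(family="LDA")


@pytest.fixture
def tiny_ga_config():
    """Small, fast GA settings for unit-level runs."""
    return GAConfig(population_size=30, n_iterations=10, restart_period=5,
                    restart_elite=3, seed=0)


@pytest.fixture
def toy_training_data(rng):
    """20 samples x 8 count features with one separating column.

    F0 takes counts 4-6 for NC and 0-1 for C: perfectly separable, but with
    the within-class variation real fingerprint counts always carry.
    """
    X = pd.DataFrame(
        rng.poisson(1.0, size=(20, 8)),
        columns=[f"F{j}" for j in range(8)],
        index=[f"M{i}" for i in range(20)],
    ).astype(float)
    y = np.array(["NC"] * 5 + ["C"] * 15, dtype=object)
    X.loc[:, "F0"] = rng.integers(0, 2, size=20).astype(float)
    X.iloc[:5, 0] = [4.0, 5.0, 6.0, 5.0, 4.0]
    return X, pd.Series(y, index=X.index)
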