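import numpy as np
import pandas as pd
import pytest

from chlamydoe import build_design, load_published_models, table1_factors
from chlamydoe.design import DesignTable
from chlamydoe.validation import load_validation_points


@pytest.fixture(scope="session")
def factors():
    return table1_factors()


@pytest.fixture(scope="session")
def design(factors):
    return build_design(factors, seed=0)


@pytest.fixture(scope="session")
def models():
    return load_published_models()


@pytest.fixture(scope="session")
def validation_points():
    return load_validation_points()


@pytest.fixture(scope="session")
def random_design(factors):
    """A 200-row design with factor values spread over the whole space.

    Used where replicate structure and factorial geometry are irrelevant
    and a generic well-conditioned design is all that matters.
    """
    rng = np.random.default_rng(42)
    cols = {"run_id": np.arange(1, 201)}
    for f in factors:
        if f.is_continuous:
            cols[f.name] = rng.uniform(f.low, f.high, 200)
        else:
            cols[f.name] = rng.choice(f.levels, 200)
    return DesignTable(pd.DataFrame(cols), list(factors))
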