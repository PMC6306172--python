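import numpy as np
import pandas as pd
import pytest

from mantella.alkaloids import AlkaloidFeature, AlkaloidMatrix
from mantella.config import SyntheticConfig


@pytest.fixture
def default_cfg():
    return SyntheticConfig(seed=123)


@pytest.fixture
def small_matrix():
    """A tiny hand-built alkaloid matrix: 4 frogs x 3 features."""
    samples = pd.DataFrame({
        "frog_id": ["1001", "1002", "2001", "2002"],
        "season": ["dry", "dry", "wet", "wet"],
        "skin_mass_g": [0.2, 0.1, 0.25, 0.5],
    })
    features = [AlkaloidFeature("211A", "DHQ", "ant"),
                AlkaloidFeature("323A", "PTX", "mite"),
                AlkaloidFeature("999Z")]
    abundance = pd.DataFrame(
        [[100.0, 0.0, 50.0],
         [200.0, 10.0, 0.0],
         [50.0, 20.0, 0.0],
         [80.0, 40.0, 0.0]],
        index=pd.Index(samples["frog_id"], name="frog_id"),
        columns=[f.code for f in features],
    )
    return AlkaloidMatrix(samples=samples, features=features, abundance=abundance)
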