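import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20240126)


def annotated_frame(rows):
    """Build a minimal annotated table from (C,H,O,N,S,class,group) tuples."""
    df = pd.DataFrame(
        rows, columns=["C", "H", "O", "N", "S", "compound_class", "element_group"]
    )
    for col in "CHONS":
        df[col] = df[col].astype("Int64")
    return df


@pytest.fixture
def make_annotated():
    return annotated_frame
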