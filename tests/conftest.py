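import numpy as np
import pytest
from hypothesis import settings

from hybridfs import Dataset, SyntheticSpec, generate

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def tiny_csv(tmp_path):
    """3 samples x 2 features with a label column, the smallest legal dataset."""
    path = tmp_path / "tiny.csv"
    path.write_text("g1,g2,class\n1,2,A\n3,4,A\n5,6,B\n")
    return path


@pytest.fixture
def indicator_dataset():
    """Binary dataset where feature 'marker' equals the class indicator and
    'flat' is constant; n=20 balanced."""
    y = np.array(["pos"] * 10 + ["neg"] * 10)
    marker = (y == "pos").astype(float)
    flat = np.zeros(20)
    return Dataset(
        values=np.column_stack([marker, flat]),
        feature_names=["marker", "flat"],
        labels=y,
    )


@pytest.fixture(scope="session")
def synthetic_default():
    """The standard planted-signal study condition (n=100, m=200, 5 informative,
    effect 2.0, seed 7) shared across recovery tests."""
    return generate(SyntheticSpec(seed=7))
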