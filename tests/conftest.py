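import numpy as np
import pandas as pd
import pytest

from mcea import BlockConfig, BlockSpec, from_frame


@pytest.fixture
def toy_config() -> BlockConfig:
    """Two one-column numeric blocks plus a label column."""
    return BlockConfig(
        blocks=(
            BlockSpec("X1", "independent", ("a",)),
            BlockSpec("Y1", "dependent", ("b",)),
            BlockSpec("D", "description", ("label",)),
        ),
        label_column="label",
    )


@pytest.fixture
def toy_frame() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "a": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
            "b": [2.0, 4.0, 6.0, 8.0, 10.0, 12.0],
            "label": ["u", "u", "u", "v", "v", "v"],
        }
    )


@pytest.fixture
def toy_collection(toy_frame, toy_config):
    return from_frame(toy_frame, toy_config)


@pytest.fixture
def gaussian_classes():
    """Two well-separated 2-D Gaussian classes, 200 points each."""
    rng = np.random.default_rng(7)
    a = rng.standard_normal((200, 2))
    b = rng.standard_normal((200, 2)) + np.array([8.0, 0.0])
    scores = np.vstack([a, b])
    labels = ["A"] * 200 + ["B"] * 200
    return scores, labels
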