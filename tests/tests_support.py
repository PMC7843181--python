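"""Small shared constructors for test fixtures."""

import numpy as np
import pandas as pd

from mcea import BlockConfig, BlockSpec, from_frame


def make_two_column_collection(a, b=None):
    """One independent column ``a``, one dependent column ``b``, two classes."""
    n = len(a)
    frame = pd.DataFrame({
        "a": a,
        "b": b if b is not None else np.arange(n, dtype=float),
        "label": ["u"] * (n // 2) + ["v"] * (n - n // 2),
    })
    cfg = BlockConfig(
        blocks=(
            BlockSpec("X1", "independent", ("a",)),
            BlockSpec("Y1", "dependent", ("b",)),
            BlockSpec("D", "description", ("label",)),
        ),
        label_column="label",
    )
    return from_frame(frame, cfg)
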