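import numpy as np
import pandas as pd
import pytest

from stemprime.io import CountMatrix, ExpressionMatrix


@pytest.fixture
def small_counts() -> CountMatrix:
    values = pd.DataFrame(
        {
            "a1": [100, 50, 8, 0],
            "a2": [120, 40, 12, 2],
            "b1": [200, 45, 9, 1],
            "b2": [180, 55, 11, 0],
        },
        index=["g1", "g2", "g3", "g4"],
    )
    return CountMatrix(values, {"a1": "A", "a2": "A", "b1": "B", "b2": "B"})


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


def make_expression(arr, genes=None, samples=None, groups=None) -> ExpressionMatrix:
    arr = np.asarray(arr, dtype=float)
    genes = genes or [f"g{i}" for i in range(arr.shape[0])]
    samples = samples or [f"s{j}" for j in range(arr.shape[1])]
    groups = groups or {s: "all" for s in samples}
    return ExpressionMatrix(pd.DataFrame(arr, index=genes, columns=samples), groups, is_raw=False)
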