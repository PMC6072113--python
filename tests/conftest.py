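import numpy as np
import pandas as pd
import pytest

from cernet.core_io import ExpressionMatrix, InteractionTable


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def count_matrix():
    values = pd.DataFrame(
        [[10.0, 5.0, 0.0], [990.0, 95.0, 100.0], [0.0, 0.0, 1.0]],
        index=["g1", "g2", "g3"],
        columns=["s1", "s2", "s3"],
    )
    return ExpressionMatrix(values, "mRNA", "raw_count",
                            {"s1": "normal", "s2": "tumor", "s3": "tumor"})


def make_interactions(pairs, kind="miRNA", source="test"):
    df = pd.DataFrame(pairs, columns=["regulator", "target"], dtype=str)
    df["regulator_kind"] = kind
    df["source"] = source
    return InteractionTable(df)


def zscore_matrix(rows, ids, samples=None, kind="mixed"):
    """Exactly standardized ExpressionMatrix from raw rows."""
    rows = np.asarray(rows, dtype=float)
    z = (rows - rows.mean(1, keepdims=True)) / rows.std(1, ddof=0, keepdims=True)
    samples = samples or [f"S{j}" for j in range(rows.shape[1])]
    return ExpressionMatrix(
        pd.DataFrame(z, index=ids, columns=samples), kind, "zscore",
        {s: "tumor" for s in samples},
    )
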