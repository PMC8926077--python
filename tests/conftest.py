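import numpy as np
import pandas as pd
import pytest

from modpres.datasets import ExpressionDataset


def make_dataset(values: np.ndarray, **meta) -> ExpressionDataset:
    """Wrap a plain genes x samples array in an ExpressionDataset."""
    n_genes, n_samples = values.shape
    genes = [f"G{i + 1:04d}" for i in range(n_genes)]
    samples = [f"S{j + 1:03d}" for j in range(n_samples)]
    metadata = pd.DataFrame(
        {
            "condition": meta.get("condition", "c"),
            "batch": meta.get("batch", ["b0"] * n_samples),
            "age": meta.get("age", np.full(n_samples, 70.0)),
            "sex": meta.get("sex", np.zeros(n_samples)),
        },
        index=samples,
    )
    return ExpressionDataset(pd.DataFrame(values, index=genes, columns=samples), metadata)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
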