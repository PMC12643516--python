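import numpy as np
import pandas as pd
import pytest

from cernascout.datasets import ExpressionDataset


def make_dataset(
    values: np.ndarray,
    n_control: int,
    biotype: str = "mRNA",
    feature_ids=None,
    cohort_id: str = "toy",
) -> ExpressionDataset:
    """Wrap a plain array into an ExpressionDataset (controls first)."""
    values = np.asarray(values, dtype=float)
    n_features, n_samples = values.shape
    features = feature_ids or [f"{biotype}:F{i:03d}" for i in range(n_features)]
    samples = [f"s{i:02d}" for i in range(n_samples)]
    group = ["control"] * n_control + ["case"] * (n_samples - n_control)
    return ExpressionDataset(
        values=pd.DataFrame(values, index=features, columns=samples),
        biotype=pd.Series(biotype, index=features),
        group=pd.Series(group, index=samples),
        cohort_id=cohort_id,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
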