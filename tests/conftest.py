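import numpy as np
import pandas as pd
import pytest

from mirlink import ExpressionMatrix, SimulationConfig, generate_dataset
from mirlink.expression import TREATED, CONTROL


def make_matrix(values, feature_ids=None, n_control=None):
    """ExpressionMatrix from a features x samples array; first half of the
    samples are control, second half treated unless n_control is given."""
    values = np.asarray(values, dtype=float)
    n_feat, n_samp = values.shape
    if n_control is None:
        n_control = n_samp // 2
    feature_ids = feature_ids or [f"f{i}" for i in range(n_feat)]
    sample_ids = [f"c{i}" for i in range(n_control)] + [
        f"t{i}" for i in range(n_samp - n_control)
    ]
    conditions = pd.Series(
        [CONTROL] * n_control + [TREATED] * (n_samp - n_control), index=sample_ids
    )
    return ExpressionMatrix(
        pd.DataFrame(values, index=feature_ids, columns=sample_ids), conditions
    )


@pytest.fixture
def small_dataset():
    config = SimulationConfig(n_mirna=8, n_mrna=40, n_planted_edges=10, seed=11)
    return generate_dataset(config)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
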