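import numpy as np
import pandas as pd
import pytest

from frdapipe import simulate_expression
from frdapipe.simcohort import pattern_recovery_config as planted_pattern_config  # noqa: F401


def make_labels(n_case: int, n_control: int) -> pd.Series:
    ids = [f"case_{i}" for i in range(n_case)] + [f"ctrl_{i}" for i in range(n_control)]
    return pd.Series(["case"] * n_case + ["control"] * n_control, index=ids, name="group")


def random_matrix(n_genes: int, n_case: int, n_control: int, seed: int) -> tuple[pd.DataFrame, pd.Series]:
    rng = np.random.default_rng(seed)
    labels = make_labels(n_case, n_control)
    mat = pd.DataFrame(
        rng.normal(size=(n_genes, n_case + n_control)),
        index=[f"g{i:04d}" for i in range(n_genes)],
        columns=labels.index,
    )
    return mat, labels


@pytest.fixture
def planted_pattern_cohort():
    cfg = planted_pattern_config(seed=11)
    return simulate_expression(cfg)
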