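import numpy as np
import pandas as pd
import pytest

from scprog import expression, synthetic


@pytest.fixture(scope="session")
def selection_dataset():
    """CV-selectable benchmark dataset (seed 1) shared across tests."""
    return synthetic.simulate_expression(synthetic.selection_benchmark_config(seed=1))


@pytest.fixture(scope="session")
def signature_dataset():
    """Wide-fold-change benchmark dataset (seed 1) shared across tests."""
    return synthetic.simulate_expression(synthetic.signature_benchmark_config(seed=1))


@pytest.fixture(scope="session")
def selection_expr(selection_dataset):
    return expression.tpm_from_counts(
        selection_dataset.counts, selection_dataset.cds_lengths
    )


@pytest.fixture(scope="session")
def signature_expr(signature_dataset):
    return expression.tpm_from_counts(
        signature_dataset.counts, signature_dataset.cds_lengths
    )


@pytest.fixture(scope="session")
def signature_true_groups(signature_dataset):
    ds = signature_dataset
    return pd.Series(
        [f"L{g}" for g in ds.true_group], index=ds.true_group.index, name="group"
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def adjusted_rand_index(a, b) -> float:
    from sklearn.metrics import adjusted_rand_score

    return float(adjusted_rand_score(list(a), list(b)))
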