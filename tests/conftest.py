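import numpy as np
import pandas as pd
import pytest

from matrixbank.bank import BankConfig, build_bank
from matrixbank.simulate import ResponseMatrix


@pytest.fixture(scope="session")
def default_bank():
    """The full default bank (220 unique items, 6 anchors, 10 forms)."""
    return build_bank(BankConfig(master_seed=20240901))


@pytest.fixture(scope="session")
def toy_config():
    return BankConfig(
        items_per_rule_count={1: 4, 2: 6, 3: 6, 4: 4},
        n_test_sets=2,
        set_composition={1: 2, 2: 3, 3: 3, 4: 2},
        anchor_composition={1: 1, 2: 1, 3: 1},
        n_practice=2,
        master_seed=11,
        rule_usage_targets=None,
    )


@pytest.fixture(scope="session")
def toy_bank(toy_config):
    return build_bank(toy_config)


def make_matrix(X, person_prefix="p", item_prefix="i", form_ids=None):
    """Wrap a numpy array (NaN = missing) into a ResponseMatrix."""
    X = np.asarray(X, dtype=float)
    persons = [f"{person_prefix}{i}" for i in range(X.shape[0])]
    items = [f"{item_prefix}{j}" for j in range(X.shape[1])]
    if form_ids is None:
        form_ids = ["F1"] * X.shape[0]
    return ResponseMatrix(
        pd.DataFrame(X, index=persons, columns=items),
        pd.Series(form_ids, index=persons, name="form_id"),
    )
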