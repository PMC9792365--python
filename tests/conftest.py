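import numpy as np
import pandas as pd
import pytest

from tmtdiff import (
    AbundanceTable,
    NormalizedMatrix,
    SyntheticConfig,
    combat_adjust,
    drop_missing,
    generate_dataset,
    log2_zscore,
    median_center,
    reference_normalize,
)

FULL_STEPS = ["reference_normalize", "median_center", "log2_zscore", "drop_missing"]


def make_matrix(values, groups, batches=None, steps=FULL_STEPS):
    """NormalizedMatrix straight from an array, for unit tests."""
    values = np.asarray(values, dtype=float)
    cols = [f"s{i}" for i in range(values.shape[1])]
    if batches is None:
        batches = ["B1"] * len(cols)
    data = pd.DataFrame(values, index=[f"P{i:04d}" for i in range(values.shape[0])], columns=cols)
    ann = pd.DataFrame({"group": list(groups), "batch": list(batches)}, index=cols)
    return NormalizedMatrix(data, ann, steps=list(steps))


@pytest.fixture
def tiny_table():
    """Two batches x (2 bio + 1 reference) hand-checkable table."""
    cols = ["c1", "k1", "r1", "c2", "k2", "r2"]
    data = pd.DataFrame(
        {
            "c1": [2.0, 8.0], "k1": [4.0, 2.0], "r1": [2.0, 4.0],
            "c2": [6.0, 1.0], "k2": [3.0, 2.0], "r2": [3.0, 2.0],
        },
        index=pd.Index(["P1", "P2"], name="protein"),
    )[cols]
    ann = pd.DataFrame(
        {
            "group": ["case", "control", "reference", "case", "control", "reference"],
            "batch": ["B1", "B1", "B1", "B2", "B2", "B2"],
        },
        index=pd.Index(cols, name="sample"),
    )
    return AbundanceTable(data, ann)


@pytest.fixture(scope="session")
def small_study():
    """One generated study (300 proteins) shared by read-only tests."""
    cfg = SyntheticConfig(n_proteins=300, seed=17)
    table, truth = generate_dataset(cfg)
    return cfg, table, truth


@pytest.fixture(scope="session")
def adjusted_study(small_study):
    """The shared study run through the full normalization cascade."""
    _, table, truth = small_study
    matrix = drop_missing(log2_zscore(median_center(reference_normalize(table))))
    adjusted, params = combat_adjust(matrix, protect_group=None)
    return table, truth, adjusted, params
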