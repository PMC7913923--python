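import numpy as np
import pandas as pd
import pytest

from tbimir.containers import AssayRole, CountMatrix, CqTable, SampleMeta


@pytest.fixture
def toy_counts() -> CountMatrix:
    """3 miRNAs x 2 samples with totals equal to column sums."""
    counts = pd.DataFrame(
        [[10, 40], [30, 40], [60, 20]],
        index=["miR-a", "miR-b", "miR-c"],
        columns=["s1", "s2"],
    )
    return CountMatrix.from_counts(counts)


@pytest.fixture
def two_group_meta() -> SampleMeta:
    table = pd.DataFrame(
        {"group": ["A", "A", "A", "B", "B", "B"]},
        index=[f"s{i}" for i in range(1, 7)],
    )
    return SampleMeta(table)


@pytest.fixture
def toy_cq() -> CqTable:
    cq = pd.DataFrame(
        {
            "miR-9a-3p": [25.0, 24.0, 26.0],
            "miR-28-3p": [24.0, 24.0, 24.0],
            "miR-23a": [26.0, 27.0, 30.0],
            "miR-451": [23.0, 24.0, 23.0],
        },
        index=["s1", "s2", "s3"],
    )
    roles = {
        "miR-9a-3p": AssayRole.TARGET,
        "miR-28-3p": AssayRole.REFERENCE,
        "miR-23a": AssayRole.HEMOLYSIS_23A,
        "miR-451": AssayRole.HEMOLYSIS_451,
    }
    return CqTable(cq, roles)


def make_count_matrix(array, mirnas=None, samples=None) -> CountMatrix:
    array = np.asarray(array)
    mirnas = mirnas or [f"m{i}" for i in range(array.shape[0])]
    samples = samples or [f"s{i}" for i in range(array.shape[1])]
    return CountMatrix.from_counts(
        pd.DataFrame(array, index=mirnas, columns=samples)
    )
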