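import pandas as pd
import pytest

from cortimir import DifferentialExpression, SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    return simulate_cohort(SimConfig(seed=11))


@pytest.fixture(scope="session")
def fitted_de(default_cohort):
    mirna = DifferentialExpression(
        default_cohort.mirna_counts, default_cohort.annotations
    ).fit()
    mrna = DifferentialExpression(
        default_cohort.mrna_counts, default_cohort.annotations
    ).fit()
    return mirna, mrna


@pytest.fixture()
def toy_counts():
    df = pd.DataFrame(
        {
            "s1": [10, 5, 0, 100],
            "s2": [20, 5, 1, 200],
            "s3": [40, 5, 6, 400],
            "s4": [15, 5, 7, 150],
        },
        index=["fA", "fB", "fC", "fD"],
    )
    from cortimir import CountMatrix

    return CountMatrix(df)
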