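import numpy as np
import pandas as pd
import pytest

from glycomark.quantify import CASE_LABEL, CONTROL_LABEL, FeatureTable
from glycomark.synthdata import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def cohort():
    """Default synthetic 20/18 cohort: 42 correlated log-normal features,
    all shifted +1.0 on the log scale in cases."""
    table, truth = generate_cohort(CohortConfig(seed=20250925))
    return table, truth


@pytest.fixture()
def small_table():
    """Tiny hand-checkable feature table: 4 cases vs 4 controls, 3 features."""
    rng = np.random.default_rng(7)
    ids = [f"s{i}" for i in range(8)]
    data = pd.DataFrame(
        rng.lognormal(mean=10, sigma=0.3, size=(8, 3)),
        index=ids,
        columns=["A", "B", "C"],
    )
    groups = pd.Series([CASE_LABEL] * 4 + [CONTROL_LABEL] * 4, index=ids)
    conc = pd.Series(rng.uniform(40, 80, size=8), index=ids)
    return FeatureTable(data, groups, conc)
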