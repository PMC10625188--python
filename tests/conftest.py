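import warnings

import numpy as np
import pandas as pd
import pytest

from ecanon.balance import fit_propensity
from ecanon.cohort import CohortTable
from ecanon.synth import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def full_config() -> CohortConfig:
    """Study-scale default configuration (3,327 RWD / 250 RCT)."""
    return CohortConfig(seed=11)


@pytest.fixture(scope="session")
def full_rwd(full_config) -> CohortTable:
    return generate_cohort(full_config, "RWD")


@pytest.fixture(scope="session")
def full_rct(full_config) -> CohortTable:
    return generate_cohort(full_config, "RCT")


@pytest.fixture(scope="session")
def full_stack(full_rwd, full_rct) -> CohortTable:
    return CohortTable(
        pd.concat([full_rwd.data, full_rct.data], ignore_index=True), "stacked"
    )


@pytest.fixture(scope="session")
def full_fit(full_stack, full_config):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return fit_propensity(full_stack, full_config.covariates["RWD"])


def toy_table(values: dict, arm: str = "RWD") -> CohortTable:
    """Minimal cohort table from explicit column values."""
    df = pd.DataFrame(values)
    if "subject_id" not in df.columns:
        df.insert(0, "subject_id", [f"{arm}-{i}" for i in range(len(df))])
    if "arm_label" not in df.columns:
        df["arm_label"] = arm
    return CohortTable(df, arm)
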