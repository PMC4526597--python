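import warnings

import numpy as np
import pandas as pd
import pytest

import habitlearn as hl

warnings.filterwarnings("ignore", category=FutureWarning)
warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture(scope="session")
def exp1_config() -> hl.TaskConfig:
    return hl.TaskConfig.exp1()


@pytest.fixture(scope="session")
def exp2_config() -> hl.TaskConfig:
    return hl.TaskConfig.exp2()


@pytest.fixture(scope="session")
def hybrid_subject(exp1_config) -> pd.DataFrame:
    """One mid-weight subject's full session log."""
    params = hl.AgentParams(alpha=0.5, beta=5.0, w=0.5, pi=0.2)
    return hl.simulate_subject(params, exp1_config, seed=11)


@pytest.fixture(scope="session")
def small_cohort(exp1_config) -> hl.Cohort:
    """20-subject cohort reused by the analysis-layer tests."""
    return hl.generate_cohort(20, config=exp1_config, seed=321)


@pytest.fixture(scope="session")
def small_design(small_cohort) -> pd.DataFrame:
    return hl.build_lagged_design(small_cohort.trials)


@pytest.fixture(scope="session")
def small_deval(small_cohort, exp1_config) -> pd.Series:
    summ = hl.subject_summaries(small_cohort.trials, exp1_config)
    return summ.set_index("subject")["deval_sensitivity"]
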