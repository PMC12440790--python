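import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from hcgdilution import (  # noqa: E402
    AnalyzerSpec,
    CohortConfig,
    StrategyConfig,
    TimingProfile,
    default_ruleset,
    generate_cohort,
    run_workflow,
)


def make_cohort_row(
    sample_id="S1",
    week=8,
    conc=150_000.0,
    sample_error=False,
    missing_info=False,
    nonpregnant=False,
):
    """Single-specimen cohort frame for worked examples."""
    return pd.DataFrame(
        {
            "sample_id": [sample_id],
            "reception_time": [pd.Timestamp("2024-01-01 08:00")],
            "gestational_week": pd.array([week], dtype="Int64"),
            "true_concentration": [conc],
            "flag_sample_error": [sample_error],
            "flag_missing_info": [missing_info],
            "flag_nonpregnant": [nonpregnant],
        }
    )


@pytest.fixture(scope="session")
def ruleset():
    return default_ruleset()


@pytest.fixture(scope="session")
def spec():
    return AnalyzerSpec()


@pytest.fixture(scope="session")
def cohort10k():
    """The default 10,000-specimen study cohort (fixed seed)."""
    return generate_cohort(CohortConfig(n_samples=10_000, seed=20240101))


@pytest.fixture(scope="session")
def strategy_outcomes(cohort10k):
    """All three strategies run on the shared default cohort."""
    out = {}
    for i, s in enumerate(("PRESET", "STRIP", "RETEST")):
        out[s] = run_workflow(
            cohort10k,
            StrategyConfig(strategy=s, seed=1000 + i),
            default_ruleset(),
            AnalyzerSpec(),
            TimingProfile(),
        )
    return out
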