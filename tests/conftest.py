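import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from phenoweek import CohortConfig, MissingnessConfig  # noqa: E402
from phenoweek.diary_comms import load_lexicon  # noqa: E402


@pytest.fixture(scope="session")
def lexicon():
    return load_lexicon()


@pytest.fixture(scope="session")
def tiny_cohort_config():
    """Small full-fidelity cohort, zero missingness (fast pipeline checks)."""
    return CohortConfig(
        n_participants=2, n_weeks=2, seed=101, missingness=MissingnessConfig.none()
    )


@pytest.fixture(scope="session")
def effect_cohort_matrix():
    """Full-fidelity 200-participant, 12-week cohort with default injected
    effects, run through the entire minutely pipeline.  Session-scoped:
    this is the expensive study-scale dataset shared by the effect-recovery
    checks."""
    from phenoweek.featurize import featurize_cohort

    cfg = CohortConfig(n_participants=200, seed=42)
    return featurize_cohort(cfg)


def minute_timestamps(date: str, n: int, start_minute: int = 0):
    """n distinct minutely timestamps on one calendar date."""
    base = pd.Timestamp(date) + pd.Timedelta(minutes=start_minute)
    return pd.date_range(base, periods=n, freq="min")


def hourly_pings(date: str, hours):
    return pd.DatetimeIndex([pd.Timestamp(date) + pd.Timedelta(hours=int(h)) for h in hours])
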