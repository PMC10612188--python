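import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    max_examples=50,
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cohort():
    """A modest synthetic cohort shared by read-only tests."""
    from glyvar import CohortParams, generate_cohort

    return generate_cohort(CohortParams(n_patients=800, seed=123))


@pytest.fixture(scope="session")
def analysis_frame(small_cohort):
    """Eligible patients merged with their variability metrics."""
    from glyvar import compute_metrics
    from glyvar.pipeline import apply_eligibility

    visits, patients, _ = apply_eligibility(
        small_cohort.visits, small_cohort.patients
    )
    metrics = compute_metrics(visits)
    return patients.merge(metrics, on="patient_id")


def random_trajectories(n, rng):
    """Random eligible HbA1c trajectories for oracle comparisons."""
    from glyvar import HbA1cTrajectory

    out = []
    for i in range(n):
        m = int(rng.integers(2, 25))
        times = np.sort(rng.choice(np.arange(0, 600), size=m, replace=False)).astype(float)
        values = np.clip(rng.normal(8.0, 1.0, m), 3.5, 15.0)
        out.append(HbA1cTrajectory(i, times, values))
    return out
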