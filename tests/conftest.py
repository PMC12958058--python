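import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import thermodev as td

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def truth():
    return td.SyntheticTruth()


@pytest.fixture(scope="session")
def noiseless_truth():
    return td.SyntheticTruth(sigma_duration=0.0, sd_length=0.0,
                             sd_width=0.0, sd_weight=0.0)


@pytest.fixture(scope="session")
def cohort(truth):
    return td.generate_cohort(truth, (15.0, 20.0, 25.0), 3, seed=7)


@pytest.fixture(scope="session")
def published_isomorphen():
    """Isomorphen table built from the published per-stage mean durations."""
    from thermodev.datasets import load_duration_summaries
    df = load_duration_summaries()
    per_temp = {}
    for temp in (15.0, 20.0, 25.0):
        per_temp[temp] = {
            s: float(df[(df.stage == s) & (df.temperature == temp)]["mean"].iloc[0])
            for s in td.STAGES}
    return td.build_isomorphen(per_temp)


@pytest.fixture(scope="session")
def noiseless_growth_models(noiseless_truth):
    return {T: td.fit_cubic_growth(
        td.generate_length_series(noiseless_truth, T, 12.0, seed=0), T)
        for T in (15.0, 20.0, 25.0)}


def random_duration_groups(rng, k=3, n=3):
    """Random positive raw groups for ANOVA equivalence checks."""
    return [rng.lognormal(mean=3.0, sigma=0.4, size=n) for _ in range(k)]
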