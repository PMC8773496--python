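import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=25, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture()
def cell_csv(tmp_path):
    """Small two-core cell table on disk."""
    rows = []
    rng = np.random.default_rng(0)
    for core_id, pid, n_cancer, n_stromal in [("c1", "p1", 12, 8), ("c2", "p2", 15, 10)]:
        for i in range(n_cancer + n_stromal):
            rows.append(
                {
                    "core_id": core_id,
                    "patient_id": pid,
                    "x_um": rng.uniform(-200, 200),
                    "y_um": rng.uniform(-200, 200),
                    "compartment": "cancer" if i < n_cancer else "stromal",
                    "cd163_intensity": rng.lognormal(2.0, 0.3),
                }
            )
    path = tmp_path / "cells.csv"
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


@pytest.fixture()
def survival_toy():
    """Six subjects, three early events in the high-metric half."""
    return dict(
        metric=np.array([1.0, 2.0, 3.0, 101.0, 102.0, 103.0]),
        time=np.array([10.0, 11.0, 12.0, 1.0, 2.0, 3.0]),
        event=np.array([False, False, False, True, True, True]),
    )


@pytest.fixture(scope="session")
def effect_cohort():
    """One seeded synthetic cohort with a true threshold effect (shared)."""
    from tamspatial.synthetic import CohortGenSpec, generate_cohort

    patients, _, truth = generate_cohort(CohortGenSpec(n_patients=300), seed=42, keep_cores=False)
    return patients, truth
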