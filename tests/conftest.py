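import numpy as np
import pandas as pd
import pytest

from rafh.simulate import CohortSimConfig, simulate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def default_cohort():
    """One trial-like simulated cohort shared across read-only tests."""
    return simulate_cohort(CohortSimConfig(seed=42))


@pytest.fixture
def tiny_cohort_frame():
    """Minimal valid two-visit, two-eye cohort table."""
    rows = []
    for pid, eye, t, a in [
        ("P001", "OD", 0.0, 2.25),
        ("P001", "OD", 1.0, 4.00),
        ("P002", "OS", 0.0, 1.00),
        ("P002", "OS", 1.5, 1.21),
    ]:
        rows.append(
            {
                "participant_id": pid,
                "eye": eye,
                "arm": "observation",
                "time_years": t,
                "rafh_g1": 0.2,
                "rafh_g2": 0.3,
                "ga_area_mm2": a,
                "ga_perimeter_mm": 2.0 * np.sqrt(np.pi * a),
                "focus_count": 1,
                "age": 75.0,
                "sex": "female",
                "bmi": 25.0,
                "smoking": "no",
                "cvd": "no",
                "faf_pattern_group": 1,
                "foveal_involvement": "yes",
                "adherence_pct": 100.0,
            }
        )
    return pd.DataFrame(rows)
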