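import numpy as np
import pandas as pd
import pytest

from ccepml.features import build_feature_table
from ccepml.synthetic import SyntheticCohortSpec, generate_cohort, generate_tests


@pytest.fixture(scope="session")
def small_cohort_dir(tmp_path_factory):
    """A small on-disk EDF cohort (8 patients, all tests usable)."""
    d = tmp_path_factory.mktemp("cohort")
    spec = SyntheticCohortSpec(seed=7, n_patients=8, tests_per_patient=(2, 4),
                               quality_pass_rate=1.0)
    manifest, truth = generate_cohort(spec, d)
    return d, manifest, truth


@pytest.fixture(scope="session")
def feature_table():
    """In-memory feature table of a 20-patient cohort (both classes)."""
    spec = SyntheticCohortSpec(seed=7, n_patients=20, tests_per_patient=(2, 4),
                               quality_pass_rate=1.0)
    tests, _ = generate_tests(spec)
    return build_feature_table(tests)


@pytest.fixture(scope="session")
def separable_table():
    """A linearly separable two-patient-cluster feature table."""
    rng = np.random.default_rng(0)
    rows = []
    for i in range(40):
        target = i % 2
        shift = 10.0 * target
        rows.append({
            "test_id": f"t{i}", "patient_id": f"p{i}", "target": target,
            "max_amp": shift + rng.normal(0, 0.3),
            "mean_amp": shift + rng.normal(0, 0.3),
            "min_amp": rng.normal(0, 0.3),
            "signal_mean": rng.normal(0, 0.3),
            "peak1_value": shift + rng.normal(0, 0.3),
            "peak1_latency": 80 + rng.normal(0, 1),
            "peak2_value": 0.0, "peak2_latency": 0.0,
            "trough1_value": 0.0, "trough1_latency": 0.0,
            "trough2_value": 0.0, "trough2_latency": 0.0,
        })
    return pd.DataFrame(rows)
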