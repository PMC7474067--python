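import numpy as np
import pandas as pd
import pytest

from normdev import CohortTable, MorphMatrix, SimConfig, generate_cohort


@pytest.fixture
def small_cohort_df():
    return pd.DataFrame(dict(
        subject_id=[f"s{i}" for i in range(6)],
        group=["case", "case", "case", "control", "control", "control"],
        sex=["male"] * 6,
        age=[8.0, 12.5, 20.0, 8.2, 12.4, 19.5],
        site=["A", "A", "B", "A", "B", "B"],
        motion_fd=[0.1, 0.2, 0.15, 0.1, 0.05, 0.3],
        euler=[10.0, 40.0, 20.0, 15.0, 30.0, 25.0],
    ))


@pytest.fixture
def small_cohort(small_cohort_df):
    return CohortTable(small_cohort_df)


@pytest.fixture
def small_morph(small_cohort_df):
    rng = np.random.default_rng(0)
    regions = ["r1", "r2", "r3"]
    vals = 2.5 + 0.1 * rng.standard_normal((6, len(regions)))
    df = pd.DataFrame(vals, index=pd.Index(small_cohort_df["subject_id"],
                                           name="subject_id"), columns=regions)
    return MorphMatrix(df)


@pytest.fixture(scope="session")
def calibration_pair():
    """Two independent control cohorts drawn from one synthetic population."""
    base = dict(n_control=800, n_case=0, n_regions=24,
                offset_range=(0.15, 0.35), tau_range=(10, 18),
                residual_sd=0.15, site_sd=0.005)
    a = generate_cohort(SimConfig(**base, seed=101))
    b = generate_cohort(SimConfig(**base, seed=102))
    return a, b


@pytest.fixture(scope="session")
def calibration_model(calibration_pair):
    """Degree-2 auto-span normative model fit on the first cohort."""
    from normdev import build_normative_model

    (cohort, morph, _), _ = calibration_pair
    return build_normative_model(cohort, morph, sex=None, seed=0, degree=2)
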