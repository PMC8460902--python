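import numpy as np
import pytest

from scolprog.cohort import (
    CohortConfig, SubjectRecord, cohort_to_frame, generate_cohort,
    sample_spine_geometry,
)
from scolprog.msk import ScalingConfig, build_model, solve_inverse_statics


@pytest.fixture(scope="session")
def default_cohort_df():
    """Default 100-subject calibrated cohort (feature mode)."""
    return cohort_to_frame(generate_cohort(CohortConfig(seed=1)))


@pytest.fixture(scope="session")
def subject():
    return SubjectRecord(id="S0001", age=12.0, sex="F", risser=1,
                         group="stable", height=158.0, weight=45.0,
                         followup_months=24.0)


@pytest.fixture(scope="session")
def scaling():
    return ScalingConfig(height=158.0, weight=45.0, age=12.0)


@pytest.fixture(scope="session")
def straight_geometry():
    rng = np.random.default_rng(0)
    return sample_spine_geometry(
        dict(tk=40.0, ll=58.0, ss=39.0, pi=47.0, cobb=0.0,
             largest_axial_rotation=0.0, n_curves=0), rng)


@pytest.fixture(scope="session")
def scoliotic_geometry():
    rng = np.random.default_rng(0)
    return sample_spine_geometry(
        dict(tk=44.0, ll=59.0, ss=39.6, pi=47.8, cobb=18.0,
             largest_axial_rotation=9.9, n_curves=1, apex="T9", side=1),
        rng)


@pytest.fixture(scope="session")
def solved_straight(subject, scaling, straight_geometry):
    model = build_model(subject, straight_geometry, scaling)
    return solve_inverse_statics(model)


@pytest.fixture(scope="session")
def solved_scoliotic(subject, scaling, scoliotic_geometry):
    model = build_model(subject, scoliotic_geometry, scaling)
    return solve_inverse_statics(model)


@pytest.fixture(scope="session")
def solved_scoliotic_mirror(subject, scaling, scoliotic_geometry):
    model = build_model(subject, scoliotic_geometry.mirrored(), scaling)
    return solve_inverse_statics(model)
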