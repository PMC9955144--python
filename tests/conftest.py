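import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from avslat import (CohortSpec, MechanisticParams, PatientMeta, PatientRecord,
                    Subtype, Thresholds)

settings.register_profile(
    "ci", derandomize=True, max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20230)


@pytest.fixture
def thresholds():
    return Thresholds()


def make_record(pid, *, rt_ok=True, surgery=True, postop_arr=90.0,
                bp_normal=True, followup=True, subtype=None):
    return PatientRecord(pid, [], PatientMeta(
        rt_sampling_complete=rt_ok, surgery_done_if_uapa=surgery,
        postop_arr=postop_arr, postop_bp_normal=bp_normal,
        followup_available=followup, subtype=subtype))


@pytest.fixture
def study_roster():
    """58-patient roster flagged to reproduce the published exclusion cascade:
    9 incomplete right sampling, 2 unoperated UAPA, 2 post-op ARR >= 200,
    0 blood-pressure failures, 1 lost to follow-up; 44 clean."""
    roster = []
    i = 0
    for _ in range(9):
        i += 1
        roster.append(make_record(f"X{i:02d}", rt_ok=False))
    for _ in range(2):
        i += 1
        roster.append(make_record(f"X{i:02d}", surgery=False))
    for _ in range(2):
        i += 1
        roster.append(make_record(f"X{i:02d}", postop_arr=250.0))
    i += 1
    roster.append(make_record(f"X{i:02d}", followup=False))
    for j in range(44):
        roster.append(make_record(f"P{j + 1:02d}"))
    return roster


@pytest.fixture
def zero_noise_params():
    return MechanisticParams(noise_cv=0.0)


@pytest.fixture
def small_cohort_spec():
    return CohortSpec(n_rt_apa=3, n_lt_apa=4, n_iha=5, mode="mechanistic", seed=11)
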