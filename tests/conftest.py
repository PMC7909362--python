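"""Shared fixtures: synthetic cohorts and processed metric tables."""

import numpy as np
import pytest

from vcgmem.simulate import CohortConfig, generate_cohort
from vcgmem.pipeline import process_cohort


@pytest.fixture(scope="session")
def study_cohort():
    """Default study conditions: n=20, 500 Hz, 10 s, four recordings each."""
    return generate_cohort(CohortConfig(n_patients=20, seed=20210215))


@pytest.fixture(scope="session")
def study_tables(study_cohort):
    recs = {p.patient_id: p.recordings for p in study_cohort.patients}
    metrics, angles = process_cohort(recs)
    return metrics, angles


@pytest.fixture(scope="session")
def clean_cohort():
    """Noise-free, rotation-free cohort for exact recovery checks."""
    cfg = CohortConfig(n_patients=6, seed=7, noise_sd_uv=0.0,
                       electrode_rotation_sd_deg=0.0, cm_person_sd_deg=0.0)
    return generate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
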