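"""Shared fixtures: desk-scale and study-scale synthetic cohorts.

Everything is generated programmatically and seeded; session scope
amortises the expensive cohorts across test modules.
"""

import numpy as np
import pandas as pd
import pytest

from nethom import simulate, study
from nethom.preprocess import BOLDRun

SMALL = dict(grid_dims=(14, 16, 14), n_timepoints=120,
             n_per_group={"control": 6, "patient_dpp": 6, "patient_dt": 6},
             network_fraction=0.14)

TINY = dict(grid_dims=(12, 14, 12), n_timepoints=60,
            n_per_group={"control": 4, "patient_dpp": 4, "patient_dt": 4},
            network_fraction=0.16)


def make_run(data, tr_s=2.0, subject_id="s", timepoint="baseline"):
    """Wrap a raw array (V x t or x,y,z,t) as a BOLDRun on a trivial grid."""
    data = np.asarray(data, dtype=float)
    if data.ndim == 2:
        data = data[:, None, None, :]
    return BOLDRun(data, tr_s, subject_id, timepoint, np.eye(4))


def flat_mask(n):
    return np.ones((n, 1, 1), dtype=bool)


@pytest.fixture(scope="session")
def small_config():
    return simulate.SimConfig(seed=101, **SMALL)


@pytest.fixture(scope="session")
def small_truth(small_config):
    return simulate.ground_truth_for(small_config)


@pytest.fixture(scope="session")
def study_config():
    """Study-scale conditions: default grid, 240 volumes, TR 2 s, and the
    post-QC arm sizes (19 DPP / 20 DT patients, 20 controls)."""
    return simulate.SimConfig(
        seed=202,
        n_per_group={"control": 20, "patient_dpp": 19, "patient_dt": 20})


@pytest.fixture(scope="session")
def dpp_study(study_config):
    """Standardised NH maps + metadata for DPP patients and controls."""
    maps, meta = study.nh_cohort(study_config, groups=("control", "patient_dpp"))
    return maps, meta


@pytest.fixture(scope="session")
def dpp_study_clinical(study_config):
    """Raw-scale DPP-patient cohort with planted clinical outcomes."""
    maps, meta = study.nh_cohort(study_config, groups=("patient_dpp",),
                                 standardize=False)
    clinical = study.clinical_table(study_config, maps)
    region = study.baseline_region_nh(study_config, maps)
    return maps, clinical, region


def baseline_design(meta: pd.DataFrame):
    """Patient-vs-control design with centred age and mean-FD covariates."""
    from nethom.inference import make_design
    frame = meta.copy()
    frame["is_patient"] = (frame.group == "patient").astype(int)
    return make_design(frame, "is_patient")
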