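import numpy as np
import pytest

import connage as ca


def make_timecourse(data, tr=0.735, subject_id="S1"):
    return ca.TimecourseMatrix(np.asarray(data, dtype=float), tr, subject_id)


@pytest.fixture(scope="session")
def small_cohort():
    """Cheap 16-subject cohort shared by shape/bookkeeping tests."""
    cfg = ca.CohortConfig(
        n_subjects=16, n_components=8, n_frames=150, n_states=2,
        state_dwell_mean=20, diagnosis_fraction=0.25, seed=7,
    )
    return ca.generate_cohort(cfg)


@pytest.fixture(scope="session")
def atlas53():
    return ca.load_default_atlas()
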