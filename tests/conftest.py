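import numpy as np
import pytest

from ipc_eval.scoring import score_cohort
from ipc_eval.synthetic import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort (96 patients, 4 timepoints, 1 dropout)."""
    return generate_cohort(CohortConfig(seed=0))


@pytest.fixture(scope="session")
def scored_cohort(default_cohort):
    return score_cohort(default_cohort)


@pytest.fixture(scope="session")
def bp_map(default_cohort):
    return {(r.patient_id, r.timepoint): (r.sbp, r.dbp)
            for r in default_cohort}


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
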