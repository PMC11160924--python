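import warnings

import numpy as np
import pytest

from stimmap.synthdata import CohortSpec, make_session


@pytest.fixture(scope="session")
def small_session():
    """One synthetic session shared by unit tests (read-only)."""
    cohort = CohortSpec(n_subjects=1, seed=11)
    session, gt = make_session(cohort, 0)
    return session, gt, cohort


@pytest.fixture(scope="session")
def preprocessed(small_session):
    from stimmap.preprocess import preprocess_session

    session, gt, cohort = small_session
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return preprocess_session(session), gt


@pytest.fixture(scope="session")
def instances(preprocessed):
    from stimmap.spectral import compute_instance

    sd, gt = preprocessed
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return [compute_instance(p, "sub-01") for p in sd.pairs], gt


@pytest.fixture(scope="session")
def cohort12_result():
    """Full-pipeline run at the default 12-subject study conditions.

    Session-scoped: the parameter-recovery acceptance checks all read from
    this single run.
    """
    from stimmap import PipelineConfig, run_pipeline

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_pipeline(PipelineConfig(seed=0, cohort={"n_subjects": 12}))


def rng(seed=0):
    return np.random.default_rng(seed)
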