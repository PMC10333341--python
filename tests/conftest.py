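import numpy as np
import pytest

from ecmnet.ecm_core import ec_table
from ecmnet.roi_atlas import default_registry
from ecmnet.synthetic_cohort import CohortConfig, generate_cohort
from ecmnet.timeseries_prep import preprocess_subject


def cohort_ec_table(config: CohortConfig):
    """Generate a cohort and push it through prep + ECM."""
    subjects, pheno = generate_cohort(config)
    cleaned = [
        (s.subject_id, preprocess_subject(s.data, s.motion, s.wm, s.csf)[0])
        for s in subjects
    ]
    groups = dict(zip(pheno["subject_id"], pheno["ptsd"]))
    return ec_table(cleaned, groups=groups), pheno


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def small_cohort():
    """A fast, fully planted cohort for unit tests."""
    cfg = CohortConfig(n_ptsd=12, n_control=14, n_volumes=80,
                       n_missing_months=3, seed=321)
    subjects, pheno = generate_cohort(cfg)
    return subjects, pheno, cfg


@pytest.fixture(scope="session")
def planted_run():
    """One default-scale planted cohort taken through prep + ECM."""
    cfg = CohortConfig(seed=11)
    table, pheno = cohort_ec_table(cfg)
    return table, pheno, cfg


@pytest.fixture(scope="session")
def planted_suite():
    """Twenty default-scale planted cohorts (shared by the heavy
    acceptance tests for hub power, moderation and WQS recovery)."""
    runs = []
    for seed in range(20):
        cfg = CohortConfig(seed=seed)
        table, pheno = cohort_ec_table(cfg)
        runs.append((table, pheno, cfg))
    return runs


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
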