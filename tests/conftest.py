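import numpy as np
import pytest

from pnesent.classify import ClassifierSpec, run_cv
from pnesent.entropy import extract_features
from pnesent.preprocess import preprocess_cohort
from pnesent.synth import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort_config():
    """Desk-scale cohort: 5 subjects/class, 4 epochs each, theta contrast."""
    return CohortConfig(n_pnes=5, n_epilepsy=5, epochs_per_subject=4, seed=7)


@pytest.fixture(scope="session")
def small_cohort(small_cohort_config):
    return generate_cohort(small_cohort_config)


@pytest.fixture(scope="session")
def small_banded(small_cohort):
    banded, _ = preprocess_cohort(small_cohort)
    return banded


@pytest.fixture(scope="session")
def renyi_features(small_banded):
    return extract_features(small_banded, "renyi")


def cv_balanced_accuracy(features, kind="knn", folds=5, seed=0):
    cv = run_cv(features, ClassifierSpec(kind=kind, seed=seed), folds=folds, seed=seed)
    return cv.mean_balanced_accuracy
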