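import numpy as np
import pytest

from mmfde.ensemble import BaseModelSpec, fit_ensemble
from mmfde.synthetic import GeneratorSpec, generate_cohort, worked_example_fixture


def fast_specs(seed: int = 42, n_estimators: int = 40) -> dict:
    """Reduced-size boosters for tests whose property does not depend on
    the reference hyperparameters."""
    return {
        "lightgbm": BaseModelSpec("lightgbm", n_estimators=n_estimators, max_depth=4,
                                  regularization=(("l1", 0.1), ("l2", 0.1)), seed=seed),
        "xgboost": BaseModelSpec("xgboost", n_estimators=n_estimators, max_depth=4,
                                 regularization=(("l1", 0.1), ("l2", 0.1)), seed=seed),
        "gbm": BaseModelSpec("gbm", n_estimators=n_estimators, max_depth=3,
                             regularization=(("subsample", 0.8),), seed=seed),
        "adaboost": BaseModelSpec("adaboost", n_estimators=n_estimators, seed=seed),
    }


@pytest.fixture(scope="session")
def worked_example():
    return worked_example_fixture()


@pytest.fixture(scope="session")
def small_cohort():
    """A 240-sample cohort with clear signal for fast end-to-end tests."""
    return generate_cohort(GeneratorSpec(n=240, prevalence=0.44, noise_sd=0.6, seed=7))


@pytest.fixture(scope="session")
def fitted_handle(small_cohort):
    """Base ensemble fitted on the first 180 rows of the small cohort."""
    X = small_cohort.features.iloc[:180]
    y = small_cohort.outcome[:180]
    return fit_ensemble(X, y, specs=fast_specs())


@pytest.fixture(scope="session")
def holdout(small_cohort):
    """The held-out rows matching ``fitted_handle``'s training split."""
    return small_cohort.features.iloc[180:], small_cohort.outcome[180:]


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
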