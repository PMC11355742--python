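import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import riskcascade as rc
from riskcascade.cascade import CascadeConfig, StageSpec

settings.register_profile("suite", deadline=None, derandomize=True,
                          max_examples=25)
settings.load_profile("suite")

# Published benchmark ranks: nine single learners + cascade over the three
# dataset instances (all 38 features / 37 without age / 37 without centre).
BENCHMARK_ALGORITHMS = [
    "AdaBoost", "Bagging", "Bernoulli NB", "Decision Tree", "Extra Trees",
    "Gradient Boosting", "Gaussian NB", "Logistic Regression",
    "Random Forest", "Cascade",
]
BENCHMARK_RANKS = pd.DataFrame(
    [[10.0, 5.5, 8.0, 7.0, 5.5, 2.0, 9.0, 4.0, 3.0, 1.0],
     [9.5, 4.0, 7.0, 6.0, 5.0, 2.0, 8.0, 9.5, 3.0, 1.0],
     [10.0, 4.5, 8.0, 7.0, 6.0, 2.0, 9.0, 4.5, 3.0, 1.0]],
    index=["38", "37a", "37c"], columns=BENCHMARK_ALGORITHMS)


@pytest.fixture(scope="session")
def schema():
    return rc.default_schema()


@pytest.fixture(scope="session")
def effects():
    return rc.default_effects()


@pytest.fixture(scope="session")
def cohort(schema, effects):
    """Default study-scale synthetic cohort (n = 1179, seed 7)."""
    return rc.generate_cohort(schema, effects, n=1179, seed=7)


@pytest.fixture(scope="session")
def split(cohort):
    return rc.split_cohort(cohort, 0.75, seed=1)


@pytest.fixture(scope="session")
def fitted(split):
    """Default three-stage cascade fitted on the 884-row training part."""
    train, _ = split
    return rc.fit_cascade(train, CascadeConfig())


@pytest.fixture(scope="session")
def prediction(fitted, split):
    _, test = split
    return fitted.predict(test)


@pytest.fixture(scope="session")
def small_cohort(schema, effects):
    """Smaller cohort for tests where fitting speed matters."""
    return rc.generate_cohort(schema, effects, n=300, seed=11)


@pytest.fixture(scope="session")
def fast_config():
    """Cheap-to-fit stages for flow/property tests."""
    return CascadeConfig(stages=(
        StageSpec("decision_tree", {"max_depth": 4}),
        StageSpec("gaussian_nb"),
        StageSpec("logistic_regression"),
    ))
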