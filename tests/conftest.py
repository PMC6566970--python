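import numpy as np
import pytest

import celearn as ce
from celearn.learners import LearnerSpec


@pytest.fixture(scope="session")
def blob_table():
    """A moderately separated 4-class blob table for learner tests."""
    return ce.make_feature_table(
        ce.SynthSpec(
            n_samples=300, n_classes=4, n_features=10,
            class_separation=4.0, noise_sd=1.0, seed=42,
        )
    )


@pytest.fixture(scope="session")
def separable_table():
    """An (effectively) infinitely separated blob table: any learner
    should reach 100% training accuracy."""
    return ce.make_feature_table(
        ce.SynthSpec(
            n_samples=120, n_classes=3, n_features=6,
            class_separation=1e6, noise_sd=1.0, seed=7,
        )
    )


@pytest.fixture(scope="session")
def small_specs():
    """Small learner configurations keeping cascade tests fast."""
    return (
        LearnerSpec("boosted_trees", {"n_rounds": 5, "max_depth": 2}),
        LearnerSpec("gini_bagged", {"n_trees": 25}),
        LearnerSpec("fully_random", {"n_trees": 25}),
        LearnerSpec("softmax", {"n_iterations": 100}),
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(20260921)
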